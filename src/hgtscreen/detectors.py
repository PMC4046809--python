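"""Similarity-based HGT candidate screening.

The core detector is the *alien index*: the ratio of the best homology
bit score among putative donor ("distant") groups to the best among the
recipient's close relatives.  A gene whose strongest homologs sit in
prokaryotes or algae rather than in metazoans/fungi scores above 1, and
the conventional candidate threshold is 1.2 (inclusive: a gene at
exactly the threshold is retained).  A gene with distant homologs but no
close homolog at all scores +infinity; a gene with no homologs on either
side is reported separately as NO_HOMOLOGY and is never a candidate,
because every transfer call ultimately rests on donor-group homology.

Externally produced candidate lists (e.g. from lineage-probability or
tree-pipeline screens) plug in through :func:`import_candidates`, so
multi-program consensus accounting works without re-implementing those
programs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .blast_tab import HitTable, top_hit_per_group
from .taxonomy import Group

log = logging.getLogger(__name__)

__all__ = [
    "AI_THRESHOLD_DEFAULT",
    "CLOSE_GROUPS_DEFAULT",
    "DISTANT_GROUPS_DEFAULT",
    "PREDICTED",
    "NOT_PREDICTED",
    "NOT_RUN",
    "AlienScore",
    "DetectorVerdicts",
    "alien_index",
    "screen_genome",
    "import_candidates",
]

AI_THRESHOLD_DEFAULT = 1.2
#: "Closely related taxa": the focal lineage's vertical kin.  Other
#: eukaryotes count toward neither side by default; both sets are
#: configurable because the screen targets donor-group affiliation.
CLOSE_GROUPS_DEFAULT = frozenset({Group.KIN})
DISTANT_GROUPS_DEFAULT = frozenset({Group.PROKARYOTE, Group.ALGA})

PREDICTED = "predicted"
NOT_PREDICTED = "not_predicted"
NOT_RUN = "not_run"


@dataclass
class AlienScore:
    """Alien-index result for one query.

    ``ai`` is +inf when distant homologs exist but no close homolog does,
    and NaN when the query has no homologs on either side (then
    ``no_homology`` is set and the query is not a candidate).
    """

    query_id: str
    close_best: float | None
    distant_best: float | None
    ai: float
    is_candidate: bool
    no_homology: bool = False


def alien_index(
    table: HitTable,
    query: str,
    close_groups: frozenset[Group] = CLOSE_GROUPS_DEFAULT,
    distant_groups: frozenset[Group] = DISTANT_GROUPS_DEFAULT,
    threshold: float = AI_THRESHOLD_DEFAULT,
) -> AlienScore:
    """Score one query; the table should already be filtered (no SELF hits)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    try:
        tops = top_hit_per_group(table, query)
    except KeyError:
        tops = {}
    close = [tops[g].bitscore for g in close_groups if g in tops]
    distant = [tops[g].bitscore for g in distant_groups if g in tops]
    close_best = max(close) if close else None
    distant_best = max(distant) if distant else None
    if distant_best is None and close_best is None:
        return AlienScore(query, None, None, math.nan, False, no_homology=True)
    if distant_best is None:
        return AlienScore(query, close_best, None, 0.0, False)
    if close_best is None or close_best == 0.0:
        return AlienScore(query, close_best, distant_best, math.inf, True)
    ai = distant_best / close_best
    return AlienScore(query, close_best, distant_best, ai, ai >= threshold)


class DetectorVerdicts:
    """Tri-state per-query flags (predicted / not-predicted / not-run)
    for any number of named detectors, with provenance strings."""

    def __init__(self, queries: Iterable[str] = ()):
        self.queries: list[str] = list(dict.fromkeys(queries))
        self._flags: dict[str, dict[str, str]] = {}
        self.provenance: dict[str, str] = {}
        self.scores: dict[str, AlienScore] = {}

    @property
    def detectors(self) -> list[str]:
        return list(self._flags)

    def add_detector(
        self,
        name: str,
        predicted: Iterable[str],
        run_on: Iterable[str] | None = None,
        provenance: str = "",
    ) -> None:
        if name in self._flags:
            raise ValueError(f"detector {name!r} already present")
        predicted = set(predicted)
        ran = set(run_on) if run_on is not None else set(self.queries) | predicted
        for q in predicted | ran:
            if q not in self.queries:
                self.queries.append(q)
        flags = {}
        for q in self.queries:
            if q in predicted:
                flags[q] = PREDICTED
            elif q in ran:
                flags[q] = NOT_PREDICTED
            else:
                flags[q] = NOT_RUN
        self._flags[name] = flags
        self.provenance[name] = provenance

    def flag(self, query: str, detector: str) -> str:
        return self._flags.get(detector, {}).get(query, NOT_RUN)

    def flags_for(self, query: str) -> dict[str, str]:
        return {d: self.flag(query, d) for d in self._flags}

    def predicted(self, detector: str) -> set[str]:
        return {q for q, f in self._flags[detector].items() if f == PREDICTED}

    def predicted_any(self) -> set[str]:
        out: set[str] = set()
        for d in self._flags:
            out |= self.predicted(d)
        return out

    def merge(self, other: "DetectorVerdicts") -> "DetectorVerdicts":
        """Fold another verdict set into this one (detector names must differ)."""
        for q in other.queries:
            if q not in self.queries:
                self.queries.append(q)
        for name in other.detectors:
            if name in self._flags:
                raise ValueError(f"detector {name!r} present in both verdict sets")
            self._flags[name] = {
                q: other.flag(q, name) for q in self.queries
            }
            self.provenance[name] = other.provenance.get(name, "")
        # re-pad existing detectors for newly discovered queries
        for name, flags in self._flags.items():
            for q in self.queries:
                flags.setdefault(q, NOT_RUN)
        self.scores.update(other.scores)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.queries:
            for d in self._flags:
                score = self.scores.get(q)
                rows.append(
                    {
                        "query_id": q,
                        "detector": d,
                        "flag": self.flag(q, d),
                        "ai": score.ai if score and d == "alien_index" else math.nan,
                    }
                )
        return pd.DataFrame(rows, columns=["query_id", "detector", "flag", "ai"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def screen_genome(
    table: HitTable,
    queries: Iterable[str],
    close_groups: frozenset[Group] = CLOSE_GROUPS_DEFAULT,
    distant_groups: frozenset[Group] = DISTANT_GROUPS_DEFAULT,
    threshold: float = AI_THRESHOLD_DEFAULT,
    detector_name: str = "alien_index",
) -> DetectorVerdicts:
    """Run the alien-index detector over a query list.

    Deterministic given inputs; one verdict row per query.  Queries with
    no homology are flagged not-predicted and kept retrievable through
    ``verdicts.scores`` (their ``no_homology`` flag is set).
    """
    queries = list(dict.fromkeys(queries))
    verdicts = DetectorVerdicts(queries)
    predicted = []
    for q in queries:
        score = alien_index(table, q, close_groups, distant_groups, threshold)
        verdicts.scores[q] = score
        if score.is_candidate:
            predicted.append(q)
    verdicts.add_detector(
        detector_name,
        predicted,
        run_on=queries,
        provenance=f"alien_index threshold={threshold:g} "
        f"close={sorted(g.value for g in close_groups)} "
        f"distant={sorted(g.value for g in distant_groups)}",
    )
    return verdicts


def import_candidates(
    path: str | Path,
    detector_name: str,
    queries: Iterable[str],
) -> DetectorVerdicts:
    """Import an externally produced candidate list (one query id per line).

    Listed queries are flagged predicted for ``detector_name``; all other
    known queries not-predicted.  Ids not in ``queries`` are ignored with
    a warning; duplicates are deduplicated and logged.
    """
    queries = list(dict.fromkeys(queries))
    known = set(queries)
    listed: list[str] = []
    with open(path) as fh:
        for raw in fh:
            qid = raw.strip()
            if qid and not qid.startswith("#"):
                listed.append(qid)
    if len(set(listed)) < len(listed):
        log.info("candidate list %s contains duplicates; deduplicating", path)
    unknown = [q for q in dict.fromkeys(listed) if q not in known]
    for q in unknown:
        log.warning("candidate list names unknown query %r; ignored", q)
    predicted = [q for q in dict.fromkeys(listed) if q in known]
    verdicts = DetectorVerdicts(queries)
    verdicts.add_detector(
        detector_name, predicted, run_on=queries, provenance=f"imported from {path}"
    )
    return verdicts
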