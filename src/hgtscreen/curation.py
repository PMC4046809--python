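"""Consensus curation: final transfer calls, donors, directions, events.

Detector verdicts are screens, not calls.  A gene is ACCEPTED when either
of two evidence routes holds:

* its gene tree shows a supported (>= 70% bootstrap by default) clade of
  the query with prokaryote and/or alga homologs excluding kin, or
* its phyletic pattern is restricted — homologs occur only in the focal
  lineage plus prokaryotes and/or algae (patterns PROK_ONLY, ALGA_ONLY,
  PROK_ALGA_ONLY).

Both routes are recorded; a gene with a tree that fails the clade test
and a broad pattern is REJECTED, and a gene lacking usable evidence is
NO_CALL.  Direction follows the asymmetry of phagotrophy: restricted
patterns, and broad patterns whose accepted clade is donor-affiliated,
are read as transfer *into* the focal genome; everything else stays
undetermined.  Donor class comes from the supporting clade's donor
composition (all-alga -> ALGA, all-prokaryote -> BACTERIA, mixed ->
EITHER); for pattern-route calls without a clade it falls back on the
pattern and on the margin between the best alga and best prokaryote bit
scores.

Since duplication can follow acquisition, accepted genes that cluster
together in their family tree are collapsed into a single HGT *event*;
focal leaves separated by donor leaves stay separate events, and genes
from different families are never merged.  Manual-inspection evidence
(shared indels, conserved residues, gene structure, alignment quality,
scaffold-neighbor contamination checks) is carried as a free-form
checklist on each record rather than decided algorithmically; a helper
implements the scaffold-neighbor contamination heuristic given a gene
order table.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .blast_tab import HitTable, top_hit_per_group
from .detectors import DetectorVerdicts, NOT_PREDICTED, PREDICTED
from .taxonomy import Group
from .treescan import (
    CURATION_SUPPORT_DEFAULT,
    DONOR_GROUPS_DEFAULT,
    CladeTestResult,
    GeneTree,
    clade_test,
)

log = logging.getLogger(__name__)

__all__ = [
    "SHARE_EVALUE_DEFAULT",
    "PhyleticPattern",
    "DonorClass",
    "Direction",
    "Status",
    "CurationRecord",
    "EventCluster",
    "ConsensusSummary",
    "phyletic_pattern",
    "curate_gene",
    "infer_direction",
    "classify_donor",
    "collapse_events",
    "homolog_sharing",
    "consensus_accounting",
    "flag_scaffold_contamination",
    "records_to_frame",
    "write_ledger",
    "read_ledger",
]

#: E-value cutoff for calling a homolog shared with the second proteome.
SHARE_EVALUE_DEFAULT = 1e-40


class PhyleticPattern(str, enum.Enum):
    PROK_ONLY = "PROK_ONLY"
    ALGA_ONLY = "ALGA_ONLY"
    PROK_ALGA_ONLY = "PROK_ALGA_ONLY"
    BROAD = "BROAD"
    NO_HOMOLOGY = "NO_HOMOLOGY"


RESTRICTED_PATTERNS = frozenset(
    {PhyleticPattern.PROK_ONLY, PhyleticPattern.ALGA_ONLY, PhyleticPattern.PROK_ALGA_ONLY}
)


class DonorClass(str, enum.Enum):
    ALGA = "ALGA"
    BACTERIA = "BACTERIA"
    EITHER = "EITHER"


class Direction(str, enum.Enum):
    INTO_FOCAL = "INTO_FOCAL"
    UNDETERMINED = "UNDETERMINED"


class Status(str, enum.Enum):
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"
    NO_CALL = "NO_CALL"


@dataclass
class CurationRecord:
    """Per-gene ledger row combining every line of evidence."""

    gene_id: str
    detector_flags: dict[str, str] = field(default_factory=dict)
    phyletic_pattern: PhyleticPattern | None = None
    tree_result: CladeTestResult | None = None
    donor_class: DonorClass | None = None
    direction: Direction = Direction.UNDETERMINED
    status: Status = Status.NO_CALL
    event_id: str | None = None
    shared_with_second_species: bool | None = None
    evidence: dict[str, bool] = field(default_factory=dict)


@dataclass
class EventCluster:
    event_id: str
    genes: tuple[str, ...]
    donor_class: DonorClass | None


def phyletic_pattern(table: HitTable, query: str) -> PhyleticPattern:
    """Distribution pattern of a query's homologs across groups.

    SELF hits never widen the pattern (presence in the focal lineage is a
    given); a query with no non-SELF hits signals NO_HOMOLOGY.
    """
    try:
        sub = table.for_query(query)
    except KeyError:
        return PhyleticPattern.NO_HOMOLOGY
    groups = set(sub["group"]) - {Group.SELF}
    if not groups:
        return PhyleticPattern.NO_HOMOLOGY
    if groups == {Group.PROKARYOTE}:
        return PhyleticPattern.PROK_ONLY
    if groups == {Group.ALGA}:
        return PhyleticPattern.ALGA_ONLY
    if groups <= {Group.PROKARYOTE, Group.ALGA}:
        return PhyleticPattern.PROK_ALGA_ONLY
    return PhyleticPattern.BROAD


def infer_direction(record: CurationRecord) -> Direction:
    """Transfer direction from the pattern and the accepted clade."""
    if record.phyletic_pattern in RESTRICTED_PATTERNS:
        return Direction.INTO_FOCAL
    if (
        record.phyletic_pattern is PhyleticPattern.BROAD
        and record.tree_result is not None
        and record.tree_result.passed
    ):
        return Direction.INTO_FOCAL
    return Direction.UNDETERMINED


def classify_donor(
    record: CurationRecord,
    table: HitTable | None = None,
    margin: float = 0.1,
) -> DonorClass:
    """Donor class of an accepted gene.

    Clade route: all donor leaves alga -> ALGA, all prokaryote ->
    BACTERIA, mixed -> EITHER.  Pattern route (no passing clade):
    PROK_ONLY -> BACTERIA, ALGA_ONLY -> ALGA; PROK_ALGA_ONLY compares the
    best alga and prokaryote bit scores and returns EITHER when their
    relative difference is below ``margin``.
    """
    if record.status is not Status.ACCEPTED:
        raise ValueError(f"donor classification requires an ACCEPTED record: {record.gene_id}")
    tr = record.tree_result
    if tr is not None and tr.passed:
        n_alga = tr.donor_composition.get(Group.ALGA, 0)
        n_prok = tr.donor_composition.get(Group.PROKARYOTE, 0)
        if n_alga and n_prok:
            return DonorClass.EITHER
        if n_alga:
            return DonorClass.ALGA
        if n_prok:
            return DonorClass.BACTERIA
        return DonorClass.EITHER  # supported but donor-ambiguous
    if record.phyletic_pattern is PhyleticPattern.PROK_ONLY:
        return DonorClass.BACTERIA
    if record.phyletic_pattern is PhyleticPattern.ALGA_ONLY:
        return DonorClass.ALGA
    if record.phyletic_pattern is PhyleticPattern.PROK_ALGA_ONLY:
        if table is None:
            return DonorClass.EITHER
        tops = top_hit_per_group(table, record.gene_id)
        best_a = tops[Group.ALGA].bitscore if Group.ALGA in tops else 0.0
        best_p = tops[Group.PROKARYOTE].bitscore if Group.PROKARYOTE in tops else 0.0
        top = max(best_a, best_p)
        if top <= 0 or abs(best_a - best_p) / top < margin:
            return DonorClass.EITHER
        return DonorClass.ALGA if best_a > best_p else DonorClass.BACTERIA
    return DonorClass.EITHER


def curate_gene(
    query: str,
    table: HitTable,
    tree: GeneTree | None,
    detector_flags: Mapping[str, str] | None = None,
    donor_groups: frozenset[Group] = DONOR_GROUPS_DEFAULT,
    curation_support: float = CURATION_SUPPORT_DEFAULT,
    allowed_other: str = "lenient",
    donor_margin: float = 0.1,
) -> CurationRecord:
    """Full per-gene curation: pattern, clade test, status, donor, direction."""
    pattern = phyletic_pattern(table, query)
    tree_result = (
        clade_test(tree, donor_groups, curation_support, allowed_other)
        if tree is not None
        else None
    )
    if pattern in RESTRICTED_PATTERNS or (tree_result is not None and tree_result.passed):
        status = Status.ACCEPTED
    elif tree_result is None:
        status = Status.NO_CALL
    else:
        status = Status.REJECTED
    record = CurationRecord(
        gene_id=query,
        detector_flags=dict(detector_flags or {}),
        phyletic_pattern=pattern,
        tree_result=tree_result,
        status=status,
    )
    record.direction = infer_direction(record)
    if status is Status.ACCEPTED:
        record.donor_class = classify_donor(record, table, margin=donor_margin)
    return record


# --------------------------------------------------------------------------
# Event collapsing

def _event_clusters(
    tree: GeneTree,
    accepted: set[str],
    neutral_leaves: set[str],
) -> list[frozenset]:
    """Maximal separator-free clades with at least one accepted leaf.

    Separators are leaves that are neither family genes nor SELF-group
    homologs; they break event clusters.  Evaluated on the unrooted
    topology, so the result is invariant to how the newick was rooted.
    """

    def is_separator(node) -> bool:
        if not node.is_leaf():
            return False
        label = node.taxon.label
        return label not in neutral_leaves and tree.groups.get(label) is not Group.SELF

    adj = tree.adjacency()
    sep_leaves = [n for n in adj if is_separator(n)]
    if not sep_leaves:
        return [frozenset(accepted)] if accepted else []
    root = sep_leaves[0]
    clusters: list[frozenset] = []

    # iterative post-order from the separator root
    start = adj[root][0]
    stack = [(start, root, False)]
    state: dict = {}
    while stack:
        node, parent, processed = stack.pop()
        if not processed:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb is not parent:
                    stack.append((nb, node, False))
            continue
        if node.is_leaf():
            label = node.taxon.label
            if is_separator(node):
                state[node] = None  # dirty
            else:
                state[node] = {label} & accepted
            continue
        children = [nb for nb in adj[node] if nb is not parent]
        child_states = [state[c] for c in children]
        if any(s is None for s in child_states):
            for s in child_states:
                if s is not None and s:
                    clusters.append(frozenset(s))
            state[node] = None
        else:
            merged: set = set()
            for s in child_states:
                merged |= s
            state[node] = merged
    top = state[start]
    if top is not None and top:
        clusters.append(frozenset(top))
    return clusters


def collapse_events(
    records: Iterable[CurationRecord],
    family_trees: Mapping[str, GeneTree],
    family_map: Mapping[str, str] | None = None,
) -> tuple[list[EventCluster], list[tuple[str, str]]]:
    """Collapse accepted genes into HGT events, one family tree at a time.

    Genes absent from ``family_map`` form singleton families.  A
    multi-gene family without a tree, or an accepted gene missing from
    its family tree, produces an error record; affected genes fall back
    to singleton events.  Assigned event ids are written back onto the
    records.  Returns (clusters, errors).
    """
    records = list(records)
    family_map = dict(family_map or {})
    by_record = {r.gene_id: r for r in records}
    accepted = {r.gene_id for r in records if r.status is Status.ACCEPTED}

    families: dict[str, list[str]] = defaultdict(list)
    for r in records:
        families[family_map.get(r.gene_id, r.gene_id)].append(r.gene_id)

    clusters: list[EventCluster] = []
    errors: list[tuple[str, str]] = []
    for fam in sorted(families):
        genes = families[fam]
        fam_accepted = [g for g in genes if g in accepted]
        if not fam_accepted:
            continue
        tree = family_trees.get(fam)
        raw_clusters: list[frozenset]
        if tree is None:
            if len(genes) > 1:
                errors.append((fam, "multi-gene family without a family tree"))
            raw_clusters = [frozenset({g}) for g in fam_accepted]
        else:
            missing = [g for g in fam_accepted if g not in tree.leaves]
            for g in missing:
                errors.append((g, f"accepted gene absent from family tree {fam!r}"))
            present = set(fam_accepted) - set(missing)
            raw_clusters = _event_clusters(tree, present, neutral_leaves=set(genes))
            raw_clusters += [frozenset({g}) for g in missing]
        for i, members in enumerate(sorted(raw_clusters, key=lambda s: sorted(s)), 1):
            event_id = f"{fam}.e{i}"
            donors = {
                by_record[g].donor_class for g in members if by_record[g].donor_class
            }
            donor = donors.pop() if len(donors) == 1 else (DonorClass.EITHER if donors else None)
            clusters.append(EventCluster(event_id, tuple(sorted(members)), donor))
            for g in members:
                by_record[g].event_id = event_id
    return clusters, errors


def homolog_sharing(
    accepted: Iterable[str],
    second_proteome_hits: HitTable,
    evalue_max: float = SHARE_EVALUE_DEFAULT,
) -> dict[str, bool]:
    """Flag genes whose best second-proteome hit is at or below the cutoff.

    A shared homolog is read as acquisition before the two species split.
    Genes with no hit are not shared.
    """
    best = second_proteome_hits.df.groupby("query_id")["evalue"].min()
    return {g: bool(best.get(g, float("inf")) <= evalue_max) for g in accepted}


@dataclass
class ConsensusSummary:
    """Detector-overlap accounting over the final curated calls.

    ``positive_rate`` is curated-true candidates over all candidates a
    detector predicted (None when it predicted nothing); the
    ``false_negative_rate`` is the share of accepted genes the detector
    missed.  Rates are fractions in [0, 1].
    """

    per_detector: pd.DataFrame
    accepted_total: int
    union_accepted: int
    missed_by_all: int


def consensus_accounting(
    verdicts: DetectorVerdicts,
    records: Iterable[CurationRecord],
) -> ConsensusSummary:
    records = list(records)
    accepted = {r.gene_id for r in records if r.status is Status.ACCEPTED}
    union: set[str] = set()
    rows = []
    for det in verdicts.detectors:
        predicted = verdicts.predicted(det)
        pred_accepted = predicted & accepted
        union |= pred_accepted
        rows.append(
            {
                "detector": det,
                "predicted_total": len(predicted),
                "predicted_accepted": len(pred_accepted),
                "positive_rate": (len(pred_accepted) / len(predicted)) if predicted else None,
                "false_negative_rate": (
                    len(accepted - predicted) / len(accepted) if accepted else None
                ),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "detector", "predicted_total", "predicted_accepted",
        "positive_rate", "false_negative_rate",
    ])
    return ConsensusSummary(
        per_detector=df,
        accepted_total=len(accepted),
        union_accepted=len(union),
        missed_by_all=len(accepted - union),
    )


def flag_scaffold_contamination(
    gene_order: pd.DataFrame,
    kin_affiliated: set[str],
    genes: Iterable[str],
) -> dict[str, bool]:
    """Scaffold-neighbor contamination heuristic.

    ``gene_order`` needs columns gene_id, scaffold, position.  A gene is
    flagged when every adjacent gene on its scaffold lacks kin
    (metazoan/fungal) affiliation — the signature of a contaminating
    contig rather than a native acquisition.  Genes without neighbors
    are not flagged.
    """
    flags: dict[str, bool] = {}
    order = gene_order.sort_values(["scaffold", "position"])
    neighbors: dict[str, list[str]] = defaultdict(list)
    for _, scaffold_df in order.groupby("scaffold"):
        ids = list(scaffold_df["gene_id"])
        for i, g in enumerate(ids):
            if i > 0:
                neighbors[g].append(ids[i - 1])
            if i + 1 < len(ids):
                neighbors[g].append(ids[i + 1])
    for g in genes:
        nb = neighbors.get(g, [])
        flags[g] = bool(nb) and all(n not in kin_affiliated for n in nb)
    return flags


# --------------------------------------------------------------------------
# Ledger I/O

def records_to_frame(records: Iterable[CurationRecord]) -> pd.DataFrame:
    records = list(records)
    detector_names = sorted({d for r in records for d in r.detector_flags})
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "status": r.status.value,
            "phyletic_pattern": r.phyletic_pattern.value if r.phyletic_pattern else "",
            "donor_class": r.donor_class.value if r.donor_class else "",
            "direction": r.direction.value,
            "clade_passed": bool(r.tree_result.passed) if r.tree_result else False,
            "clade_support": (
                r.tree_result.support if r.tree_result and r.tree_result.passed else ""
            ),
            "event_id": r.event_id or "",
            "shared_with_second_species": (
                "" if r.shared_with_second_species is None else r.shared_with_second_species
            ),
        }
        for d in detector_names:
            row[f"det_{d}"] = r.detector_flags.get(d, "not_run")
        rows.append(row)
    return pd.DataFrame(rows)


def write_ledger(records: Iterable[CurationRecord] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def read_ledger(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
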