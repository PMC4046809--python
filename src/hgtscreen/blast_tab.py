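"""Tabular homology hits: parsing, exclusion filters, per-group best hits.

Input is BLAST outfmt-6-style TSV extended with a subject taxon column and
(optionally) a subject annotation column; column order is configurable.
Three exclusion rules mirror standard practice for similarity-based HGT
screens of a focal proteome:

1. drop hits to the focal (SELF) lineage — self matches carry no donor
   signal;
2. drop hits covering less than 10% of the query length — spurious
   local matches;
3. drop hits whose subject annotation marks a pseudo-entry ("artificial
   sequence", "synthetic construct", "plasmid"), matched
   case-insensitively as substrings.

Coverage is query-relative: alignment length divided by query length.
When one query has several HSPs to the same subject, the maximum-bitscore
HSP represents the pair, matching single-number "top hit" semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .taxonomy import Group, TaxonomyScheme

log = logging.getLogger(__name__)

__all__ = [
    "Hit",
    "HitTable",
    "ParseError",
    "parse_hits",
    "filter_hits",
    "top_hit_per_group",
    "table_from_frame",
    "ARTIFICIAL_ANNOTATIONS",
    "DEFAULT_COLUMNS",
    "EVALUE_MAX_AI_SCREEN",
    "EVALUE_MAX_TREE_SCREEN",
    "MIN_COVERAGE_DEFAULT",
]

#: Default E-value ceiling for the similarity (alien index) screen.
EVALUE_MAX_AI_SCREEN = 1e-5
#: Default E-value ceiling for the gene-tree screening pipeline.
EVALUE_MAX_TREE_SCREEN = 1e-10
#: Minimum fraction of the query covered by the alignment.
MIN_COVERAGE_DEFAULT = 0.10
#: Annotation substrings marking pseudo-entries (case-insensitive).
ARTIFICIAL_ANNOTATIONS = ("artificial sequence", "synthetic construct", "plasmid")

DEFAULT_COLUMNS = (
    "query_id",
    "subject_id",
    "bitscore",
    "evalue",
    "coverage",
    "subject_taxon",
    "subject_annotation",
)

_FIELDS = [
    "query_id",
    "subject_id",
    "bitscore",
    "evalue",
    "coverage",
    "subject_taxon",
    "subject_annotation",
    "group",
]


class Hit(NamedTuple):
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    coverage: float
    subject_taxon: str
    subject_annotation: str
    group: Group


@dataclass
class ParseError:
    line: int
    reason: str


@dataclass
class HitTable:
    """Homology hits grouped by query, each labeled with a taxonomy group.

    ``filters`` records the provenance of every filter applied so a
    written table carries an audit trail in its header.
    """

    df: pd.DataFrame
    filters: tuple[str, ...] = ()
    errors: list[ParseError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def queries(self) -> list[str]:
        return list(dict.fromkeys(self.df["query_id"]))

    def for_query(self, query: str) -> pd.DataFrame:
        return self.df[self.df["query_id"] == query]

    def hits(self) -> list[Hit]:
        return [Hit(*row) for row in self.df[_FIELDS].itertuples(index=False)]

    def write(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for applied in self.filters:
                fh.write(f"# filter: {applied}\n")
            out = self.df[_FIELDS[:-1]]
            out.to_csv(fh, sep="\t", index=False)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({name: pd.Series(dtype=t) for name, t in zip(
        _FIELDS, [str, str, float, float, float, str, str, object])})


def table_from_frame(df: pd.DataFrame, scheme: TaxonomyScheme) -> HitTable:
    """Label a raw hit frame with taxonomy groups; unknown taxa are dropped."""
    df = df.copy()
    if "subject_annotation" not in df:
        df["subject_annotation"] = ""
    known = df["subject_taxon"].map(lambda t: t in scheme).astype(bool)
    errors = [
        ParseError(i, f"unknown taxon {t!r}")
        for i, t in zip(df.index[~known], df.loc[~known, "subject_taxon"])
    ]
    if errors:
        log.warning("dropped %d hits with unknown taxa", len(errors))
    df = df[known].copy()
    df["group"] = df["subject_taxon"].map(scheme.group_of)
    df = df[_FIELDS].reset_index(drop=True)
    return HitTable(df=df, errors=errors)


def parse_hits(
    path: str | Path,
    scheme: TaxonomyScheme,
    columns: Iterable[str] = DEFAULT_COLUMNS,
    dedup_subjects: bool = True,
) -> HitTable:
    """Parse a tabular hit file and label every hit with its group.

    ``columns`` names the file's columns in order; use ``"_"`` for columns
    to ignore.  Coverage may be given directly (``coverage``, a fraction)
    or derived from ``length`` and ``qlen`` (alignment length over query
    length).  Malformed rows are recorded with their line number and
    skipped; an empty file yields an empty table with a warning.
    """
    columns = list(columns)
    rows: list[dict] = []
    errors: list[ParseError] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(columns):
                errors.append(ParseError(lineno, f"expected {len(columns)} fields, got {len(parts)}"))
                continue
            rec = {name: value for name, value in zip(columns, parts) if name != "_"}
            try:
                row = _coerce_row(rec)
            except ValueError as exc:
                errors.append(ParseError(lineno, str(exc)))
                continue
            rows.append(row)
    if not rows:
        log.warning("no hits parsed from %s", path)
        table = HitTable(df=_empty_frame(), errors=errors)
        return table
    df = pd.DataFrame(rows)
    table = table_from_frame(df, scheme)
    table.errors = errors + table.errors
    if dedup_subjects:
        table = _best_hsp_per_pair(table)
    return table


def _coerce_row(rec: dict) -> dict:
    for key in ("query_id", "subject_id", "subject_taxon"):
        if key not in rec or not str(rec[key]).strip():
            raise ValueError(f"missing field {key}")
    bitscore = float(rec["bitscore"])
    evalue = float(rec["evalue"])
    if "coverage" in rec:
        coverage = float(rec["coverage"])
    elif "length" in rec and "qlen" in rec:
        qlen = float(rec["qlen"])
        if qlen <= 0:
            raise ValueError("non-positive query length")
        coverage = float(rec["length"]) / qlen
    else:
        raise ValueError("no coverage column and no length/qlen pair")
    if not (bitscore >= 0) or bitscore != bitscore or bitscore == float("inf"):
        raise ValueError(f"bitscore out of range: {bitscore}")
    if evalue < 0:
        raise ValueError(f"negative E-value: {evalue}")
    if not (0.0 <= coverage <= 1.0):
        raise ValueError(f"coverage outside [0, 1]: {coverage}")
    return {
        "query_id": str(rec["query_id"]),
        "subject_id": str(rec["subject_id"]),
        "bitscore": bitscore,
        "evalue": evalue,
        "coverage": coverage,
        "subject_taxon": str(rec["subject_taxon"]),
        "subject_annotation": str(rec.get("subject_annotation", "")),
    }


def _best_hsp_per_pair(table: HitTable) -> HitTable:
    df = (
        table.df.sort_values(
            ["bitscore", "evalue"], ascending=[False, True], kind="mergesort"
        )
        .drop_duplicates(["query_id", "subject_id"])
        .sort_index()
        .reset_index(drop=True)
    )
    return replace(table, df=df)


def filter_hits(
    table: HitTable,
    evalue_max: float | None = EVALUE_MAX_AI_SCREEN,
    min_coverage: float | None = MIN_COVERAGE_DEFAULT,
    exclude_annotations: Iterable[str] = ARTIFICIAL_ANNOTATIONS,
    exclude_groups: Iterable[Group] = (Group.SELF,),
) -> HitTable:
    """Apply the exclusion rules, preserving relative hit order.

    Any rule can be disabled by passing None/empty; an empty result is
    valid.  The applied settings are appended to the table's provenance.
    """
    if evalue_max is not None and evalue_max < 0:
        raise ValueError("evalue_max must be non-negative")
    if min_coverage is not None and min_coverage < 0:
        raise ValueError("min_coverage must be non-negative")
    df = table.df
    applied = []
    mask = pd.Series(True, index=df.index)
    if evalue_max is not None:
        mask &= df["evalue"] <= evalue_max
        applied.append(f"evalue<={evalue_max:g}")
    if min_coverage is not None:
        mask &= df["coverage"] >= min_coverage
        applied.append(f"coverage>={min_coverage:g}")
    patterns = [p.lower() for p in (exclude_annotations or ())]
    if patterns:
        ann = df["subject_annotation"].str.lower()
        bad = pd.Series(False, index=df.index)
        for pat in patterns:
            bad |= ann.str.contains(pat, regex=False)
        mask &= ~bad
        applied.append("exclude_annotations=" + "|".join(patterns))
    groups = set(exclude_groups or ())
    if groups:
        mask &= ~df["group"].isin(groups)
        applied.append("exclude_groups=" + ",".join(sorted(g.value for g in groups)))
    return HitTable(
        df=df[mask].reset_index(drop=True),
        filters=table.filters + tuple(applied),
        errors=list(table.errors),
    )


def top_hit_per_group(table: HitTable, query: str) -> dict[Group, Hit]:
    """Best hit per group for one query.

    "Best" is maximal bitscore; ties break on lower E-value, then on
    lexicographically smaller subject id.  Groups with no hits are absent
    from the mapping.  A query absent from the table raises ``KeyError``.
    """
    sub = table.for_query(query)
    if sub.empty:
        raise KeyError(f"query not in hit table: {query!r}")
    ordered = sub.sort_values(
        ["bitscore", "evalue", "subject_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.drop_duplicates("group")
    return {row.group: Hit(*row) for row in best[_FIELDS].itertuples(index=False)}
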