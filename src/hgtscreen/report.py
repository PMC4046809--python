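"""Summary reporting over a curation ledger.

Condenses a per-gene ledger into the screen's headline statistics: the
genome fraction attributable to transfer, donor-class and event counts,
per-detector overlap (share of the detector-union, positive rate,
false-negative rate), the homolog-sharing split with a sister species,
and functional-category percentages.  All percentages are rounded
half-up to one decimal; category percentages use only the functionally
categorized subset as denominator, with unknown-function genes (with or
without recognizable domains) reported as separate buckets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .detectors import DetectorVerdicts

__all__ = [
    "SummaryReport",
    "DetectorStats",
    "CategoryRow",
    "summarize",
    "render",
    "report_from_json",
    "report_from_tsv",
    "round_half_up",
    "UNCATEGORIZED_DEFAULT",
]

#: Category labels excluded from the categorized denominator.
UNCATEGORIZED_DEFAULT = ("unknown", "unknown_domain_only", "")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: float, denominator: float) -> float:
    return round_half_up(100.0 * numerator / denominator) if denominator else 0.0


@dataclass
class DetectorStats:
    detector: str
    predicted_accepted: int
    predicted_total: int | None
    pct_of_union: float
    positive_rate_pct: float | None
    false_negative_rate_pct: float


@dataclass
class CategoryRow:
    category: str
    count: int
    pct: float


@dataclass
class SummaryReport:
    accepted_total: int
    genome_total: int
    genome_fraction_pct: float
    donor_counts: dict = field(default_factory=dict)
    event_counts: dict = field(default_factory=dict)
    detector_overlap: list = field(default_factory=list)
    union_accepted: int = 0
    missed_by_all: int = 0
    shared_with_second: int = 0
    not_shared_with_second: int = 0
    categorized_total: int = 0
    category_table: list = field(default_factory=list)
    uncategorized_counts: dict = field(default_factory=dict)
    exclusive_categories: bool = True

    def category_count(self, *names: str) -> int:
        return sum(row.count for row in self.category_table if row.category in names)


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "shared")
    return bool(value) and not pd.isna(value)


def summarize(
    ledger: pd.DataFrame,
    genome_total: int,
    categories: Mapping[str, str] | pd.DataFrame | None = None,
    verdicts: DetectorVerdicts | None = None,
    uncategorized: Iterable[str] = UNCATEGORIZED_DEFAULT,
    exclusive_categories: bool = True,
) -> SummaryReport:
    """Compute the summary report from a curation ledger.

    ``ledger`` is the per-gene table written by the curation stage (or
    the packaged fixture); detector flags live in ``det_<name>`` columns.
    ``categories`` optionally maps gene id -> functional category and
    overrides any ``category`` column.  ``verdicts``, when given, supply
    each detector's *total* candidate count (including candidates that
    failed curation) so positive rates can be reported; without it they
    are NA.  ``genome_total`` below the accepted count is a hard error.
    """
    accepted_mask = ledger["status"] == "ACCEPTED"
    accepted = ledger[accepted_mask]
    n_accepted = int(accepted_mask.sum())
    if genome_total < n_accepted:
        raise ValueError(
            f"genome_total ({genome_total}) below accepted gene count ({n_accepted})"
        )

    report = SummaryReport(
        accepted_total=n_accepted,
        genome_total=int(genome_total),
        genome_fraction_pct=_pct(n_accepted, genome_total),
        exclusive_categories=exclusive_categories,
    )

    if "donor_class" in ledger and n_accepted:
        counts = accepted["donor_class"].value_counts()
        report.donor_counts = {str(k): int(v) for k, v in counts.items() if str(k)}

    if "event_id" in ledger and n_accepted:
        with_events = accepted[accepted["event_id"].astype(str).str.len() > 0]
        if len(with_events):
            report.event_counts = {
                str(k): int(v)
                for k, v in with_events.groupby("donor_class")["event_id"].nunique().items()
                if str(k)
            }

    det_cols = [c for c in ledger.columns if c.startswith("det_")]
    accepted_ids = set(accepted["gene_id"])
    union: set[str] = set()
    for col in det_cols:
        union |= set(accepted.loc[accepted[col] == "predicted", "gene_id"])
    report.union_accepted = len(union)
    report.missed_by_all = n_accepted - len(union)
    for col in det_cols:
        name = col[len("det_"):]
        pred_accepted = set(accepted.loc[accepted[col] == "predicted", "gene_id"])
        if verdicts is not None and name in verdicts.detectors:
            total = len(verdicts.predicted(name))
        else:
            total = int((ledger[col] == "predicted").sum())
            if total == len(pred_accepted) and len(ledger) == n_accepted:
                total = None  # ledger holds accepted genes only: totals unknown
        stats = DetectorStats(
            detector=name,
            predicted_accepted=len(pred_accepted),
            predicted_total=total,
            pct_of_union=_pct(len(pred_accepted), len(union)),
            positive_rate_pct=_pct(len(pred_accepted), total) if total else None,
            false_negative_rate_pct=_pct(
                n_accepted - len(pred_accepted), n_accepted
            ),
        )
        report.detector_overlap.append(stats)

    if "shared_with_second_species" in ledger and n_accepted:
        flags = accepted["shared_with_second_species"].map(_truthy)
        report.shared_with_second = int(flags.sum())
        report.not_shared_with_second = n_accepted - report.shared_with_second

    cat_series = None
    if categories is not None:
        mapping = (
            dict(zip(categories["gene_id"], categories["category"]))
            if isinstance(categories, pd.DataFrame)
            else dict(categories)
        )
        cat_series = accepted["gene_id"].map(mapping).fillna("")
    elif "category" in ledger:
        cat_series = accepted["category"].fillna("")
    if cat_series is not None and n_accepted:
        uncategorized = set(uncategorized)
        is_cat = ~cat_series.isin(uncategorized)
        categorized = cat_series[is_cat]
        report.categorized_total = int(is_cat.sum())
        for cat, count in categorized.value_counts().items():
            report.category_table.append(
                CategoryRow(str(cat), int(count), _pct(count, report.categorized_total))
            )
        report.category_table.sort(key=lambda r: (-r.count, r.category))
        unc = cat_series[~is_cat].value_counts()
        report.uncategorized_counts = {str(k) or "unknown": int(v) for k, v in unc.items()}
    return report


# --------------------------------------------------------------------------
# rendering

def render(report: SummaryReport, fmt: str, path: str | Path | None = None) -> str:
    """Render a report as json, tsv or text; json and tsv round-trip."""
    if fmt == "json":
        text = json.dumps(asdict(report), indent=2, sort_keys=True) + "\n"
    elif fmt == "tsv":
        text = _render_tsv(report)
    elif fmt == "text":
        text = _render_text(report)
    else:
        raise ValueError(f"unknown format {fmt!r}; use json, tsv or text")
    if path is not None:
        Path(path).write_text(text)
    return text


def report_from_json(text: str) -> SummaryReport:
    data = json.loads(text)
    data["detector_overlap"] = [DetectorStats(**d) for d in data["detector_overlap"]]
    data["category_table"] = [CategoryRow(**d) for d in data["category_table"]]
    return SummaryReport(**data)


_NA = "NA"


def _fmt(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _render_tsv(report: SummaryReport) -> str:
    lines = ["[summary]", "key\tvalue"]
    for key in (
        "accepted_total", "genome_total", "genome_fraction_pct", "union_accepted",
        "missed_by_all", "shared_with_second", "not_shared_with_second",
        "categorized_total", "exclusive_categories",
    ):
        lines.append(f"{key}\t{_fmt(getattr(report, key))}")
    lines.append("[donor_counts]")
    lines.append("donor_class\tgenes\tevents")
    for donor in sorted(set(report.donor_counts) | set(report.event_counts)):
        lines.append(
            f"{donor}\t{report.donor_counts.get(donor, 0)}"
            f"\t{_fmt(report.event_counts.get(donor))}"
        )
    lines.append("[detectors]")
    lines.append(
        "detector\tpredicted_accepted\tpredicted_total\tpct_of_union"
        "\tpositive_rate_pct\tfalse_negative_rate_pct"
    )
    for d in report.detector_overlap:
        lines.append(
            f"{d.detector}\t{d.predicted_accepted}\t{_fmt(d.predicted_total)}"
            f"\t{_fmt(d.pct_of_union)}\t{_fmt(d.positive_rate_pct)}"
            f"\t{_fmt(d.false_negative_rate_pct)}"
        )
    lines.append("[categories]")
    lines.append("category\tcount\tpct")
    for row in report.category_table:
        lines.append(f"{row.category}\t{row.count}\t{_fmt(row.pct)}")
    lines.append("[uncategorized]")
    lines.append("bucket\tcount")
    for bucket, count in sorted(report.uncategorized_counts.items()):
        lines.append(f"{bucket}\t{count}")
    return "\n".join(lines) + "\n"


def report_from_tsv(text: str) -> SummaryReport:
    section = None
    summary: dict = {}
    donor_counts: dict = {}
    event_counts: dict = {}
    detectors: list[DetectorStats] = []
    categories: list[CategoryRow] = []
    uncategorized: dict = {}

    def parse_scalar(value: str):
        if value == _NA:
            return None
        if value in ("True", "False"):
            return value == "True"
        try:
            return int(value)
        except ValueError:
            return float(value)

    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        parts = line.split("\t")
        if section == "summary":
            if parts[0] == "key":
                continue
            summary[parts[0]] = parse_scalar(parts[1])
        elif section == "donor_counts":
            if parts[0] == "donor_class":
                continue
            donor_counts[parts[0]] = int(parts[1])
            if parts[2] != _NA:
                event_counts[parts[0]] = int(parts[2])
        elif section == "detectors":
            if parts[0] == "detector":
                continue
            detectors.append(
                DetectorStats(
                    detector=parts[0],
                    predicted_accepted=int(parts[1]),
                    predicted_total=None if parts[2] == _NA else int(parts[2]),
                    pct_of_union=float(parts[3]),
                    positive_rate_pct=None if parts[4] == _NA else float(parts[4]),
                    false_negative_rate_pct=float(parts[5]),
                )
            )
        elif section == "categories":
            if parts[0] == "category":
                continue
            categories.append(CategoryRow(parts[0], int(parts[1]), float(parts[2])))
        elif section == "uncategorized":
            if parts[0] == "bucket":
                continue
            uncategorized[parts[0]] = int(parts[1])
    return SummaryReport(
        accepted_total=summary["accepted_total"],
        genome_total=summary["genome_total"],
        genome_fraction_pct=float(summary["genome_fraction_pct"]),
        donor_counts=donor_counts,
        event_counts=event_counts,
        detector_overlap=detectors,
        union_accepted=summary["union_accepted"],
        missed_by_all=summary["missed_by_all"],
        shared_with_second=summary["shared_with_second"],
        not_shared_with_second=summary["not_shared_with_second"],
        categorized_total=summary["categorized_total"],
        category_table=categories,
        uncategorized_counts=uncategorized,
        exclusive_categories=bool(summary["exclusive_categories"]),
    )


def _render_text(report: SummaryReport) -> str:
    lines = [
        "HGT screen summary",
        "==================",
        f"Accepted transferred genes: {report.accepted_total} of "
        f"{report.genome_total} genome models ({report.genome_fraction_pct}%)",
    ]
    if report.donor_counts:
        donors = ", ".join(
            f"{donor}: {count}" for donor, count in sorted(report.donor_counts.items())
        )
        lines.append(f"Donor classes: {donors}")
    if report.event_counts:
        events = ", ".join(
            f"{donor}: {count}" for donor, count in sorted(report.event_counts.items())
        )
        lines.append(f"Estimated events: {events}")
    if report.detector_overlap:
        lines.append(
            f"Detector union among accepted: {report.union_accepted}; "
            f"missed by all detectors: {report.missed_by_all}"
        )
        for d in report.detector_overlap:
            pr = _NA if d.positive_rate_pct is None else f"{d.positive_rate_pct}%"
            lines.append(
                f"  {d.detector}: {d.predicted_accepted} accepted "
                f"({d.pct_of_union}% of union), positive rate {pr}, "
                f"false-negative rate {d.false_negative_rate_pct}%"
            )
    lines.append(
        f"Shared with second species: {report.shared_with_second}; "
        f"not shared: {report.not_shared_with_second}"
    )
    if report.category_table:
        lines.append(f"Functionally categorized: {report.categorized_total}")
        for row in report.category_table:
            lines.append(f"  {row.category}: {row.count} ({row.pct}%)")
    for bucket, count in sorted(report.uncategorized_counts.items()):
        lines.append(f"  [{bucket}]: {count}")
    return "\n".join(lines) + "\n"
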