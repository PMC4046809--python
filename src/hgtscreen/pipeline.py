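"""End-to-end screen -> tree test -> curation orchestration.

Ties the stages together the way a genome screen runs in practice:
filter the raw hit table, run the enabled detectors (similarity screen
at the candidate threshold, batch tree screen at the recall-oriented
support level), pool their candidate lists, then curate each candidate
at the stricter curation support and collapse accepted genes into
events.  Genes no detector flagged never reach curation and stay
NO_CALL — mirroring a real screen, where manual curation only sees the
candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .blast_tab import EVALUE_MAX_AI_SCREEN, MIN_COVERAGE_DEFAULT, HitTable, filter_hits
from .curation import (
    SHARE_EVALUE_DEFAULT,
    CurationRecord,
    EventCluster,
    Status,
    collapse_events,
    curate_gene,
    homolog_sharing,
)
from .detectors import AI_THRESHOLD_DEFAULT, DetectorVerdicts, screen_genome
from .synthetic_data import SimBundle
from .treescan import (
    CURATION_SUPPORT_DEFAULT,
    DONOR_GROUPS_DEFAULT,
    SCREEN_SUPPORT_DEFAULT,
    batch_screen,
)

__all__ = ["PipelineResult", "run_pipeline", "score_against_truth"]


@dataclass
class PipelineResult:
    records: list[CurationRecord]
    events: list[EventCluster]
    verdicts: DetectorVerdicts
    filtered_hits: HitTable

    def accepted(self) -> set[str]:
        return {r.gene_id for r in self.records if r.status is Status.ACCEPTED}


def run_pipeline(
    bundle: SimBundle,
    detectors: tuple[str, ...] = ("alien_index", "treescan"),
    ai_threshold: float = AI_THRESHOLD_DEFAULT,
    screen_support: float = SCREEN_SUPPORT_DEFAULT,
    curation_support: float = CURATION_SUPPORT_DEFAULT,
    evalue_max: float = EVALUE_MAX_AI_SCREEN,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
    share_evalue: float = SHARE_EVALUE_DEFAULT,
    allowed_other: str = "lenient",
) -> PipelineResult:
    """Run the full screen over a simulation bundle (or equivalent)."""
    genes = list(bundle.truth["gene_id"])
    filtered = filter_hits(bundle.hits, evalue_max=evalue_max, min_coverage=min_coverage)

    verdicts = DetectorVerdicts(genes)
    if "alien_index" in detectors:
        verdicts.merge(screen_genome(filtered, genes, threshold=ai_threshold))
    if "treescan" in detectors:
        verdicts.merge(
            batch_screen(
                bundle.trees,
                donor_groups=DONOR_GROUPS_DEFAULT,
                min_support=screen_support,
                allowed_other=allowed_other,
            )
        )

    candidates = verdicts.predicted_any()
    records: list[CurationRecord] = []
    for gene in genes:
        flags = verdicts.flags_for(gene)
        if gene in candidates:
            record = curate_gene(
                gene,
                filtered,
                bundle.trees.get(gene),
                detector_flags=flags,
                curation_support=curation_support,
                allowed_other=allowed_other,
            )
        else:
            record = CurationRecord(gene_id=gene, detector_flags=flags)
        records.append(record)

    shared = homolog_sharing(
        [r.gene_id for r in records if r.status is Status.ACCEPTED],
        bundle.second_hits,
        evalue_max=share_evalue,
    )
    for r in records:
        if r.gene_id in shared:
            r.shared_with_second_species = shared[r.gene_id]

    events, _ = collapse_events(records, bundle.family_trees, bundle.family_map)
    return PipelineResult(records=records, events=events, verdicts=verdicts,
                          filtered_hits=filtered)


def score_against_truth(result: PipelineResult, truth: pd.DataFrame) -> dict[str, float]:
    """Sensitivity/specificity of the final accepted set versus the
    planted labels, plus planted and recovered event counts."""
    accepted = result.accepted()
    is_hgt = dict(zip(truth["gene_id"], truth["is_hgt"]))
    positives = {g for g, h in is_hgt.items() if h}
    negatives = {g for g, h in is_hgt.items() if not h}
    tp = len(accepted & positives)
    tn = len(negatives - accepted)
    sensitivity = tp / len(positives) if positives else float("nan")
    specificity = tn / len(negatives) if negatives else float("nan")
    planted_events = truth.loc[truth["is_hgt"], "event"].nunique()
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "n_true": len(positives),
        "n_negative": len(negatives),
        "events_planted": int(planted_events),
        "events_recovered": len(result.events),
    }
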