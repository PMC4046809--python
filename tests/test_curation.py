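from __future__ import annotations

import pandas as pd
import pytest

from conftest import make_table
from hgtscreen.curation import (
    CurationRecord,
    Direction,
    DonorClass,
    PhyleticPattern,
    Status,
    classify_donor,
    collapse_events,
    consensus_accounting,
    curate_gene,
    flag_scaffold_contamination,
    homolog_sharing,
    infer_direction,
    phyletic_pattern,
    read_ledger,
    records_to_frame,
    write_ledger,
)
from hgtscreen.detectors import DetectorVerdicts
from hgtscreen.synthetic_data import make_paper_fixture, make_paper_verdicts
from hgtscreen.treescan import parse_tree

TAXON_OF = {
    "Q": "Monosiga", "Q1": "Monosiga", "Q2": "Monosiga", "Q3": "Monosiga",
    "SR": "Salpingoeca",
    "B1": "Escherichia", "B2": "Bacillus", "A1": "Ostreococcus",
    "A2": "Thalassiosira", "H1": "Homo", "F1": "Saccharomyces",
    "E1": "Dictyostelium",
}


def tree_of(newick, scheme, query="Q"):
    return parse_tree(newick, scheme, query, taxon_of=TAXON_OF)


# ---------------------------------------------------------------------------
# phyletic patterns

@pytest.mark.parametrize(
    "taxa, expected",
    [
        (["Escherichia"] * 4, PhyleticPattern.PROK_ONLY),
        (["Ostreococcus"] * 3, PhyleticPattern.ALGA_ONLY),
        (["Ostreococcus"] * 3 + ["Escherichia"] * 2, PhyleticPattern.PROK_ALGA_ONLY),
        (["Ostreococcus"] * 3 + ["Homo"], PhyleticPattern.BROAD),
        (["Escherichia", "Dictyostelium"], PhyleticPattern.BROAD),
        (["Salpingoeca", "Escherichia"], PhyleticPattern.PROK_ONLY),  # SELF ignored
        (["Salpingoeca"], PhyleticPattern.NO_HOMOLOGY),
        ([], PhyleticPattern.NO_HOMOLOGY),
    ],
)
def test_phyletic_pattern(scheme, taxa, expected):
    rows = [("q", f"s{i}", 100.0, 1e-30, 0.9, t) for i, t in enumerate(taxa)]
    table = make_table(rows, scheme)
    assert phyletic_pattern(table, "q") is expected


# ---------------------------------------------------------------------------
# direction and donor classification

def test_restricted_patterns_imply_transfer_into_focal():
    for pattern in (PhyleticPattern.PROK_ONLY, PhyleticPattern.ALGA_ONLY,
                    PhyleticPattern.PROK_ALGA_ONLY):
        rec = CurationRecord(gene_id="g", phyletic_pattern=pattern)
        assert infer_direction(rec) is Direction.INTO_FOCAL


def test_broad_pattern_with_passing_clade_into_focal(scheme):
    tree = tree_of("((Q,A1)95,(H1,F1),B1);", scheme)
    rec = curate_gene("Q", make_table(
        [("Q", "s1", 300.0, 1e-40, 0.9, "Ostreococcus"),
         ("Q", "s2", 100.0, 1e-10, 0.9, "Homo")], scheme), tree)
    assert rec.status is Status.ACCEPTED
    assert rec.direction is Direction.INTO_FOCAL


def test_broad_pattern_with_failed_clade_undetermined(scheme):
    tree = tree_of("((Q,H1)95,(A1,B1));", scheme)
    rec = curate_gene("Q", make_table(
        [("Q", "s1", 300.0, 1e-40, 0.9, "Ostreococcus"),
         ("Q", "s2", 100.0, 1e-10, 0.9, "Homo")], scheme), tree)
    assert rec.status is Status.REJECTED
    assert rec.direction is Direction.UNDETERMINED


@pytest.mark.parametrize(
    "newick, expected",
    [
        ("(((Q,A1)90,A2)85,(H1,F1),B1);", DonorClass.ALGA),
        ("(((Q,B1)90,B2)85,(H1,F1),A1);", DonorClass.BACTERIA),
    ],
)
def test_donor_class_from_clade_composition(scheme, newick, expected):
    tree = tree_of(newick, scheme)
    rec = curate_gene("Q", make_table(
        [("Q", "s", 300.0, 1e-40, 0.9, "Homo"),
         ("Q", "s2", 400.0, 1e-50, 0.9, "Ostreococcus")], scheme), tree)
    assert rec.status is Status.ACCEPTED
    assert rec.donor_class is expected


def test_donor_class_mixed_clade_is_either(scheme):
    tree = tree_of("((Q,(A1,B1)90)85,(H1,F1),A2);", scheme)
    rec = curate_gene("Q", make_table(
        [("Q", "s", 300.0, 1e-40, 0.9, "Homo")], scheme), tree)
    assert rec.status is Status.ACCEPTED
    assert rec.donor_class is DonorClass.EITHER


def test_donor_class_pattern_route(scheme):
    table = make_table([("q", "s", 300.0, 1e-40, 0.9, "Escherichia")], scheme)
    rec = curate_gene("q", table, None)
    assert rec.status is Status.ACCEPTED
    assert rec.phyletic_pattern is PhyleticPattern.PROK_ONLY
    assert rec.donor_class is DonorClass.BACTERIA


def test_donor_margin_rule_for_mixed_pattern(scheme):
    near = make_table(
        [("q", "a", 300.0, 1e-40, 0.9, "Ostreococcus"),
         ("q", "b", 290.0, 1e-39, 0.9, "Escherichia")], scheme)
    far = make_table(
        [("q", "a", 300.0, 1e-40, 0.9, "Ostreococcus"),
         ("q", "b", 150.0, 1e-20, 0.9, "Escherichia")], scheme)
    assert curate_gene("q", near, None).donor_class is DonorClass.EITHER
    assert curate_gene("q", far, None).donor_class is DonorClass.ALGA


def test_classify_donor_requires_accepted():
    rec = CurationRecord(gene_id="g", status=Status.REJECTED)
    with pytest.raises(ValueError, match="ACCEPTED"):
        classify_donor(rec)


def test_gene_without_tree_and_broad_pattern_is_no_call(scheme):
    table = make_table(
        [("q", "a", 300.0, 1e-40, 0.9, "Ostreococcus"),
         ("q", "b", 250.0, 1e-30, 0.9, "Homo")], scheme)
    assert curate_gene("q", table, None).status is Status.NO_CALL


# ---------------------------------------------------------------------------
# event collapsing

def accepted_record(gene, donor=DonorClass.BACTERIA):
    return CurationRecord(gene_id=gene, status=Status.ACCEPTED, donor_class=donor)


def test_duplicated_transfer_collapses_to_one_event(scheme):
    tree = parse_tree("((Q1,Q2)88,B1,A1);", scheme, "Q1", taxon_of=TAXON_OF)
    records = [accepted_record("Q1"), accepted_record("Q2")]
    clusters, errors = collapse_events(records, {"fam": tree},
                                       {"Q1": "fam", "Q2": "fam"})
    assert not errors
    assert len(clusters) == 1
    assert clusters[0].genes == ("Q1", "Q2")
    assert records[0].event_id == records[1].event_id


def test_focal_leaves_split_by_donors_are_separate_events(scheme):
    tree = parse_tree("((Q1,B1),(Q2,B2));", scheme, "Q1", taxon_of=TAXON_OF)
    records = [accepted_record("Q1"), accepted_record("Q2")]
    clusters, _ = collapse_events(records, {"fam": tree}, {"Q1": "fam", "Q2": "fam"})
    assert len(clusters) == 2


def test_second_species_leaf_does_not_split_an_event(scheme):
    tree = parse_tree("(((Q1,SR)90,Q2)88,B1,A1);", scheme, "Q1", taxon_of=TAXON_OF)
    records = [accepted_record("Q1"), accepted_record("Q2")]
    clusters, _ = collapse_events(records, {"fam": tree}, {"Q1": "fam", "Q2": "fam"})
    assert len(clusters) == 1


def test_singleton_families_each_one_event(scheme):
    records = [accepted_record(g) for g in ("g1", "g2", "g3")]
    clusters, errors = collapse_events(records, {}, {})
    assert not errors and len(clusters) == 3


def test_event_count_never_exceeds_accepted_count(clean_bundle):
    from hgtscreen.pipeline import run_pipeline

    result = run_pipeline(clean_bundle)
    assert len(result.events) <= len(result.accepted())


def test_accepted_gene_missing_from_tree_is_error_record(scheme):
    tree = parse_tree("((Q1,B1),(A1,H1));", scheme, "Q1", taxon_of=TAXON_OF)
    records = [accepted_record("Q1"), accepted_record("Q9")]
    clusters, errors = collapse_events(records, {"fam": tree},
                                       {"Q1": "fam", "Q9": "fam"})
    assert any("Q9" in e[0] for e in errors)
    assert len(clusters) == 2  # the missing gene falls back to a singleton


def test_collapse_invariant_under_rerooting(scheme):
    rotations = [
        "((Q1,Q2)88,B1,A1);",
        "(B1,(Q1,Q2)88,A1);",
        "(A1,B1,(Q2,Q1)88);",
        "((B1,A1),(Q1,Q2)88);",
    ]
    counts = set()
    for newick in rotations:
        tree = parse_tree(newick, scheme, "Q1", taxon_of=TAXON_OF)
        records = [accepted_record("Q1"), accepted_record("Q2")]
        clusters, _ = collapse_events(records, {"fam": tree},
                                      {"Q1": "fam", "Q2": "fam"})
        counts.add(len(clusters))
    assert counts == {1}


def test_mixed_member_donors_give_either_event(scheme):
    tree = parse_tree("((Q1,Q2)88,B1,A1);", scheme, "Q1", taxon_of=TAXON_OF)
    records = [accepted_record("Q1", DonorClass.ALGA),
               accepted_record("Q2", DonorClass.BACTERIA)]
    clusters, _ = collapse_events(records, {"fam": tree}, {"Q1": "fam", "Q2": "fam"})
    assert clusters[0].donor_class is DonorClass.EITHER


# ---------------------------------------------------------------------------
# homolog sharing

def test_homolog_sharing_threshold_boundary(scheme):
    rows = [
        ("g1", "sr1", 500.0, 1e-50, 0.9, "Salpingoeca"),
        ("g2", "sr2", 300.0, 1e-30, 0.9, "Salpingoeca"),
        ("g3", "sr3", 400.0, 1e-40, 0.9, "Salpingoeca"),
    ]
    hits = make_table(rows, scheme)
    flags = homolog_sharing(["g1", "g2", "g3", "g4"], hits, evalue_max=1e-40)
    assert flags == {"g1": True, "g2": False, "g3": True, "g4": False}


def test_tightening_share_cutoff_never_gains_shared(scheme):
    rows = [("g%d" % i, "s", 100.0, 10.0 ** (-10 * i), 0.9, "Salpingoeca")
            for i in range(1, 8)]
    hits = make_table(rows, scheme)
    genes = [r[0] for r in rows]
    previous = None
    for cutoff in (1e-20, 1e-40, 1e-60):
        shared = {g for g, f in homolog_sharing(genes, hits, cutoff).items() if f}
        if previous is not None:
            assert shared <= previous
        previous = shared


# ---------------------------------------------------------------------------
# consensus accounting

def fixture_records():
    ledger = make_paper_fixture()
    records = []
    for row in ledger.itertuples(index=False):
        records.append(
            CurationRecord(
                gene_id=row.gene_id,
                status=Status.ACCEPTED,
                detector_flags={
                    "alieng": row.det_alieng,
                    "darkhorse": row.det_darkhorse,
                    "phylogenie": row.det_phylogenie,
                },
            )
        )
    return ledger, records


def test_consensus_accounting_on_fixture():
    ledger, records = fixture_records()
    verdicts = make_paper_verdicts(ledger)
    summary = consensus_accounting(verdicts, records)
    assert summary.accepted_total == 405
    assert summary.union_accepted == 388
    assert summary.missed_by_all == 17
    per = summary.per_detector.set_index("detector")
    assert per.loc["alieng", "predicted_accepted"] == 358
    assert per.loc["darkhorse", "predicted_accepted"] == 345
    assert per.loc["phylogenie", "predicted_accepted"] == 204
    assert per.loc["alieng", "positive_rate"] == pytest.approx(358 / 833)


def test_detector_predicting_nothing_has_na_positive_rate():
    verdicts = DetectorVerdicts(["g1", "g2"])
    verdicts.add_detector("mute", [], run_on=["g1", "g2"])
    records = [accepted_record("g1")]
    summary = consensus_accounting(verdicts, records)
    assert pd.isna(summary.per_detector.loc[0, "positive_rate"])


def test_detector_predicting_all_accepted_has_zero_fnr():
    verdicts = DetectorVerdicts(["g1", "g2"])
    verdicts.add_detector("sharp", ["g1", "g2"], run_on=["g1", "g2"])
    records = [accepted_record("g1"), accepted_record("g2")]
    summary = consensus_accounting(verdicts, records)
    assert summary.per_detector.loc[0, "false_negative_rate"] == 0.0


# ---------------------------------------------------------------------------
# contamination helper and ledger round trip

def test_scaffold_contamination_heuristic():
    order = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d", "e"],
            "scaffold": ["s1", "s1", "s1", "s2", "s2"],
            "position": [1, 2, 3, 1, 2],
        }
    )
    kin_affiliated = {"a", "c"}
    flags = flag_scaffold_contamination(order, kin_affiliated, ["b", "d", "e"])
    assert flags["b"] is False  # both neighbors kin-affiliated
    assert flags["d"] is True and flags["e"] is True


def test_ledger_round_trip(tmp_path, scheme):
    table = make_table([("q", "s", 300.0, 1e-40, 0.9, "Escherichia")], scheme)
    rec = curate_gene("q", table, None, detector_flags={"alien_index": "predicted"})
    path = tmp_path / "ledger.tsv"
    write_ledger([rec], path)
    back = read_ledger(path)
    assert back.loc[0, "gene_id"] == "q"
    assert back.loc[0, "status"] == "ACCEPTED"
    assert back.loc[0, "donor_class"] == "BACTERIA"
    assert back.loc[0, "det_alien_index"] == "predicted"
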