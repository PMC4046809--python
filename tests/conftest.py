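from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from hgtscreen.blast_tab import HitTable, table_from_frame
from hgtscreen.synthetic_data import SimulationConfig, simulate
from hgtscreen.taxonomy import TaxonomyScheme, default_scheme

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

HIT_COLUMNS = [
    "query_id", "subject_id", "bitscore", "evalue", "coverage",
    "subject_taxon", "subject_annotation",
]


def make_table(rows, scheme: TaxonomyScheme) -> HitTable:
    """Build a HitTable from (q, s, bits, evalue, cov, taxon[, annotation]) tuples."""
    full = [tuple(r) + ("",) * (7 - len(r)) for r in rows]
    return table_from_frame(pd.DataFrame(full, columns=HIT_COLUMNS), scheme)


@pytest.fixture(scope="session")
def scheme() -> TaxonomyScheme:
    return default_scheme()


@pytest.fixture(scope="session")
def clean_bundle():
    """Small noise-free simulation shared by read-only tests."""
    return simulate(SimulationConfig(n_genes=80, hgt_fraction=0.25, noise_sd=0.0, seed=7))
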