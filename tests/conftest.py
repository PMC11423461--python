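"""Shared fixtures: one synthetic dataset per scope, plus small builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lysompn import synthio


@pytest.fixture(scope="session")
def sim():
    return synthio.SimConfig(seed=0)


@pytest.fixture(scope="session")
def cohort_data(sim):
    return synthio.simulate_cohort(sim)


@pytest.fixture(scope="session")
def bulk_data(sim):
    return synthio.simulate_bulk_counts(sim)


@pytest.fixture(scope="session")
def sc_data(sim):
    return synthio.simulate_sc_dataset(sim)


@pytest.fixture(scope="session")
def lr_db():
    return synthio.make_lr_database()


def make_variant_row(**overrides):
    """A retained, non-qualifying variant by default."""
    row = {
        "subject_id": "S1",
        "gene": "GBA",
        "chrom": "1",
        "pos": 100,
        "ref": "A",
        "alt": "T",
        "consequence": "missense_variant",
        "is_indel": False,
        "clinvar_significance": "",
        "gnomad_af": 0.001,
        "depth": 50,
        "alt_reads": 20,
    }
    row.update(overrides)
    return row


@pytest.fixture
def variant_row():
    return make_variant_row


def toy_counts(seed=0, n_genes=50, n_samples=8):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(100, size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{i}" for i in range(n_samples)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "ld_status": ["carrier"] * (n_samples // 2)
            + ["noncarrier"] * (n_samples - n_samples // 2),
            "subtype": ["PMF", "PV"] * (n_samples // 2),
        }
    )
    return counts, meta
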