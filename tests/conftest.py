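"""Shared fixtures: small hand-built tables and the synthetic standard table."""

import datetime

import numpy as np
import pandas as pd
import pytest

from rarecohort import OtuTable, synth


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 samples x 4 taxa with dates and taxonomy, hand-checkable."""
    counts = pd.DataFrame(
        [[5, 0, 1, 4], [3, 2, 1, 5], [2, 1, 0, 7]],
        index=["S1", "S2", "S3"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    dates = {
        "S1": datetime.date(2005, 5, 1),
        "S2": datetime.date(2005, 7, 1),
        "S3": datetime.date(2005, 9, 1),
    }
    taxonomy = {
        "otuA": ("Bacteria", "Proteobacteria", "Betaproteobacteria",
                 "Burkholderiales", "Comamonadaceae"),
        "otuB": ("Bacteria", "Bacteroidetes"),
        "otuC": ("Bacteria", "Proteobacteria"),
        "otuD": ("Bacteria", "Nitrospirae", "Nitrospira", "Nitrospirales",
                 "Nitrospiraceae"),
    }
    return OtuTable(counts, sample_dates=dates, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def standard_table() -> OtuTable:
    """The frozen synthetic community: 12 dated samples x 300 taxa."""
    return synth.example_table()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20110)


def random_table(rng, n_samples=6, n_taxa=30, lam=8.0) -> OtuTable:
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_samples, n_taxa)),
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"T{j}" for j in range(n_taxa)],
    )
    return OtuTable(counts)
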