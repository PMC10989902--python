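"""Shared fixtures: tiny hand-built trees and count tables."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from soilassembly import CountTable


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def table_from_array(counts, samples=None, taxa=None, kingdom="bacteria"):
    counts = np.asarray(counts)
    samples = samples or [f"S{i + 1}" for i in range(counts.shape[0])]
    taxa = taxa or [f"T{i + 1}" for i in range(counts.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CountTable(pd.DataFrame(counts, index=samples, columns=taxa), kingdom)


@pytest.fixture
def caterpillar4():
    """Four-tip caterpillar with unit branch lengths."""
    return tree_from_newick("(((A:1,B:1):1,C:1):1,D:1);")


@pytest.fixture
def three_taxon_tree():
    """((A,(B,C)) with unit branch lengths: d(A,B)=d(A,C)=3, d(B,C)=2."""
    return tree_from_newick("(A:1,(B:1,C:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
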