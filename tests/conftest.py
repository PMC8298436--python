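"""Shared synthetic fixtures (all generated at test time; no data files)."""

import numpy as np
import pandas as pd
import pytest

import mprastat as m


@pytest.fixture(scope="session")
def small_design():
    """20 SNPs x 10 barcodes/allele + 110 basal barcodes."""
    d = m.generate_library(n_snps=20, seed=101)
    d.validate()
    return d


@pytest.fixture(scope="session")
def null_expr(small_design):
    """Filtered expression from an all-null simulation (beta = 0)."""
    truth = m.make_truth(small_design)
    counts = m.simulate_counts(small_design, truth, seed=102)
    expr, _ = m.filter_table(m.compute_expression(counts), small_design)
    return expr


@pytest.fixture(scope="session")
def effect_design_truth():
    """Design with planted allelic, drug and interaction effects."""
    d = m.generate_library(n_snps=10, seed=201)
    truth = m.make_truth(
        d,
        beta_allele={"snp00001": 1.0, "snp00002": 0.5},
        beta_drug=0.2,
        beta_inter={"snp00003": 0.6, "snp00004": 1.0},
        sigma_rep=0.05,
    )
    return d, truth


@pytest.fixture(scope="session")
def effect_expr(effect_design_truth):
    d, truth = effect_design_truth
    counts = m.simulate_counts(d, truth, seed=202)
    expr, _ = m.filter_table(m.compute_expression(counts), d)
    return expr


def tiny_counts():
    """Hand-written count tables for exact-value quantification tests."""
    barcodes = ["bc1", "bc2", "bc3", "bc4"]
    dna = pd.Series([100, 100, 200, 100], index=barcodes)
    rna = pd.DataFrame(
        {"vehicle_rep1": [100, 200, 200, 100],
         "vehicle_rep2": [50, 100, 100, 50]},
        index=barcodes)
    meta = pd.DataFrame(
        {"condition": ["vehicle", "vehicle"], "replicate": [1, 2]},
        index=pd.Index(["vehicle_rep1", "vehicle_rep2"], name="sample_id"))
    return m.CountTables(dna=dna, rna=rna, sample_meta=meta)
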