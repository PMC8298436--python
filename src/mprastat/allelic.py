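"""Per-SNP allelic activity tests with basal-barcode empirical nulls.

The primary statistic is a two-sample t test on per-sample element means
(alternative vs reference allele).  Because barcode identity itself drives
expression variability, parametric p-values are complemented by an empirical
p-value (Pemp): random disjoint subsets of basal (promoter-only) barcodes are
treated as pseudo-alleles and pushed through the identical statistic, yielding
a null distribution that embodies barcode-driven variability.  Normality is
checked per SNP (Shapiro-Wilk on per-allele-centered values) with a
Mann-Whitney U fallback recorded — never used for exclusion — and BH FDR is
available for single-condition analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .quantify import ElementExpression, ExpressionTable, basal_matrix, element_means
from .synthetic import LibraryDesign

N_NULL_SIMS = 20_000
PEMP_SIGNIFICANCE = 0.05
SHAPIRO_ALPHA = 0.05


@dataclass
class BasalNull:
    """Null statistic vector from randomized basal-only pseudo-allelic tests."""

    statistic: str            # "t" or "lmm_F"
    stats: np.ndarray
    n_sims: int
    subset_size: int
    seed: int

    def __post_init__(self):
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.stats) != self.n_sims:
            raise InsufficientDataError("null vector length != n_sims")
        if not np.isfinite(self.stats).all():
            raise InsufficientDataError("null statistics must all be finite")


def _nan_t(a: np.ndarray, b: np.ndarray, axis: int = -1,
           variant: str = "welch") -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware two-sample t statistic and df along ``axis`` (a minus b)."""
    n1 = np.sum(~np.isnan(a), axis=axis)
    n2 = np.sum(~np.isnan(b), axis=axis)
    m1, m2 = np.nanmean(a, axis=axis), np.nanmean(b, axis=axis)
    v1 = np.nanvar(a, axis=axis, ddof=1)
    v2 = np.nanvar(b, axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "welch":
            se2 = v1 / n1 + v2 / n2
            df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
        elif variant == "pooled":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1 / n1 + 1 / n2)
            df = n1 + n2 - 2
        else:
            raise ValueError(f"unknown t-test variant {variant!r}")
        t = (m1 - m2) / np.sqrt(se2)
    return t, df


def composite_log2fc(elem: ElementExpression, snp_id: str) -> float:
    """Mean over samples of (alt - ref) element expression, paired per sample."""
    try:
        alt = elem.allele_values(snp_id, "alt")
        ref = elem.allele_values(snp_id, "ref")
    except KeyError:
        raise InsufficientDataError(f"{snp_id}: allele missing from element table")
    paired = pd.concat({"alt": alt, "ref": ref}, axis=1).dropna()
    if paired.empty:
        raise InsufficientDataError(f"{snp_id}: no sample with both alleles measured")
    return float((paired["alt"] - paired["ref"]).mean())


def allelic_ttest(elem: ElementExpression, snp_id: str,
                  variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t test of alt vs ref per-sample element values."""
    alt = elem.allele_values(snp_id, "alt").dropna().to_numpy()
    ref = elem.allele_values(snp_id, "ref").dropna().to_numpy()
    if len(alt) < 2 or len(ref) < 2:
        raise InsufficientDataError(f"{snp_id}: need >=2 samples per allele")
    if np.var(alt) == 0 and np.var(ref) == 0:
        if np.mean(alt) == np.mean(ref):
            return 0.0, 1.0  # degenerate: identical constant groups
        return np.inf * np.sign(np.mean(alt) - np.mean(ref)), 0.0
    res = stats.ttest_ind(alt, ref, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def build_basal_null(expr: ExpressionTable, design: LibraryDesign,
                     statistic: str = "t", subset_size: int | None = None,
                     n_sims: int = N_NULL_SIMS, seed: int = 0,
                     samples: list[str] | None = None,
                     variant: str = "welch") -> BasalNull:
    """Null statistics from random disjoint basal pseudo-alleles.

    Each simulation draws two disjoint subsets of basal barcodes (size
    defaulting to the design's barcodes-per-allele), averages them to
    per-sample pseudo-element means, and computes the statistic exactly as for
    a real SNP.  Deterministic given ``seed``.
    """
    if statistic == "lmm_F":
        from .interaction import basal_F_null
        nulls = basal_F_null(expr, design, n_sims=n_sims, seed=seed,
                             subset_size=subset_size)
        return nulls["allele"]
    if statistic != "t":
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_sims < 1:
        raise InsufficientDataError("n_sims must be >= 1")
    if subset_size is None:
        subset_size = design.barcodes_per_allele
    V = basal_matrix(expr, design)
    if samples is not None:
        V = V.loc[samples]
    arr = V.to_numpy().T                       # (n_basal, n_samples)
    n_basal = arr.shape[0]
    if 2 * subset_size > n_basal:
        raise InsufficientDataError(
            f"need >= {2 * subset_size} basal barcodes, have {n_basal}")

    rng = np.random.default_rng(seed)
    order = rng.random((n_sims, n_basal)).argsort(axis=1)
    idx1 = order[:, :subset_size]
    idx2 = order[:, subset_size:2 * subset_size]
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(arr[idx1, :], axis=1)  # (n_sims, n_samples) pseudo-elements
        m2 = np.nanmean(arr[idx2, :], axis=1)
    t, _ = _nan_t(m1, m2, axis=1, variant=variant)
    t = t[np.isfinite(t)]
    return BasalNull(statistic="t", stats=t, n_sims=len(t),
                     subset_size=subset_size, seed=seed)


def empirical_p(obs_stat: float, null: BasalNull,
                sidedness: str = "two_sided") -> float:
    """Add-one empirical p: (1 + #{null at least as extreme}) / (1 + n_sims)."""
    stats_ = null.stats
    if sidedness == "two_sided":
        k = int(np.sum(np.abs(stats_) >= abs(obs_stat)))
    elif sidedness == "one_sided":
        k = int(np.sum(stats_ >= obs_stat))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return (1 + k) / (1 + null.n_sims)


def empirical_p_vector(obs: np.ndarray, null: BasalNull,
                       sidedness: str = "two_sided") -> np.ndarray:
    """Vectorized :func:`empirical_p` over many observed statistics."""
    ns = np.sort(np.abs(null.stats) if sidedness == "two_sided" else null.stats)
    o = np.abs(obs) if sidedness == "two_sided" else np.asarray(obs, float)
    k = len(ns) - np.searchsorted(ns, o, side="left")
    return (1 + k) / (1 + null.n_sims)


def normality_gate(alt_values: np.ndarray, ref_values: np.ndarray,
                   alpha: float = SHAPIRO_ALPHA) -> tuple[float, bool]:
    """Shapiro-Wilk on pooled per-allele-centered element values.

    Returns ``(shapiro_p, needs_fallback)``; constant input is flagged with a
    NaN p and no fallback (no distributional evidence either way).
    """
    alt = np.asarray(alt_values, float)
    ref = np.asarray(ref_values, float)
    alt, ref = alt[~np.isnan(alt)], ref[~np.isnan(ref)]
    pooled = np.concatenate([alt - alt.mean(), ref - ref.mean()])
    if len(pooled) < 3:
        raise InsufficientDataError("Shapiro-Wilk needs >= 3 values")
    if np.ptp(pooled) == 0:
        return float("nan"), False
    p = float(stats.shapiro(pooled).pvalue)
    return p, p <= alpha


def mwu_fallback(alt_values: np.ndarray, ref_values: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p (verification only, never exclusionary)."""
    alt = np.asarray(alt_values, float)
    ref = np.asarray(ref_values, float)
    alt, ref = alt[~np.isnan(alt)], ref[~np.isnan(ref)]
    if np.array_equal(np.sort(alt), np.sort(ref)):
        return 1.0
    return float(stats.mannwhitneyu(alt, ref, alternative="two-sided").pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def power_analysis(barcode_sd: float = 0.12, n_replicates: int = 6,
                   barcodes_per_allele: int = 10, effect_log2fc: float = 1.1,
                   alpha: float = 0.1, n_tests_bonferroni: int = 1013,
                   n_sims: int = 2000, seed: int = 0,
                   variant: str = "welch") -> float:
    """Monte-Carlo power of the allelic t-test pipeline.

    Simulates barcode-level log2 noise, averages barcodes to per-replicate
    element means, and t-tests alt vs ref at the Bonferroni-corrected level
    ``alpha / n_tests_bonferroni``.  Returns the fraction of simulations
    reaching significance.
    """
    for v in (barcode_sd, n_replicates, barcodes_per_allele, alpha,
              n_tests_bonferroni, n_sims):
        if v <= 0:
            raise ValueError("all power-analysis parameters must be positive")
    rng = np.random.default_rng(seed)
    shape = (n_sims, n_replicates, barcodes_per_allele)
    ref = rng.normal(0.0, barcode_sd, size=shape).mean(axis=2)
    alt = rng.normal(effect_log2fc, barcode_sd, size=shape).mean(axis=2)
    t, df = _nan_t(alt, ref, axis=1, variant=variant)
    p = 2 * stats.t.sf(np.abs(t), df)
    return float(np.mean(p < alpha / n_tests_bonferroni))


def run_allelic_analysis(expr: ExpressionTable, design: LibraryDesign,
                         samples: list[str] | None = None,
                         n_sims: int = N_NULL_SIMS, seed: int = 0,
                         variant: str = "welch",
                         null: BasalNull | None = None,
                         pemp_threshold: float = PEMP_SIGNIFICANCE) -> pd.DataFrame:
    """Full per-SNP allelic analysis over the given samples.

    Returns one row per testable SNP with the composite log2 fold change
    (alt - ref), t statistic and parametric p, empirical p from the shared
    basal null, BH q over the parametric p-values (used by single-condition
    FDR analyses), Shapiro-Wilk p, Mann-Whitney fallback p where triggered,
    and the effect direction.
    """
    sub = expr.subset_samples(samples) if samples is not None else expr
    elem = element_means(sub, design)
    if null is None:
        null = build_basal_null(sub, design, statistic="t", n_sims=n_sims,
                                seed=seed, variant=variant)
    rows = []
    for snp_id in design.snp_ids:
        try:
            fc = composite_log2fc(elem, snp_id)
            t, p = allelic_ttest(elem, snp_id, variant=variant)
        except InsufficientDataError:
            continue
        alt = elem.allele_values(snp_id, "alt").to_numpy()
        ref = elem.allele_values(snp_id, "ref").to_numpy()
        try:
            shapiro_p, needs_fb = normality_gate(alt, ref)
        except InsufficientDataError:
            shapiro_p, needs_fb = float("nan"), False
        rows.append({
            "snp_id": snp_id, "composite_log2fc": fc, "t_stat": t, "t_pvalue": p,
            "shapiro_p": shapiro_p, "needs_fallback": needs_fb,
            "direction": int(np.sign(fc)),
            "n_alt": int(np.sum(~np.isnan(alt))), "n_ref": int(np.sum(~np.isnan(ref))),
        })
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_emp"] = empirical_p_vector(res["t_stat"].to_numpy(), null)
    res["fdr_q"] = bh_fdr(res["t_pvalue"].to_numpy())
    # MWU verification for significant SNPs failing the normality gate
    mwu = np.full(len(res), np.nan)
    for i, row in res.iterrows():
        if row["needs_fallback"] and row["p_emp"] < pemp_threshold:
            alt = elem.allele_values(row["snp_id"], "alt")
            ref = elem.allele_values(row["snp_id"], "ref")
            mwu[i] = mwu_fallback(alt.to_numpy(), ref.to_numpy())
    res["mwu_p"] = mwu
    return res
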