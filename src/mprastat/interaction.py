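"""Allele x drug linear mixed models with basal-barcode empirical F nulls.

Per SNP, barcode-level expression is modelled as

    expression ~ allele + drug + allele:drug + (1 | replicate)

with allele coded ref=0/alt=1, drug coded vehicle=0/ATRA=1, and a random
intercept for the replicate (well-pair index shared across the two conditions,
since paired wells are transfected and processed together).  Wald F statistics
per fixed coefficient are referenced to empirical nulls built from randomized
basal-only pseudo-allelic fits of the identical model, and interactions are
validated by a likelihood-ratio test of the ML interaction model against the
ML additive model (chi-square, 1 df).

The fitter exploits the single-random-intercept structure: the profiled
(RE)ML criterion is a one-dimensional function of the variance ratio
``lambda = sigma_rep^2 / sigma_resid^2``, evaluated in O(groups x p^2) from
sufficient statistics via per-group Woodbury identities.  This makes the
20,000-fit null distributions tractable; the fitter is validated against
statsmodels' MixedLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .allelic import BasalNull, bh_fdr, empirical_p_vector, run_allelic_analysis
from .errors import InsufficientDataError
from .quantify import ExpressionTable, basal_matrix
from .synthetic import LibraryDesign

N_NULL_SIMS = 20_000
MIN_MEASUREMENT_FRACTION = 0.40
_LOG_LAMBDA_GRID = (-10.0, -6.0, -2.0, 0.0, 2.0, 6.0)
_LOG_LAMBDA_BOUNDS = (-14.0, 10.0)


@dataclass
class Thresholds:
    """Significance thresholds for SNP effect classification."""

    inter_pemp: float = 0.05
    allele_pemp: float = 0.05
    vehicle_pemp: float = 0.10
    atra_fdr: float = 0.10


@dataclass
class LMMResult:
    """Mixed-model output for one SNP (empirical p's filled in later)."""

    snp_id: str
    beta_allele: float
    beta_drug: float
    beta_inter: float
    se_allele: float
    se_drug: float
    se_inter: float
    F_allele: float
    F_drug: float
    F_inter: float
    sigma_rep: float
    sigma_resid: float
    n_measurements: int
    loglik: float
    converged: bool
    p_emp_allele: float | None = None
    p_emp_drug: float | None = None
    p_emp_inter: float | None = None
    lrt_p: float | None = None
    category: str | None = None


# ---------------------------------------------------------------------------
# profiled single-random-intercept (RE)ML fitter
# ---------------------------------------------------------------------------

@dataclass
class _SuffStats:
    """Sufficient statistics for the profiled variance-ratio criterion."""

    XtX: np.ndarray   # (p, p)
    Xty: np.ndarray   # (p,)
    yty: float
    Sx: np.ndarray    # (G, p) per-group column sums of X
    Sy: np.ndarray    # (G,)   per-group sums of y
    ng: np.ndarray    # (G,)
    n: int

    @classmethod
    def build(cls, y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> "_SuffStats":
        G = int(groups.max()) + 1
        Sx = np.zeros((G, X.shape[1]))
        Sy = np.zeros(G)
        np.add.at(Sx, groups, X)
        np.add.at(Sy, groups, y)
        ng = np.bincount(groups, minlength=G).astype(float)
        return cls(XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y),
                   Sx=Sx, Sy=Sy, ng=ng, n=len(y))


def _gls_pieces(ss: _SuffStats, lam: float):
    """GLS normal equations and weighted RSS at variance ratio ``lam``."""
    c = lam / (1.0 + lam * ss.ng)                   # per-group shrinkage
    A = ss.XtX - ss.Sx.T @ (c[:, None] * ss.Sx)
    b = ss.Xty - ss.Sx.T @ (c * ss.Sy)
    q = ss.yty - float(c @ (ss.Sy ** 2))
    beta = np.linalg.solve(A, b)
    rss = max(q - float(beta @ b), 1e-300)
    logdetV = float(np.sum(np.log1p(lam * ss.ng)))
    return A, beta, rss, logdetV


def _objective(ss: _SuffStats, lam: float, method: str) -> float:
    A, _, rss, logdetV = _gls_pieces(ss, lam)
    p = ss.XtX.shape[0]
    if method == "reml":
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return logdetV + logdetA + (ss.n - p) * np.log(rss)
    return logdetV + ss.n * np.log(rss)


def _profile_fit(ss: _SuffStats, method: str = "reml"):
    """Minimize the profiled criterion over lambda >= 0 (grid + bounded search)."""
    objs = {0.0: _objective(ss, 0.0, method)}
    best_theta, best_val = None, np.inf
    for theta in _LOG_LAMBDA_GRID:
        v = _objective(ss, np.exp(theta), method)
        objs[np.exp(theta)] = v
        if v < best_val:
            best_theta, best_val = theta, v
    converged = True
    if best_val < objs[0.0]:
        lo = max(best_theta - 4.0, _LOG_LAMBDA_BOUNDS[0])
        hi = min(best_theta + 4.0, _LOG_LAMBDA_BOUNDS[1])
        res = optimize.minimize_scalar(
            lambda th: _objective(ss, np.exp(th), method),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6, "maxiter": 200})
        converged = bool(res.success)
        lam = float(np.exp(res.x)) if res.fun <= min(best_val, objs[0.0]) else 0.0
        if objs[0.0] <= res.fun:
            lam = 0.0
    else:
        lam = 0.0

    A, beta, rss, logdetV = _gls_pieces(ss, lam)
    p = ss.XtX.shape[0]
    dof = ss.n - p if method == "reml" else ss.n
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    # actual ML log-likelihood (needed for likelihood-ratio tests)
    sigma2_ml = rss / ss.n
    loglik_ml = -0.5 * (ss.n * np.log(2 * np.pi * sigma2_ml) + logdetV + ss.n)
    return {
        "beta": beta, "se": se, "lam": lam,
        "sigma_resid": float(np.sqrt(sigma2)),
        "sigma_rep": float(np.sqrt(lam * sigma2)),
        "loglik_ml": float(loglik_ml), "converged": converged,
    }


# ---------------------------------------------------------------------------
# per-SNP model fitting
# ---------------------------------------------------------------------------

def _snp_long_data(expr: ExpressionTable, design: LibraryDesign, snp_id: str,
                   replicate_coding: str = "pair"):
    """Unmasked barcode-level rows for one SNP: y, design matrix, group codes."""
    bm = design.barcode_map
    bcs = bm.loc[bm["snp_id"] == snp_id]
    if bcs.empty:
        raise InsufficientDataError(f"unknown SNP {snp_id!r}")
    masked = expr.masked_values()[list(bcs["barcode"])]
    meta = expr.sample_meta
    is_alt = (bcs["allele"] == "alt").to_numpy()

    drug = (meta["condition"] == "ATRA").to_numpy(dtype=float)
    if replicate_coding == "pair":
        rep = meta["replicate"].to_numpy()
    elif replicate_coding == "well":
        rep = pd.factorize(list(zip(meta["condition"], meta["replicate"])))[0] + 1
    else:
        raise ValueError(f"unknown replicate_coding {replicate_coding!r}")
    rep_codes = pd.factorize(rep)[0]

    vals = masked.to_numpy()                      # (n_samples, n_barcodes)
    n_s, n_b = vals.shape
    y = vals.T.ravel()                            # barcode-major
    allele = np.repeat(is_alt.astype(float), n_s)
    drug_col = np.tile(drug, n_b)
    groups = np.tile(rep_codes, n_b)
    valid = ~np.isnan(y)
    X = np.column_stack([np.ones(len(y)), allele, drug_col, allele * drug_col])
    n_possible = n_b * n_s
    return y[valid], X[valid], groups[valid], n_possible


def fit_lmm(expr: ExpressionTable, design: LibraryDesign, snp_id: str,
            min_fraction: float = MIN_MEASUREMENT_FRACTION,
            method: str = "reml", replicate_coding: str = "pair") -> LMMResult:
    """Fit the allele x drug mixed model for one SNP.

    Requires at least ``min_fraction`` of the possible (barcode, sample)
    measurements (40% of 240 = 96 under the default two-condition design);
    below that the SNP is rejected.  Coefficient reporting uses REML by
    default; Wald F per coefficient is the squared coefficient z-score.
    """
    y, X, groups, n_possible = _snp_long_data(expr, design, snp_id, replicate_coding)
    min_n = int(np.ceil(min_fraction * n_possible))
    if len(y) < min_n:
        raise InsufficientDataError(
            f"{snp_id}: {len(y)} of {n_possible} measurements "
            f"(< required {min_n})")
    if np.ptp(X[:, 2]) == 0:  # single condition: no drug/interaction columns
        raise InsufficientDataError(
            f"{snp_id}: interaction model needs both conditions")
    ss = _SuffStats.build(y, X, groups)
    fit = _profile_fit(ss, method=method)
    beta, se = fit["beta"], fit["se"]
    F = (beta / se) ** 2
    return LMMResult(
        snp_id=snp_id,
        beta_allele=float(beta[1]), beta_drug=float(beta[2]), beta_inter=float(beta[3]),
        se_allele=float(se[1]), se_drug=float(se[2]), se_inter=float(se[3]),
        F_allele=float(F[1]), F_drug=float(F[2]), F_inter=float(F[3]),
        sigma_rep=fit["sigma_rep"], sigma_resid=fit["sigma_resid"],
        n_measurements=len(y), loglik=fit["loglik_ml"], converged=fit["converged"])


def lrt_interaction(expr: ExpressionTable, design: LibraryDesign, snp_id: str,
                    min_fraction: float = MIN_MEASUREMENT_FRACTION,
                    replicate_coding: str = "pair") -> float:
    """Likelihood-ratio p for the interaction term (ML full vs ML additive)."""
    y, X, groups, n_possible = _snp_long_data(expr, design, snp_id, replicate_coding)
    if len(y) < int(np.ceil(min_fraction * n_possible)):
        raise InsufficientDataError(f"{snp_id}: below measurement threshold")
    if np.ptp(X[:, 3]) == 0:  # interaction column constant -> models identical
        return 1.0
    ss_full = _SuffStats.build(y, X, groups)
    ss_add = _SuffStats.build(y, X[:, :3], groups)
    fit_full = _profile_fit(ss_full, method="ml")
    fit_add = _profile_fit(ss_add, method="ml")
    lr = max(2.0 * (fit_full["loglik_ml"] - fit_add["loglik_ml"]), 0.0)
    return float(stats.chi2.sf(lr, df=1))


# ---------------------------------------------------------------------------
# basal F nulls and empirical p-values
# ---------------------------------------------------------------------------

def basal_F_null(expr: ExpressionTable, design: LibraryDesign,
                 n_sims: int = N_NULL_SIMS, subset_size: int | None = None,
                 seed: int = 0, method: str = "reml",
                 replicate_coding: str = "pair") -> dict[str, BasalNull]:
    """Null F statistics per coefficient from randomized basal-only LMM fits.

    Each simulation draws two disjoint basal-barcode subsets as pseudo-alleles
    (drug labels from the true sample conditions) and fits the identical mixed
    model; returns null vectors keyed 'allele', 'drug', 'inter'.
    """
    if n_sims < 1:
        raise InsufficientDataError("n_sims must be >= 1")
    if subset_size is None:
        subset_size = design.barcodes_per_allele
    V = basal_matrix(expr, design)
    arr = V.to_numpy().T                                    # (n_basal, n_samples)
    n_basal, n_s = arr.shape
    if 2 * subset_size > n_basal:
        raise InsufficientDataError(
            f"need >= {2 * subset_size} basal barcodes, have {n_basal}")

    meta = expr.sample_meta
    drug = (meta["condition"] == "ATRA").to_numpy(dtype=float)
    if np.ptp(drug) == 0:
        raise InsufficientDataError("F null needs both conditions present")
    if replicate_coding == "pair":
        rep = meta["replicate"].to_numpy()
    else:
        rep = pd.factorize(list(zip(meta["condition"], meta["replicate"])))[0] + 1
    rep_codes = pd.factorize(rep)[0]

    n_b = 2 * subset_size
    allele = np.repeat(np.arange(n_b) >= subset_size, n_s).astype(float)
    drug_col = np.tile(drug, n_b)
    X_full = np.column_stack(
        [np.ones(n_b * n_s), allele, drug_col, allele * drug_col])
    groups_full = np.tile(rep_codes, n_b)

    # cache X-side sufficient statistics for the (common) complete-data case
    G = int(groups_full.max()) + 1
    XtX_full = X_full.T @ X_full
    Sx_full = np.zeros((G, 4))
    np.add.at(Sx_full, groups_full, X_full)
    ng_full = np.bincount(groups_full, minlength=G).astype(float)
    onehot = np.zeros((G, n_b * n_s))
    onehot[groups_full, np.arange(n_b * n_s)] = 1.0

    rng = np.random.default_rng(seed)
    Fs = np.empty((n_sims, 3))
    for i in range(n_sims):
        sel = rng.choice(n_basal, size=n_b, replace=False)
        y = arr[sel, :].ravel()
        valid = ~np.isnan(y)
        if valid.all():
            ss = _SuffStats(XtX=XtX_full, Xty=X_full.T @ y, yty=float(y @ y),
                            Sx=Sx_full, Sy=onehot @ y, ng=ng_full, n=len(y))
        else:
            ss = _SuffStats.build(y[valid], X_full[valid], groups_full[valid])
        fit = _profile_fit(ss, method=method)
        Fs[i] = (fit["beta"][1:] / fit["se"][1:]) ** 2

    return {
        name: BasalNull(statistic="lmm_F", stats=Fs[:, j], n_sims=n_sims,
                        subset_size=subset_size, seed=seed)
        for j, name in enumerate(["allele", "drug", "inter"])
    }


def lmm_empirical_p(result: LMMResult, nulls: dict[str, BasalNull]) -> LMMResult:
    """Attach one-sided empirical p-values (F is one-sided by construction)."""
    for coef, F in [("allele", result.F_allele), ("drug", result.F_drug),
                    ("inter", result.F_inter)]:
        null = nulls[coef]
        p = float(empirical_p_vector(np.array([F]), null, sidedness="one_sided")[0])
        setattr(result, f"p_emp_{coef}", p)
    return result


# ---------------------------------------------------------------------------
# classification and diagnostics
# ---------------------------------------------------------------------------

def classify_effects(p_emp_allele: float, p_emp_inter: float,
                     vehicle_pemp: float | None = None,
                     atra_fdr: float | None = None,
                     vehicle_direction: int | None = None,
                     atra_direction: int | None = None,
                     thresholds: Thresholds | None = None) -> str:
    """Assign a SNP to {allele_only, interaction_only, both, none}.

    Interaction is present iff its empirical p clears the threshold.  When the
    allele coefficient is also significant, a "meaningful" main effect further
    requires concordant single-condition evidence: same allelic direction in
    vehicle and ATRA, vehicle Pemp and ATRA FDR below their thresholds.
    """
    th = thresholds or Thresholds()
    inter = p_emp_inter < th.inter_pemp
    allele = p_emp_allele < th.allele_pemp
    if inter and allele:
        if vehicle_pemp is None or atra_fdr is None \
                or vehicle_direction is None or atra_direction is None:
            raise InsufficientDataError(
                "single-condition results required to qualify a main effect "
                "alongside an interaction")
        qualified = (vehicle_pemp < th.vehicle_pemp and atra_fdr < th.atra_fdr
                     and vehicle_direction == atra_direction
                     and vehicle_direction != 0)
        return "both" if qualified else "interaction_only"
    if inter:
        return "interaction_only"
    if allele:
        return "allele_only"
    return "none"


def variance_homogeneity(expr: ExpressionTable) -> pd.DataFrame:
    """Per-condition percentiles of barcode expression SD across replicates.

    Used to check that residual variability is comparable between drug and
    vehicle conditions before pooling them in one mixed model.
    """
    masked = expr.masked_values()
    rows = []
    for cond, meta in expr.sample_meta.groupby("condition"):
        if len(meta) < 2:
            raise InsufficientDataError(
                f"condition {cond!r} needs >= 2 replicates")
        sds = masked.loc[meta.index].std(axis=0, ddof=1).dropna()
        q25, med, q75 = np.percentile(sds, [25, 50, 75])
        rows.append({"condition": cond, "q25_sd": q25, "median_sd": med,
                     "q75_sd": q75, "n_barcodes": len(sds)})
    out = pd.DataFrame(rows).set_index("condition")
    if len(out) == 2:
        a, b = out.index
        for col in ["q25_sd", "median_sd", "q75_sd"]:
            out.loc["abs_difference", col] = abs(out.at[a, col] - out.at[b, col])
    return out


def run_interaction_analysis(expr: ExpressionTable, design: LibraryDesign,
                             n_sims: int = N_NULL_SIMS, seed: int = 0,
                             thresholds: Thresholds | None = None,
                             min_fraction: float = MIN_MEASUREMENT_FRACTION,
                             method: str = "reml",
                             replicate_coding: str = "pair",
                             nulls: dict[str, BasalNull] | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Full second-assay pipeline: LMM, empirical p's, LRT, classification.

    Returns ``(lmm_results, vehicle_single, atra_single, skipped)`` where the
    single-condition tables come from :func:`run_allelic_analysis` on the
    vehicle (Pemp-based) and ATRA (FDR-based) samples, and ``skipped`` maps
    snp_id -> reason for SNPs that failed the measurement filter.
    """
    th = thresholds or Thresholds()
    if nulls is None:
        nulls = basal_F_null(expr, design, n_sims=n_sims, seed=seed,
                             method=method, replicate_coding=replicate_coding)

    vehicle = run_allelic_analysis(
        expr, design, samples=expr.condition_samples("vehicle"),
        n_sims=n_sims, seed=seed + 1)
    atra = run_allelic_analysis(
        expr, design, samples=expr.condition_samples("ATRA"),
        n_sims=n_sims, seed=seed + 2)
    vehicle_ix = vehicle.set_index("snp_id") if not vehicle.empty else vehicle
    atra_ix = atra.set_index("snp_id") if not atra.empty else atra

    rows, skipped = [], {}
    for snp_id in design.snp_ids:
        try:
            res = fit_lmm(expr, design, snp_id, min_fraction=min_fraction,
                          method=method, replicate_coding=replicate_coding)
        except InsufficientDataError as exc:
            skipped[snp_id] = str(exc)
            continue
        res = lmm_empirical_p(res, nulls)
        res.lrt_p = lrt_interaction(expr, design, snp_id,
                                    min_fraction=min_fraction,
                                    replicate_coding=replicate_coding)
        kwargs = {}
        if snp_id in getattr(vehicle_ix, "index", []):
            v = vehicle_ix.loc[snp_id]
            kwargs.update(vehicle_pemp=float(v["p_emp"]),
                          vehicle_direction=int(v["direction"]))
        if snp_id in getattr(atra_ix, "index", []):
            a = atra_ix.loc[snp_id]
            kwargs.update(atra_fdr=float(a["fdr_q"]),
                          atra_direction=int(a["direction"]))
        try:
            res.category = classify_effects(
                res.p_emp_allele, res.p_emp_inter, thresholds=th, **kwargs)
        except InsufficientDataError:
            res.category = "unclassified"
        rows.append(vars(res).copy())

    lmm_df = pd.DataFrame(rows)
    return lmm_df, vehicle, atra, skipped
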