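"""Resampling TF-motif enrichment, motif/expression concordance, ChIP overlap.

For each transcription factor, the number of functional SNPs carrying a motif
perturbation is compared with the counts obtained in random draws of the same
number of SNPs from the full analyzed set (a label permutation), yielding an
add-one empirical enrichment p-value, BH-corrected across TFs.  A concordance
variant asks how often the allele that better matches the motif is also the
allele driving higher reporter expression — the expectation for strictly
activating TFs.  SNP positions can additionally be intersected with ChIP-seq
peak tracks (BED, 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .allelic import bh_fdr
from .errors import InsufficientDataError

N_DRAWS = 10_000


@dataclass
class IntervalSet:
    """A named set of genomic intervals (0-based half-open), e.g. one ChIP track."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"{self.label}: intervals must have start < end")
        self.intervals = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            self._trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"]))

    def overlaps(self, chrom: str, pos0: int) -> bool:
        """Whether 0-based position ``pos0`` falls in any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))


def _hit_matrix(records: pd.DataFrame, analyzed: np.ndarray,
                min_strength: str) -> tuple[np.ndarray, list[str]]:
    """Boolean (n_analyzed, n_tfs) matrix: SNP has a qualifying record for TF."""
    allowed = {"strong"} if min_strength == "strong" else {"strong", "weak"}
    recs = records[records["strength"].isin(allowed)]
    tfs = sorted(recs["tf_name"].unique())
    pos = {s: i for i, s in enumerate(analyzed)}
    hits = np.zeros((len(analyzed), len(tfs)), dtype=bool)
    for j, tf in enumerate(tfs):
        for snp in recs.loc[recs["tf_name"] == tf, "snp_id"]:
            if snp in pos:
                hits[pos[snp], j] = True
    return hits, tfs


def _resampling_p(hits: np.ndarray, functional_mask: np.ndarray,
                  n_draws: int, rng: np.random.Generator) -> pd.DataFrame:
    """Empirical enrichment of column-wise hit counts among functional rows."""
    n_func = int(functional_mask.sum())
    observed = hits[functional_mask].sum(axis=0)
    order = np.argsort(rng.random((n_draws, hits.shape[0])), axis=1)[:, :n_func]
    null_counts = np.empty((n_draws, hits.shape[1]), dtype=np.int64)
    for j in range(hits.shape[1]):                    # per TF to bound memory
        null_counts[:, j] = hits[order, j].sum(axis=1)
    p = (1 + (null_counts >= observed).sum(axis=0)) / (1 + n_draws)
    return pd.DataFrame({
        "n_functional_hit": observed,
        "n_background_hit": hits[~functional_mask].sum(axis=0),
        "null_mean": null_counts.mean(axis=0),
        "null_sd": null_counts.std(axis=0, ddof=1),
        "p_emp": p,
    })


def motif_enrichment(functional_ids: set, analyzed_ids: set,
                     records: pd.DataFrame, n_draws: int = N_DRAWS,
                     seed: int = 0, min_strength: str = "strong") -> pd.DataFrame:
    """Per-TF resampling enrichment of motif perturbations in functional SNPs.

    Null hit counts come from ``n_draws`` random subsets of ``analyzed_ids`` of
    size |functional|, drawn without replacement; p-values use the add-one
    convention and are BH-corrected across TFs.
    """
    functional = set(functional_ids)
    analyzed = np.array(sorted(analyzed_ids))
    if not functional:
        raise InsufficientDataError("functional SNP set is empty")
    if not functional <= set(analyzed):
        raise InsufficientDataError("functional SNPs must be a subset of analyzed")
    if n_draws < 1:
        raise InsufficientDataError("n_draws must be >= 1")
    hits, tfs = _hit_matrix(records, analyzed, min_strength)
    if not tfs:
        return pd.DataFrame(columns=["tf_name", "n_functional_hit", "n_background_hit",
                                     "null_mean", "null_sd", "p_emp", "fdr_q"])
    func_mask = np.isin(analyzed, sorted(functional))
    rng = np.random.default_rng(seed)
    out = _resampling_p(hits, func_mask, n_draws, rng)
    out.insert(0, "tf_name", tfs)
    out["fdr_q"] = bh_fdr(out["p_emp"].to_numpy())
    return out


def concordance_enrichment(functional_ids: set, analyzed_ids: set,
                           records: pd.DataFrame, allelic_results: pd.DataFrame,
                           n_draws: int = N_DRAWS, seed: int = 0,
                           min_strength: str = "strong") -> tuple[pd.DataFrame, dict]:
    """Per-TF enrichment of motif/expression-concordant functional SNPs.

    A (SNP, TF) pair is concordant when the allele better matching the motif is
    the allele with higher reporter expression (sign of the composite log2FC).
    Ties in either direction are excluded and counted in the returned report.
    """
    functional = set(functional_ids)
    analyzed = np.array(sorted(analyzed_ids))
    if not functional:
        raise InsufficientDataError("functional SNP set is empty")
    direction = allelic_results.set_index("snp_id")["direction"]
    missing = functional - set(direction.index)
    if missing:
        raise InsufficientDataError(
            f"no expression direction for functional SNPs: {sorted(missing)[:5]}")

    allowed = {"strong"} if min_strength == "strong" else {"strong", "weak"}
    recs = records[records["strength"].isin(allowed)].copy()
    recs = recs[recs["snp_id"].isin(direction.index)]
    dirs = direction.reindex(recs["snp_id"]).to_numpy()
    better = recs["better_allele"].to_numpy()
    tie = (better == "tie") | (dirs == 0)
    concordant = ((better == "alt") & (dirs > 0)) | ((better == "ref") & (dirs < 0))
    recs["concordant"] = concordant & ~tie
    report = {"n_pairs": len(recs), "n_ties_excluded": int(tie.sum())}

    conc = recs[recs["concordant"]]
    hits, tfs = _hit_matrix(conc.assign(strength="strong"), analyzed, "strong")
    if not tfs:
        empty = pd.DataFrame(columns=["tf_name", "n_functional_hit", "n_background_hit",
                                      "null_mean", "null_sd", "p_emp", "fdr_q"])
        return empty, report
    func_mask = np.isin(analyzed, sorted(functional))
    rng = np.random.default_rng(seed)
    out = _resampling_p(hits, func_mask, n_draws, rng)
    out.insert(0, "tf_name", tfs)
    out["fdr_q"] = bh_fdr(out["p_emp"].to_numpy())
    out = out.rename(columns={"n_functional_hit": "n_concordant"})
    return out, report


def compare_sets(lmm_results: pd.DataFrame, mode: str,
                 allelic_results: pd.DataFrame | None = None
                 ) -> tuple[set, set]:
    """Materialize (functional, analyzed) SNP ID sets for an enrichment run.

    Modes: ``allele_vs_null`` — allele-main-effect SNPs (Pemp < 0.1) vs SNPs
    with Pemp > 0.1 for allele, drug and interaction; ``interaction_vs_allele``
    — interaction SNPs (Pemp < 0.05) vs allele-main-effect SNPs (allele
    Pemp < 0.1, interaction Pemp > 0.1); ``allelic`` — single-assay analysis,
    Pemp < 0.05 vs the rest of the analyzed SNPs (requires
    ``allelic_results``).
    """
    if mode == "allelic":
        if allelic_results is None:
            raise InsufficientDataError("mode 'allelic' needs allelic_results")
        functional = set(allelic_results.loc[allelic_results["p_emp"] < 0.05, "snp_id"])
        analyzed = set(allelic_results["snp_id"])
    elif mode == "allele_vs_null":
        functional = set(lmm_results.loc[lmm_results["p_emp_allele"] < 0.1, "snp_id"])
        null = lmm_results[(lmm_results["p_emp_allele"] > 0.1)
                           & (lmm_results["p_emp_drug"] > 0.1)
                           & (lmm_results["p_emp_inter"] > 0.1)]
        analyzed = functional | set(null["snp_id"])
    elif mode == "interaction_vs_allele":
        functional = set(lmm_results.loc[lmm_results["p_emp_inter"] < 0.05, "snp_id"])
        background = lmm_results[(lmm_results["p_emp_allele"] < 0.1)
                                 & (lmm_results["p_emp_inter"] > 0.1)]
        analyzed = functional | set(background["snp_id"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not functional:
        raise InsufficientDataError(f"mode {mode!r}: functional SNP set is empty")
    return functional, analyzed


def chip_overlap(snp_positions: pd.DataFrame,
                 peaks: list[IntervalSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap SNP positions with peak tracks.

    ``snp_positions`` needs columns snp_id, chrom, pos (1-based); a SNP
    overlaps an interval iff ``start <= pos-1 < end``.  Returns the per-SNP
    boolean overlap table (one column per track plus ``any_track``) and
    per-track summary counts.
    """
    flags = pd.DataFrame(index=snp_positions["snp_id"].to_numpy())
    pos0 = snp_positions["pos"].to_numpy() - 1
    chroms = snp_positions["chrom"].to_numpy()
    for track in peaks:
        flags[track.label] = [track.overlaps(c, p) for c, p in zip(chroms, pos0)]
    if peaks:
        flags["any_track"] = flags[[t.label for t in peaks]].any(axis=1)
    else:
        flags["any_track"] = False
    summary = pd.DataFrame({
        "track": [t.label for t in peaks],
        "n_overlapping": [int(flags[t.label].sum()) for t in peaks],
    })
    summary["fraction"] = summary["n_overlapping"] / max(len(flags), 1)
    return flags, summary
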