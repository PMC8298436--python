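"""Barcode counts -> filtered log2 activity values and element-level means.

Activity of a barcode in a sample is the log2 ratio of its depth-normalized
RNA abundance to its depth-normalized abundance in the input DNA (plasmid)
library.  A single shared DNA library is assumed.  Filtering masks barcodes
with poor DNA representation, RNA dropout cells, and alleles left with too few
barcodes; an element's per-sample expression is the mean over its surviving
barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FilterError
from .synthetic import CountTables, LibraryDesign

# default filter thresholds (config-exposed; conventional MPRA practice)
MIN_DNA_COUNT = 10
MIN_BARCODES_PER_ALLELE = 3
MIN_SAMPLES_PER_BARCODE = 1
PSEUDOCOUNT = 1.0


@dataclass
class ExpressionTable:
    """Per (sample, barcode) log2 activity with a validity mask.

    ``values`` and ``mask`` are sample x barcode; cells where ``mask`` is False
    are excluded from every downstream statistic.  The DNA counts, raw-RNA zero
    pattern and sample metadata travel with the table so that filtering and
    condition-subset analyses are self-contained.
    """

    values: pd.DataFrame        # index sample_id, columns barcode
    mask: pd.DataFrame          # same shape, bool
    sample_meta: pd.DataFrame   # index sample_id; condition, replicate
    dna_counts: pd.Series       # barcode -> raw DNA count
    rna_zero: pd.DataFrame      # sample x barcode, True where raw RNA count == 0
    norm: dict = field(default_factory=dict)

    def masked_values(self) -> pd.DataFrame:
        """Values with masked cells as NaN."""
        return self.values.where(self.mask)

    def subset_samples(self, samples: list[str]) -> "ExpressionTable":
        return ExpressionTable(
            values=self.values.loc[samples], mask=self.mask.loc[samples],
            sample_meta=self.sample_meta.loc[samples],
            dna_counts=self.dna_counts, rna_zero=self.rna_zero.loc[samples],
            norm=dict(self.norm))

    def condition_samples(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["condition"] == condition])


@dataclass
class ElementExpression:
    """Per-sample mean activity of each (SNP, allele) element."""

    values: pd.DataFrame      # index (snp_id, allele), columns sample_id
    n_barcodes: pd.DataFrame  # same shape; barcodes contributing per cell

    def allele_values(self, snp_id: str, allele: str) -> pd.Series:
        return self.values.loc[(snp_id, allele)]


def compute_expression(counts: CountTables, pseudocount: float = PSEUDOCOUNT,
                       normalization: str = "total-count") -> ExpressionTable:
    """log2( (rna+pc)/libsize_rna ) - log2( (dna+pc)/libsize_dna ) per cell.

    Library sizes are raw totals (before pseudocount).  Barcodes absent from
    the DNA library (count 0) start out masked everywhere.  A zero pseudocount
    is permitted (exact log-ratios) but only safe on all-positive counts.
    """
    if pseudocount < 0:
        raise FilterError("pseudocount must be >= 0")
    if normalization != "total-count":
        raise FilterError(f"unknown normalization {normalization!r}")
    libsize_dna = float(counts.dna.sum())
    if libsize_dna <= 0:
        raise FilterError("DNA library has zero total counts")
    libsize_rna = counts.rna.sum(axis=0).astype(float)
    zero = libsize_rna[libsize_rna <= 0]
    if len(zero):
        raise FilterError(f"sample(s) with zero total RNA counts: {list(zero.index)}")

    rna = counts.rna.T.astype(float)                     # sample x barcode
    dna = counts.dna.reindex(rna.columns).astype(float)
    with np.errstate(divide="ignore"):
        log_rna = np.log2((rna + pseudocount).div(libsize_rna, axis=0))
        log_dna = np.log2((dna + pseudocount) / libsize_dna)
    values = log_rna.sub(log_dna, axis=1)

    mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    mask.loc[:, dna <= 0] = False
    return ExpressionTable(
        values=values, mask=mask, sample_meta=counts.sample_meta.copy(),
        dna_counts=counts.dna.copy(), rna_zero=(counts.rna.T == 0),
        norm={"libsize_dna": libsize_dna, "libsize_rna": libsize_rna.to_dict(),
              "pseudocount": pseudocount})


def filter_table(expr: ExpressionTable, design: LibraryDesign,
                 min_dna_count: int = MIN_DNA_COUNT,
                 min_barcodes_per_allele: int = MIN_BARCODES_PER_ALLELE,
                 min_samples_per_barcode: int = MIN_SAMPLES_PER_BARCODE,
                 mask_zero_rna: bool = True) -> tuple[ExpressionTable, dict]:
    """Apply DNA-depth, RNA-dropout, barcode- and allele-representation filters.

    Steps, in order: (1) mask barcodes with DNA count below ``min_dna_count``;
    (2) mask (sample, barcode) cells with zero raw RNA; (3) mask barcodes left
    unmasked in fewer than ``min_samples_per_barcode`` samples; (4) mask whole
    alleles with fewer than ``min_barcodes_per_allele`` surviving barcodes.
    Idempotent; returns the filtered table and a removal report.
    """
    if min(min_dna_count, min_barcodes_per_allele, min_samples_per_barcode) < 0:
        raise FilterError("thresholds must be >= 0")
    mask = expr.mask.copy()
    report: dict = {"n_barcodes": mask.shape[1], "n_samples": mask.shape[0]}

    low_dna = expr.dna_counts.reindex(mask.columns) < min_dna_count
    report["barcodes_low_dna"] = int(low_dna.sum())
    mask.loc[:, low_dna] = False

    if mask_zero_rna:
        zero_cells = expr.rna_zero & mask
        report["cells_zero_rna"] = int(zero_cells.to_numpy().sum())
        mask &= ~expr.rna_zero
    else:
        report["cells_zero_rna"] = 0

    barcode_samples = mask.sum(axis=0)
    low_rep = barcode_samples < min_samples_per_barcode
    # only count barcodes newly removed at this step
    report["barcodes_low_sample"] = int((low_rep & (barcode_samples > 0)).sum())
    mask.loc[:, low_rep] = False

    surviving = mask.any(axis=0)
    n_alleles_dropped = 0
    for _, group in design.barcode_map.groupby(["snp_id", "allele"]):
        bcs = [b for b in group["barcode"] if b in mask.columns]
        if surviving[bcs].sum() < min_barcodes_per_allele:
            if surviving[bcs].any():
                n_alleles_dropped += 1
            mask.loc[:, bcs] = False
    report["alleles_dropped"] = n_alleles_dropped
    report["barcodes_surviving"] = int(mask.any(axis=0).sum())

    filtered = ExpressionTable(
        values=expr.values, mask=mask, sample_meta=expr.sample_meta,
        dna_counts=expr.dna_counts, rna_zero=expr.rna_zero, norm=dict(expr.norm))
    return filtered, report


def expr_allele_index(design: LibraryDesign) -> pd.Series:
    """barcode -> (snp_id, allele) tuples; basal barcodes map to NaN."""
    s = pd.Series(
        list(zip(design.barcode_map["snp_id"], design.barcode_map["allele"])),
        index=design.barcode_map["barcode"])
    basal = pd.Series([np.nan] * len(design.basal_barcodes),
                      index=pd.Index(design.basal_barcodes), dtype=object)
    return pd.concat([s, basal])


def element_means(expr: ExpressionTable, design: LibraryDesign) -> ElementExpression:
    """Mean unmasked barcode activity per (SNP, allele, sample)."""
    masked = expr.masked_values()
    groups = design.barcode_map.groupby(["snp_id", "allele"])["barcode"].apply(list)
    vals = {}
    nbc = {}
    for key, bcs in groups.items():
        sub = masked[bcs]
        vals[key] = sub.mean(axis=1)
        nbc[key] = sub.notna().sum(axis=1)
    values = pd.DataFrame(vals).T
    values.index = pd.MultiIndex.from_tuples(values.index, names=["snp_id", "allele"])
    n_barcodes = pd.DataFrame(nbc).T
    n_barcodes.index = values.index
    return ElementExpression(values=values, n_barcodes=n_barcodes)


def basal_matrix(expr: ExpressionTable, design: LibraryDesign) -> pd.DataFrame:
    """Sample x basal-barcode masked activity values (NaN where masked)."""
    return expr.masked_values()[list(design.basal_barcodes)]
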