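"""Synthetic MPRA experiments with known ground truth.

Emulates the design of a barcoded reporter screen of GWAS SNPs: each SNP
contributes two element sequences (reference and alternative allele, variant
base at the center), each allele is tagged by a fixed number of unique
barcodes, and a set of "basal" barcodes (minimal promoter only, no element)
provides the feedstock for empirical null distributions.  Counts are generated
from a latent log2 activity per (barcode, sample):

    mu0 + b_k + [alt]*beta_allele + [drug]*beta_drug + [alt & drug]*beta_inter
        + u_r + eps,   eps ~ N(0, sigma_e)

with barcode offsets ``b_k ~ N(0, sigma_bc)`` and replicate (well) offsets
``u_r ~ N(0, sigma_rep)``; basal barcodes carry no allele/drug/interaction
terms.  Because expression is the depth-normalized RNA/DNA ratio, a well
offset shared by every barcode in a sample cancels exactly in normalization;
the component that survives — and that a per-SNP random replicate intercept
absorbs — is the element-by-well interaction, so ``u_r`` is drawn per
(SNP, replicate pair), shared by both alleles and conditions of that SNP.  RNA counts are Poisson around ``dna_k * 2^latent`` rescaled to the
sample sequencing depth (a Poisson-lognormal mixture overall); DNA counts are
lognormal around ``depth / n_barcodes``.  Defaults mirror a two-condition
(vehicle vs ATRA) assay with 6 replicates per condition, 10 barcodes per
allele and 110 basal barcodes; the default residual scale is chosen so the
realized barcode-level log-ratio SD is ~0.12.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, SimulationError
from .motifs import BASES, PWM

# default experiment geometry and noise scales (log2 units)
BARCODES_PER_ALLELE = 10
N_BASAL = 110
ELEMENT_LENGTH = 125
BARCODE_LENGTH = 10
N_REPLICATES = 6
CONDITIONS = ("vehicle", "ATRA")
SIGMA_E = 0.125  # realized median barcode SD (n=6 samples, incl. count noise) ~0.122
SIGMA_BC = 0.05
# Element-by-well interaction SD.  The basal-null methodology presumes that
# element and basal barcodes are exchangeable under the null; a per-element
# well effect has no basal counterpart and would break that premise, so the
# default null model carries none and sigma_rep is an explicit robustness
# knob (used e.g. in mixed-model recovery tests).
SIGMA_REP = 0.0
DEPTH_PER_BARCODE = 2000


@dataclass
class LibraryDesign:
    """Barcode <-> (SNP, allele) map plus the basal barcode registry."""

    snps: pd.DataFrame          # snp_id, locus_id, chrom, pos, ref_allele, alt_allele,
                                # ref_seq, alt_seq, snp_index
    barcode_map: pd.DataFrame   # barcode, snp_id, allele
    basal_barcodes: list[str]
    barcodes_per_allele: int = BARCODES_PER_ALLELE
    n_basal: int = N_BASAL

    @property
    def all_barcodes(self) -> list[str]:
        return list(self.barcode_map["barcode"]) + list(self.basal_barcodes)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def validate(self) -> None:
        barcodes = self.all_barcodes
        if len(set(barcodes)) != len(barcodes):
            raise DesignError("barcodes are not unique across elements and basal set")
        if set(self.barcode_map["barcode"]) & set(self.basal_barcodes):
            raise DesignError("a barcode is both element-mapped and basal")
        counts = self.barcode_map.groupby(["snp_id", "allele"]).size()
        if not (counts == self.barcodes_per_allele).all():
            raise DesignError("each allele must have exactly barcodes_per_allele barcodes")
        for _, row in self.snps.iterrows():
            diffs = [i for i, (a, b) in enumerate(zip(row.ref_seq, row.alt_seq)) if a != b]
            if diffs != [int(row.snp_index)]:
                raise DesignError(
                    f"{row.snp_id}: ref/alt sequences must differ exactly at the SNP")


@dataclass
class GroundTruth:
    """Generative parameters: planted fixed effects and variance components."""

    effects: pd.DataFrame       # index snp_id; beta_allele, beta_drug, beta_inter
    mu0: float = 0.0
    sigma_e: float = SIGMA_E
    sigma_bc: float = SIGMA_BC
    sigma_rep: float = SIGMA_REP
    # optional pre-drawn offsets; simulate_counts draws them when absent.
    # replicate_offsets: DataFrame indexed by snp_id, one column per replicate
    # pair (element-by-well interaction; global well shifts cancel in
    # depth normalization and are therefore not simulated)
    replicate_offsets: pd.DataFrame | None = None
    barcode_offsets: pd.Series | None = None

    def validate(self) -> None:
        if not np.isfinite(self.effects.to_numpy(dtype=float)).all():
            raise SimulationError("planted effects must be finite")
        for s in (self.sigma_e, self.sigma_bc, self.sigma_rep):
            if s < 0:
                raise SimulationError("variance components must be nonnegative")


@dataclass
class CountTables:
    """Raw barcode counts: one DNA (input plasmid) library, RNA per sample."""

    dna: pd.Series              # barcode -> count
    rna: pd.DataFrame           # index barcode, columns sample_id
    sample_meta: pd.DataFrame   # index sample_id; condition, replicate

    def validate(self, design: LibraryDesign | None = None) -> None:
        if (self.dna < 0).any() or (self.rna < 0).any().any():
            raise SimulationError("counts must be nonnegative")
        if set(self.rna.columns) - set(self.sample_meta.index):
            raise SimulationError("sample_meta does not cover every RNA column")
        if design is not None:
            known = set(design.all_barcodes)
            if set(self.rna.index) - known or set(self.dna.index) - known:
                raise SimulationError("counted barcode not present in the design")


def _draw_unique_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4 ** length:
        raise DesignError(
            f"cannot draw {n} unique barcodes from a {length}-nt space (4^{length})")
    seen: dict[str, None] = {}
    max_tries = 50 * n + 1000
    tries = 0
    while len(seen) < n:
        batch = rng.integers(0, 4, size=(n, length))
        for row in batch:
            seen.setdefault("".join(BASES[i] for i in row), None)
            if len(seen) == n:
                break
        tries += n
        if tries > max_tries:
            raise DesignError("barcode space exhausted while drawing unique barcodes")
    return list(seen)[:n]


def generate_library(n_snps: int, barcodes_per_allele: int = BARCODES_PER_ALLELE,
                     n_basal: int = N_BASAL, element_length: int = ELEMENT_LENGTH,
                     seed: int = 0, barcode_length: int = BARCODE_LENGTH,
                     snps_per_locus: int = 25) -> LibraryDesign:
    """Generate a random library design; deterministic given ``seed``.

    Element sequences are uniform random DNA of odd ``element_length`` with the
    variant base exactly at the center; each SNP gets synthetic coordinates
    (used only for interval-overlap analyses).
    """
    if n_snps < 1:
        raise DesignError("n_snps must be >= 1")
    if element_length % 2 == 0:
        raise DesignError("element_length must be odd so the SNP sits at the center")
    rng = np.random.default_rng(seed)
    center = element_length // 2

    seqs = rng.integers(0, 4, size=(n_snps, element_length))
    ref_base = seqs[:, center]
    alt_base = (ref_base + rng.integers(1, 4, size=n_snps)) % 4

    rows = []
    for i in range(n_snps):
        ref_seq = "".join(BASES[b] for b in seqs[i])
        alt_seq = ref_seq[:center] + BASES[alt_base[i]] + ref_seq[center + 1:]
        rows.append({
            "snp_id": f"snp{i + 1:05d}",
            "locus_id": f"locus{i // snps_per_locus + 1:03d}",
            "chrom": "chr1",
            "pos": 10_000 + 1_000 * i,  # 1-based synthetic coordinate
            "ref_allele": BASES[ref_base[i]],
            "alt_allele": BASES[alt_base[i]],
            "ref_seq": ref_seq,
            "alt_seq": alt_seq,
            "snp_index": center,
        })
    snps = pd.DataFrame(rows)

    n_total = n_snps * 2 * barcodes_per_allele + n_basal
    barcodes = _draw_unique_barcodes(rng, n_total, barcode_length)
    bc_iter = iter(barcodes)
    map_rows = [
        {"barcode": next(bc_iter), "snp_id": snp_id, "allele": allele}
        for snp_id in snps["snp_id"]
        for allele in ("ref", "alt")
        for _ in range(barcodes_per_allele)
    ]
    basal = [next(bc_iter) for _ in range(n_basal)]

    design = LibraryDesign(
        snps=snps, barcode_map=pd.DataFrame(map_rows), basal_barcodes=basal,
        barcodes_per_allele=barcodes_per_allele, n_basal=n_basal)
    return design


def make_truth(design: LibraryDesign, beta_allele=0.0, beta_drug=0.0, beta_inter=0.0,
               mu0: float = 0.0, sigma_e: float = SIGMA_E, sigma_bc: float = SIGMA_BC,
               sigma_rep: float = SIGMA_REP) -> GroundTruth:
    """Build a GroundTruth from scalars (broadcast) or per-SNP mappings/Series."""
    idx = pd.Index(design.snps["snp_id"], name="snp_id")
    def _col(v):
        if np.isscalar(v):
            return pd.Series(float(v), index=idx)
        s = pd.Series(v, dtype=float)
        unknown = set(s.index) - set(idx)
        if unknown:
            raise SimulationError(f"effects name unknown SNPs: {sorted(unknown)[:5]}")
        return s.reindex(idx, fill_value=0.0)  # unplanted SNPs have no effect
    effects = pd.DataFrame({
        "beta_allele": _col(beta_allele),
        "beta_drug": _col(beta_drug),
        "beta_inter": _col(beta_inter),
    })
    return GroundTruth(effects=effects, mu0=mu0, sigma_e=sigma_e,
                       sigma_bc=sigma_bc, sigma_rep=sigma_rep)


def random_truth(design: LibraryDesign, seed: int, frac_allelic: float = 0.1,
                 allele_range: tuple[float, float] = (0.1, 1.1),
                 frac_inter: float = 0.0, inter_range: tuple[float, float] = (0.2, 1.0),
                 beta_drug: float = 0.2, **kwargs) -> GroundTruth:
    """Plant allelic and interaction effects in random subsets of SNPs.

    Effect magnitudes are uniform over the given ranges with random sign,
    mirroring the small regulatory effect sizes (|log2FC| ~ 0.1-1.1) that such
    screens are designed to detect.
    """
    rng = np.random.default_rng(seed)
    snp_ids = np.array(design.snp_ids)
    n = len(snp_ids)

    def _plant(frac, rng_range):
        vals = pd.Series(0.0, index=snp_ids)
        k = int(round(frac * n))
        if k:
            chosen = rng.choice(snp_ids, size=k, replace=False)
            mags = rng.uniform(*rng_range, size=k)
            signs = rng.choice([-1.0, 1.0], size=k)
            vals[chosen] = mags * signs
        return vals

    return make_truth(design,
                      beta_allele=_plant(frac_allelic, allele_range),
                      beta_drug=beta_drug,
                      beta_inter=_plant(frac_inter, inter_range),
                      **kwargs)


def simulate_counts(design: LibraryDesign, truth: GroundTruth,
                    n_replicates_per_condition: int = N_REPLICATES,
                    depth: int | None = None, seed: int = 0,
                    conditions: tuple[str, ...] = CONDITIONS,
                    dna_lognormal_sigma: float = 0.25) -> CountTables:
    """Simulate DNA and per-sample RNA barcode counts; deterministic given seed.

    ``depth`` is the total read count per library (DNA, and each RNA sample);
    defaults to 2000 reads per barcode.  Single-condition assays are simulated
    by passing ``conditions=("vehicle",)``.
    """
    truth.validate()
    missing = set(design.snp_ids) - set(truth.effects.index)
    if missing:
        raise SimulationError(f"ground truth missing for SNPs: {sorted(missing)[:5]} ...")
    barcodes = design.all_barcodes
    n_bc = len(barcodes)
    if depth is None:
        depth = DEPTH_PER_BARCODE * n_bc
    if depth <= 0:
        raise SimulationError("depth must be > 0")

    rng = np.random.default_rng(seed)
    samples = [(f"{cond}_rep{r}", cond, r)
               for cond in conditions for r in range(1, n_replicates_per_condition + 1)]
    sample_meta = pd.DataFrame(
        [{"sample_id": s, "condition": c, "replicate": r} for s, c, r in samples]
    ).set_index("sample_id")

    # DNA library: lognormal around depth / n_barcodes
    mean_dna = depth / n_bc
    dna = np.round(rng.lognormal(
        np.log(mean_dna) - dna_lognormal_sigma ** 2 / 2, dna_lognormal_sigma,
        size=n_bc)).astype(np.int64)
    dna_series = pd.Series(dna, index=pd.Index(barcodes, name="barcode"),
                           name="count")

    # per-barcode covariates
    bc_map = design.barcode_map.set_index("barcode")
    is_alt = np.array([
        bc in bc_map.index and bc_map.at[bc, "allele"] == "alt" for bc in barcodes])
    is_basal = np.array([bc in set(design.basal_barcodes) for bc in barcodes])
    snp_of = np.array([bc_map.at[bc, "snp_id"] if not basal else ""
                       for bc, basal in zip(barcodes, is_basal)], dtype=object)

    beta_a = np.zeros(n_bc)
    beta_d = np.zeros(n_bc)
    beta_i = np.zeros(n_bc)
    elem = ~is_basal
    eff = truth.effects.loc[snp_of[elem]]
    beta_a[elem] = eff["beta_allele"].to_numpy()
    beta_d[elem] = eff["beta_drug"].to_numpy()
    beta_i[elem] = eff["beta_inter"].to_numpy()

    if truth.barcode_offsets is not None:
        b_k = truth.barcode_offsets.reindex(barcodes).to_numpy(dtype=float)
        if np.isnan(b_k).any():
            raise SimulationError("barcode_offsets does not cover every barcode")
    else:
        b_k = rng.normal(0.0, truth.sigma_bc, size=n_bc)

    if truth.replicate_offsets is not None:
        u_df = truth.replicate_offsets.reindex(design.snp_ids)
        if u_df.isna().any().any():
            raise SimulationError("replicate_offsets does not cover every SNP")
    else:
        # element-by-well interaction, shared across conditions within a pair
        u_df = pd.DataFrame(
            rng.normal(0.0, truth.sigma_rep,
                       size=(len(design.snp_ids), n_replicates_per_condition)),
            index=design.snp_ids,
            columns=range(1, n_replicates_per_condition + 1))
    u_bc = u_df.reindex(pd.Index(snp_of[elem])).to_numpy()  # (n_elem_bc, n_rep)

    rna = np.empty((n_bc, len(samples)), dtype=np.int64)
    for j, (sid, cond, r) in enumerate(samples):
        drug = 1.0 if cond == "ATRA" else 0.0
        eps = rng.normal(0.0, truth.sigma_e, size=n_bc)
        latent = (truth.mu0 + b_k + is_alt * beta_a + drug * beta_d
                  + (is_alt & (drug > 0)) * beta_i + eps)
        latent[elem] += u_bc[:, r - 1]
        latent[is_basal] = truth.mu0 + b_k[is_basal] + eps[is_basal]
        w = dna * np.exp2(latent)
        lam = depth * w / w.sum()
        rna[:, j] = rng.poisson(lam)
    rna_df = pd.DataFrame(rna, index=pd.Index(barcodes, name="barcode"),
                          columns=[s for s, _, _ in samples])

    tables = CountTables(dna=dna_series, rna=rna_df, sample_meta=sample_meta)
    tables.validate(design)
    return tables


def _informative_position(pwm: PWM) -> int:
    lo = pwm.log_odds[:, :4]
    return int((lo.max(axis=1) - lo.min(axis=1)).argmax())


def generate_motif_fixtures(design: LibraryDesign, n_tfs: int, plant_fraction: float,
                            seed: int = 0,
                            length_range: tuple[int, int] = (6, 12)
                            ) -> tuple[list[PWM], LibraryDesign, pd.DataFrame]:
    """Random PWMs plus a design rewritten so planted SNPs break a motif.

    A ``plant_fraction`` of SNPs get a PWM consensus written over the variant,
    aligned so the SNP falls on the matrix's most informative position: one
    allele carries the consensus base (a perfect match, relative score 1) and
    the other the least-favoured base, producing a strong allelic perturbation.
    Returns ``(pwms, updated_design, plantings)`` where ``plantings`` records
    (snp_id, tf_name, window start, better allele) for oracle tests.
    """
    if not 0.0 <= plant_fraction <= 1.0:
        raise SimulationError("plant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    pwms = []
    for t in range(n_tfs):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        mat = np.empty((L, 4))
        core = L // 2
        # One near-deterministic "core" position (where the variant is planted)
        # flanked by moderately informative positions.  The flank consensus is
        # drawn from the base pair complementary-disjoint from the core base,
        # so no shifted or reverse-complement window overlapping the SNP can
        # feed the core row its consensus base: the breaking allele's best
        # relative score is then exactly 1 minus the core's share of the total
        # score range, which is calibrated below to 0.4 (a "strong" shift).
        core_base = int(rng.integers(0, 4))
        flank_pair = [1, 2] if core_base in (0, 3) else [0, 3]  # {C,G} or {A,T}
        flank_range = 0.0
        for p in range(L):
            if p == core:
                continue
            cons = int(rng.choice(flank_pair))
            pc = rng.uniform(0.40, 0.48)
            w = 1 + 0.05 * rng.uniform(-1, 1, size=3)
            rest = (1 - pc) * w / w.sum()
            mat[p] = np.insert(rest, cons, pc)
            lo = np.log2(mat[p] / 0.25)
            flank_range += lo.max() - lo.min()
        core_range = (0.4 / 0.6) * flank_range
        pc_core = 1.0
        for _ in range(3):  # fixed point for p_cons given the target range
            off = 0.25 * 2.0 ** (np.log2(max(pc_core, 0.5) / 0.25) - core_range)
            pc_core = 1.0 - 3 * off
        mat[core] = np.insert(np.full(3, off), core_base, pc_core)
        pwms.append(PWM(tf_name=f"TF{t + 1:03d}", matrix=mat))

    snps = design.snps.copy()
    n_plant = int(round(plant_fraction * len(snps)))
    plant_rows = []
    if n_plant:
        chosen = rng.choice(len(snps), size=n_plant, replace=False)
        for row_i in chosen:
            row = snps.iloc[row_i]
            pwm = pwms[int(rng.integers(0, len(pwms)))]
            L = len(pwm)
            if len(row.ref_seq) < L:
                raise SimulationError(
                    f"element of {row.snp_id} too short for motif {pwm.tf_name}")
            c = int(row.snp_index)
            core = _informative_position(pwm)
            start = c - core
            if start < 0 or start + L > len(row.ref_seq):
                start = min(max(start, 0), len(row.ref_seq) - L)
            offset = c - start
            consensus = pwm.consensus
            match_base = consensus[offset]
            core_idx = int(pwm.matrix[offset].argmax())
            comp = {0: 3, 1: 2, 2: 1, 3: 0}
            # the breaking base may be neither the core consensus nor its
            # complement: the reverse-complement window of an odd-length motif
            # feeds the core row the complement of the SNP base itself
            safe = [b for b in range(4) if b not in (core_idx, comp[core_idx])]
            break_base = BASES[min(safe, key=lambda b: pwm.matrix[offset][b])]
            guard = BASES[safe[0]]

            def _rewrite(seq: str, center_base: str) -> str:
                # guard bases flanking the window keep boundary-shifted windows
                # from feeding the core row its consensus base
                planted = consensus[:offset] + center_base + consensus[offset + 1:]
                out = seq[:start] + planted + seq[start + L:]
                if start > 0:
                    out = out[:start - 1] + guard + out[start:]
                if start + L < len(out):
                    out = out[:start + L] + guard + out[start + L + 1:]
                return out

            better = "ref" if rng.random() < 0.5 else "alt"
            ref_base = match_base if better == "ref" else break_base
            alt_base = break_base if better == "ref" else match_base
            snps.loc[snps.index[row_i], "ref_seq"] = _rewrite(row.ref_seq, ref_base)
            snps.loc[snps.index[row_i], "alt_seq"] = _rewrite(row.alt_seq, alt_base)
            snps.loc[snps.index[row_i], "ref_allele"] = ref_base
            snps.loc[snps.index[row_i], "alt_allele"] = alt_base
            plant_rows.append({"snp_id": row.snp_id, "tf_name": pwm.tf_name,
                               "start": start, "better_allele": better})

    plantings = pd.DataFrame(plant_rows,
                             columns=["snp_id", "tf_name", "start", "better_allele"])
    new_design = replace(design, snps=snps)
    new_design.validate()
    return pwms, new_design, plantings
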