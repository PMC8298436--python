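"""PWM scanning and allelic motif-perturbation scoring.

A SNP's two element sequences are scanned with each transcription-factor
position weight matrix (PWM), restricted to windows overlapping the variant
position, on both strands.  Scores are log2 odds against a background base
distribution, rescaled to a relative score in [0, 1] between the matrix's
attainable extremes, so that thresholds are comparable across motifs of
different lengths and information content.  An allelic perturbation is the
difference in best relative score between the alternative and reference
alleles; it is labelled "strong" when one allele is a good match and the
score shift is large, "weak" for smaller shifts, and "none" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MotifError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

# default perturbation-call thresholds (relative-score units)
MATCH_THRESHOLD = 0.85
STRONG_DELTA = 0.30
WEAK_DELTA = 0.10
TIE_TOL = 1e-9


@dataclass
class PWM:
    """A position weight matrix: per-position base probabilities (columns A,C,G,T)."""

    tf_name: str
    matrix: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise MotifError(f"PWM {self.tf_name}: matrix must be positions x 4")
        if len(self.matrix) < 4:
            raise MotifError(f"PWM {self.tf_name}: length must be >= 4")
        rowsums = self.matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise MotifError(f"PWM {self.tf_name}: position probabilities must sum to 1")

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray, pseudocount: float = 0.8,
                    background: np.ndarray | None = None) -> "PWM":
        """Convert a count matrix to probabilities, pseudocount split by background."""
        counts = np.asarray(counts, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = (counts + pseudocount * bg) / (counts.sum(axis=1, keepdims=True) + pseudocount)
        return cls(tf_name=tf_name, matrix=probs, background=bg, pseudocount=pseudocount)

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 5) log2(p/bg) with an all-zero fifth column for N bases."""
        with np.errstate(divide="ignore"):
            lo = np.log2(np.maximum(self.matrix, 1e-300) / self.background)
        return np.hstack([lo, np.zeros((len(self.matrix), 1))])

    @property
    def score_range(self) -> tuple[float, float]:
        """Attainable (min, max) log-odds over all sequences of the motif length."""
        lo = self.log_odds[:, :4]
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class PerturbationRecord:
    """Allelic motif-perturbation call for one (SNP, TF) pair."""

    snp_id: str
    tf_name: str
    ref_score: float          # best log-odds, ref allele
    alt_score: float
    ref_rel: float            # best relative score in [0, 1]
    alt_rel: float
    delta: float              # alt_rel - ref_rel
    strength: str             # strong | weak | none
    better_allele: str        # ref | alt | tie
    ref_position: int         # 0-based window start of the best hit, forward coords
    alt_position: int
    ref_strand: str
    alt_strand: str


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise MotifError(f"invalid base {exc.args[0]!r} in sequence") from None


def _window_scores(idx: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Forward- and reverse-strand log-odds for every window start (forward coords)."""
    L = len(pwm)
    n_windows = len(idx) - L + 1
    lo = pwm.log_odds
    offsets = np.arange(L)
    windows = idx[np.arange(n_windows)[:, None] + offsets]          # (n_windows, L)
    fwd = lo[offsets, windows].sum(axis=1)
    # reverse strand: score the reverse complement of each window
    rc_windows = _COMPLEMENT_IDX[windows][:, ::-1]
    rev = lo[offsets, rc_windows].sum(axis=1)
    return fwd, rev


def score_sequence(seq: str, pwm: PWM) -> tuple[float, float, int, str]:
    """Best PWM match over all windows and both strands of ``seq``.

    Returns ``(log_odds, relative_score, position, strand)`` where position is
    the 0-based window start on the forward strand.  Ties are broken toward the
    leftmost position on the forward strand.
    """
    if len(seq) < len(pwm):
        raise MotifError(
            f"sequence length {len(seq)} shorter than motif {pwm.tf_name} ({len(pwm)} nt)")
    idx = _encode(seq)
    fwd, rev = _window_scores(idx, pwm)
    # tie-break: leftmost window start first, forward strand within a start
    per_start = np.where(fwd >= rev, fwd, rev)
    pos = int(per_start.argmax())
    if fwd[pos] >= rev[pos]:
        score, strand = float(fwd[pos]), "+"
    else:
        score, strand = float(rev[pos]), "-"
    lo_min, lo_max = pwm.score_range
    rel = (score - lo_min) / (lo_max - lo_min) if lo_max > lo_min else 0.0
    return score, float(rel), pos, strand


def _best_over_snp(seq: str, snp_index: int, pwm: PWM) -> tuple[float, float, int, str]:
    """Best match restricted to windows overlapping position ``snp_index``."""
    L = len(pwm)
    lo_start = max(0, snp_index - L + 1)
    hi_start = min(len(seq) - L, snp_index)
    if hi_start < lo_start:
        raise MotifError(f"no window of motif {pwm.tf_name} fits over the SNP position")
    sub = seq[lo_start:hi_start + L]
    score, rel, pos, strand = score_sequence(sub, pwm)
    return score, rel, pos + lo_start, strand


def allelic_perturbation(design, snp_id: str, pwm: PWM, *,
                         match_threshold: float = MATCH_THRESHOLD,
                         strong_delta: float = STRONG_DELTA,
                         weak_delta: float = WEAK_DELTA,
                         tie_tol: float = TIE_TOL) -> PerturbationRecord:
    """Score the allelic perturbation of one PWM at one SNP.

    Only windows overlapping the variant position are considered, so any score
    difference between alleles is attributable to the variant base.
    """
    row = design.snps.loc[design.snps["snp_id"] == snp_id]
    if row.empty:
        raise MotifError(f"unknown SNP {snp_id!r}")
    row = row.iloc[0]
    ref_seq, alt_seq, c = row["ref_seq"], row["alt_seq"], int(row["snp_index"])
    if len(ref_seq) != len(alt_seq):
        raise MotifError(f"{snp_id}: allele sequences differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
    if diffs != [c]:
        raise MotifError(
            f"{snp_id}: alleles must differ exactly at the SNP position {c} (found {diffs})")

    ref_score, ref_rel, ref_pos, ref_strand = _best_over_snp(ref_seq, c, pwm)
    alt_score, alt_rel, alt_pos, alt_strand = _best_over_snp(alt_seq, c, pwm)
    delta = alt_rel - ref_rel

    if max(ref_rel, alt_rel) >= match_threshold and abs(delta) >= strong_delta:
        strength = "strong"
    elif abs(delta) >= weak_delta:
        strength = "weak"
    else:
        strength = "none"
    if abs(delta) <= tie_tol:
        better = "tie"
    else:
        better = "alt" if delta > 0 else "ref"

    return PerturbationRecord(
        snp_id=snp_id, tf_name=pwm.tf_name,
        ref_score=ref_score, alt_score=alt_score,
        ref_rel=ref_rel, alt_rel=alt_rel, delta=delta,
        strength=strength, better_allele=better,
        ref_position=ref_pos, alt_position=alt_pos,
        ref_strand=ref_strand, alt_strand=alt_strand)


def scan_all(design, pwms: list[PWM], *, keep: str = "perturbed",
             **thresholds) -> pd.DataFrame:
    """Score every SNP x PWM pair; return records as a DataFrame.

    ``keep='perturbed'`` retains records with strength != 'none' (the input to
    enrichment); ``keep='all'`` retains everything.  Output is deterministically
    ordered by (snp_id, tf_name).
    """
    records = []
    for snp_id in sorted(design.snps["snp_id"]):
        for pwm in sorted(pwms, key=lambda p: p.tf_name):
            rec = allelic_perturbation(design, snp_id, pwm, **thresholds)
            if keep == "all" or rec.strength != "none":
                records.append(rec)
    cols = ["snp_id", "tf_name", "ref_score", "alt_score", "ref_rel", "alt_rel",
            "delta", "strength", "better_allele", "ref_position", "alt_position",
            "ref_strand", "alt_strand"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(r) for r in records])[cols]
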