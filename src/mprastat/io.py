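"""Readers and writers for the package's on-disk dialects.

Designs, counts and results travel as plain TSV; element sequences as FASTA
(record id ``snp_id|allele``); PWMs as JASPAR-style text (via Bio.motifs);
ground truth as JSON; null statistic vectors as compressed ``.npz`` arrays;
ChIP peaks as 3+ column BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import IntervalSet
from .errors import BedFormatError, DesignError
from .motifs import PWM
from .synthetic import CountTables, GroundTruth, LibraryDesign


# -- library designs ---------------------------------------------------------

def write_design(design: LibraryDesign, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bm = design.barcode_map.copy()
    basal = pd.DataFrame({"barcode": design.basal_barcodes,
                          "snp_id": "", "allele": "basal"})
    pd.concat([bm, basal]).to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    design.snps.drop(columns=["ref_seq", "alt_seq"]).to_csv(
        outdir / "snps.tsv", sep="\t", index=False)
    records = []
    for _, row in design.snps.iterrows():
        for allele in ("ref", "alt"):
            records.append(SeqRecord(Seq(row[f"{allele}_seq"]),
                                     id=f"{row.snp_id}|{allele}", description=""))
    SeqIO.write(records, outdir / "elements.fasta", "fasta")


def read_design(outdir: str | Path) -> LibraryDesign:
    outdir = Path(outdir)
    bc = pd.read_csv(outdir / "barcodes.tsv", sep="\t",
                     keep_default_na=False, dtype={"barcode": str})
    basal = list(bc.loc[bc["allele"] == "basal", "barcode"])
    bm = bc[bc["allele"] != "basal"].reset_index(drop=True)
    snps = pd.read_csv(outdir / "snps.tsv", sep="\t")
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(outdir / "elements.fasta", "fasta")}
    for allele in ("ref", "alt"):
        snps[f"{allele}_seq"] = [seqs[f"{sid}|{allele}"] for sid in snps["snp_id"]]
    canonical = ["snp_id", "locus_id", "chrom", "pos", "ref_allele",
                 "alt_allele", "ref_seq", "alt_seq", "snp_index"]
    snps = snps[canonical + [c for c in snps.columns if c not in canonical]]
    per_allele = bm.groupby(["snp_id", "allele"]).size()
    if per_allele.nunique() != 1:
        raise DesignError("unequal barcode counts per allele in design TSV")
    design = LibraryDesign(snps=snps, barcode_map=bm, basal_barcodes=basal,
                           barcodes_per_allele=int(per_allele.iloc[0]),
                           n_basal=len(basal))
    design.validate()
    return design


# -- count tables ------------------------------------------------------------

def write_counts(counts: CountTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.dna.rename("count").rename_axis("barcode").to_csv(
        outdir / "dna.tsv", sep="\t")
    counts.rna.rename_axis("barcode").to_csv(outdir / "rna.tsv", sep="\t")
    counts.sample_meta.to_csv(outdir / "samples.tsv", sep="\t")


def read_counts(outdir: str | Path) -> CountTables:
    outdir = Path(outdir)
    dna = pd.read_csv(outdir / "dna.tsv", sep="\t", index_col="barcode")["count"]
    rna = pd.read_csv(outdir / "rna.tsv", sep="\t", index_col="barcode")
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col="sample_id")
    return CountTables(dna=dna, rna=rna, sample_meta=meta)


# -- ground truth ------------------------------------------------------------

def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "mu0": truth.mu0, "sigma_e": truth.sigma_e,
        "sigma_bc": truth.sigma_bc, "sigma_rep": truth.sigma_rep,
        "effects": truth.effects.reset_index().to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    effects = pd.DataFrame(payload["effects"]).set_index("snp_id")
    return GroundTruth(effects=effects, mu0=payload["mu0"],
                       sigma_e=payload["sigma_e"], sigma_bc=payload["sigma_bc"],
                       sigma_rep=payload["sigma_rep"])


# -- PWMs (JASPAR-style text) ------------------------------------------------

def write_jaspar(pwms: list[PWM], path: str | Path, scale: float = 1000.0) -> None:
    """Write probability matrices as JASPAR count blocks (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\t{pwm.tf_name}\n")
            for base, row in zip("ACGT", (pwm.matrix * scale).T):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path: str | Path, pseudocount: float = 0.8) -> list[PWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"]).T  # positions x 4
        out.append(PWM.from_counts(m.matrix_id or m.name, counts,
                                   pseudocount=pseudocount))
    return out


# -- BED peaks ---------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError("expected >= 3 tab-separated fields", ln)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", ln)
            if start >= end:
                raise BedFormatError(f"start {start} >= end {end}", ln)
            rows.append({"chrom": fields[0], "start": start, "end": end})
    return IntervalSet(label=label or Path(path).stem,
                       intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


# -- null vectors ------------------------------------------------------------

def write_nulls(nulls: dict, path: str | Path) -> None:
    np.savez_compressed(path, **{k: v.stats for k, v in nulls.items()})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
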