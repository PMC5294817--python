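"""Readers and writers for the pipeline's external formats.

BED is 0-based half-open and is the internal convention, so BED coordinates
pass through unchanged; VCF positions (1-based) are converted on read.
Chromosome names are normalized to the chr-prefixed dialect everywhere.
All derived tables are plain TSV for human diffability.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import ConsensusLocus, GenomicInterval, PeakSet, normalize_chrom
from .ld import LEAD, HaplotypePanel, Site, SnpRecord
from .enrichment import TraitAssociation
from .motif import MotifModel

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------- BED

def read_bed(path, name: str = None) -> PeakSet:
    """Read BED3/BED6 into a PeakSet (named after the file stem by default)."""
    path = Path(path)
    name = name or path.stem
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(name, intervals)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_consensus_bed(loci, path) -> None:
    """Consensus loci as BED6; the name column holds comma-joined sources."""
    with open(path, "w") as fh:
        for loc in loci:
            srcs = ",".join(sorted(loc.sources))
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{srcs}\t0\t.\n")


def read_consensus_bed(path) -> list[ConsensusLocus]:
    loci = []
    ps = read_bed(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            sources = frozenset(fields[3].split(",")) if len(fields) >= 4 else frozenset({"unknown"})
            loci.append(
                ConsensusLocus(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])), sources
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


# ------------------------------------------------------------- GWAS catalog

DEFAULT_CATALOG_COLUMNS = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "trait": "trait",
    "study": "study",
}


def read_gwas_catalog(path, column_map: dict = None):
    """Read a GWAS-catalog-style TSV into associations and lead SNP records.

    Rows lacking a numeric chromosomal position are dropped (counted and
    logged, as catalog exports contain placeholders like "NR").  Duplicated
    (trait, SNP) rows collapse to one association.

    Returns (assocs, leads, n_dropped).
    """
    colmap = dict(DEFAULT_CATALOG_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for k, v in colmap.items() if k in ("snp_id", "chrom", "pos", "trait") and v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    pos = pd.to_numeric(df[colmap["pos"]], errors="coerce")
    bad = pos.isna()
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropped %d catalog rows without numeric position", n_dropped)
    df = df[~bad].copy()
    df["_pos"] = pos[~bad].astype(int)
    assocs = []
    leads = {}
    seen = set()
    for _, row in df.iterrows():
        snp = row[colmap["snp_id"]]
        trait = row[colmap["trait"]]
        key = (trait, snp)
        if key in seen:
            continue
        seen.add(key)
        assocs.append(TraitAssociation(trait=trait, snp_id=snp, lead_id=snp))
        if snp not in leads:
            leads[snp] = SnpRecord(
                snp_id=snp,
                chrom=normalize_chrom(row[colmap["chrom"]]),
                pos=int(row["_pos"]),
                provenance=LEAD,
            )
    return assocs, list(leads.values()), n_dropped


# ---------------------------------------------------------------------- VCF

def read_panel_vcf(path, allow_unphased: bool = False):
    """Load a phased VCF into a HaplotypePanel.

    Multi-allelic sites are split into one biallelic column per alternate
    allele (logged).  Sites with missing alleles are dropped (logged).
    Unphased genotypes are rejected unless ``allow_unphased``, in which case
    the caller should use the dosage r^2 estimator.

    Returns (panel, stats) with counts of split/dropped records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    n_split = n_dropped = 0
    n_hap = 2 * len(vcf.samples)
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]
        alleles = []
        phased_ok = True
        has_missing = False
        for g in gts:
            if len(g) < 3:
                has_missing = True
                break
            a = g[:-1]
            if any(x < 0 for x in a):
                has_missing = True
            if not g[-1]:
                phased_ok = False
            alleles.append(a)
        if has_missing:
            n_dropped += 1
            logger.info("dropped site %s:%s with missing alleles", var.CHROM, var.POS)
            continue
        if not phased_ok and not allow_unphased:
            raise FormatError(
                f"unphased genotype at {var.CHROM}:{var.POS}; "
                "pass allow_unphased=True to accept (forces dosage r^2)"
            )
        flat = np.array(alleles).reshape(-1)
        alts = var.ALT
        if len(alts) > 1:
            n_split += 1
        for ai, alt in enumerate(alts, start=1):
            col = (flat == ai).astype(np.uint8)
            sites.append(
                Site(
                    chrom=normalize_chrom(var.CHROM),
                    pos=int(var.POS) - 1,  # to 0-based
                    ref=var.REF,
                    alt=alt,
                    snp_id=(var.ID or f"{var.CHROM}:{var.POS}")
                    + (f"_alt{ai}" if len(alts) > 1 else ""),
                )
            )
            columns.append(col)
    if n_split:
        logger.info("split %d multi-allelic sites into biallelic records", n_split)
    H = np.stack(columns, axis=1) if columns else np.zeros((n_hap, 0), dtype=np.uint8)
    return HaplotypePanel(sites, H), {"n_split": n_split, "n_dropped": n_dropped}


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF v4.2 (sites in position order)."""
    n_hap = panel.n_haplotypes
    if n_hap % 2:
        raise ValueError("VCF output requires an even number of haplotypes")
    samples = [f"ind_{i:04d}" for i in range(n_hap // 2)]
    order = sorted(range(panel.n_sites), key=lambda i: (panel.sites[i].chrom, panel.sites[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({s.chrom for s in panel.sites}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i in order:
            s = panel.sites[i]
            col = panel.haplotypes[:, i]
            gts = "\t".join(f"{col[2*j]}|{col[2*j+1]}" for j in range(n_hap // 2))
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_haplotype_tsv(path) -> HaplotypePanel:
    """Plain haplotype matrix: header of site ids 'chrom:pos:ref:alt:id',
    one row of 0/1 alleles per haplotype."""
    df = pd.read_csv(path, sep="\t")
    sites = []
    for col in df.columns:
        chrom, pos, ref, alt, sid = col.split(":")
        sites.append(Site(normalize_chrom(chrom), int(pos), ref, alt, sid))
    return HaplotypePanel(sites, df.to_numpy(dtype=np.uint8))


def write_haplotype_tsv(panel: HaplotypePanel, path) -> None:
    cols = [f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}:{s.snp_id}" for s in panel.sites]
    pd.DataFrame(panel.haplotypes, columns=cols).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- SNP TSV

def write_snps_tsv(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "maf": "" if r.maf is None else f"{r.maf:.6g}",
                "provenance": r.provenance,
                "lead_id": r.lead_id or "",
                "r2_to_lead": "" if r.r2_to_lead is None else f"{r.r2_to_lead:.6g}",
            }
        )
    pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "maf", "provenance", "lead_id", "r2_to_lead"],
    ).to_csv(path, sep="\t", index=False)


def read_snps_tsv(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "lead_id": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            SnpRecord(
                snp_id=row["snp_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                maf=None if pd.isna(row["maf"]) else float(row["maf"]),
                provenance=row["provenance"],
                lead_id=None if pd.isna(row["lead_id"]) else str(row["lead_id"]),
                r2_to_lead=None if pd.isna(row["r2_to_lead"]) else float(row["r2_to_lead"]),
            )
        )
    return out


# ---------------------------------------------------------------------- PWM

def read_pwm(path) -> np.ndarray:
    """Read a JASPAR-style 4-row matrix and return column-normalized 4x6 probabilities."""
    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    if counts.shape[1] != 6:
        raise FormatError(f"{path}: expected a 6-column half-site matrix")
    return counts / counts.sum(axis=0, keepdims=True)


def write_pwm(pwm: np.ndarray, path, name: str = "DR3_half_site") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, b in enumerate("ACGT"):
            vals = " ".join(f"{v:8.4f}" for v in pwm[i])
            fh.write(f"{b} [ {vals} ]\n")


# -------------------------------------------------------------------- FASTA

def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Indexed FASTA access (pyfaidx); returns the Fasta object."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


# ------------------------------------------------------------------ manifest

def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
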