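"""Seeded synthetic-data generators for every pipeline input.

These generators emit the same external formats the pipeline reads (BED,
VCF, TSV, FASTA), with planted structure whose ground truth is recorded so
every stage has an exact oracle:

* a phased haplotype panel organised as independent LD blocks — within a
  block every site is a copy of a founder column with a small per-site
  mutation probability, so within-block r^2 is high and cross-block r^2 is
  at sampling-noise level;
* a GWAS-style catalog plus peak sets in which one planted trait's SNPs are
  covered by peaks at a chosen multiple of the background coverage rate;
* genome sequence with exact consensus DR3 15-mers planted at recorded
  positions and strands, some overlapping SNP positions;
* per-sample binding signal that decreases with alternate-allele dosage.

Each generator draws from a named substream of a single integer seed, so
adding a generator never perturbs the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import TraitAssociation
from .intervals import GenomicInterval, PeakSet, merge_consensus
from .ld import HaplotypePanel, Site
from .motif import MotifModel, default_dr3_model, reverse_complement

_STREAMS = {
    "panel": 11,
    "catalog": 23,
    "peaks": 37,
    "sequence": 53,
    "genotype": 71,
    "regdb": 89,
    "peaks_b": 97,
}

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small genome (one chromosome) sized so the whole
    pipeline runs in seconds while every stage still has signal to find:
    200 CEU-scale haplotypes over 40 independent 25-kb LD blocks, ~300-bp
    peaks covering a few percent of the genome, 20 phenotypes with one
    planted at a 10x coverage enrichment, and 20 planted DR3 motifs.
    """

    seed: int = 0
    n_haplotypes: int = 200
    n_blocks: int = 40
    block_size_bp: int = 25_000
    sites_per_block: int = 10
    mutation_rate: float = 0.02
    founder_freq_range: tuple = (0.02, 0.5)
    n_peaks: int = 300
    peak_width_mean: float = 300.0
    peak_width_sd: float = 50.0
    n_peak_sets: int = 2
    n_traits: int = 20
    snps_per_trait_mean: int = 20
    planted_trait: str = "planted_trait"
    planted_trait_snp_count: int = 50
    enrichment_factor: float = 10.0
    motif_plant_count: int = 20
    chrom: str = "chr1"

    def __post_init__(self):
        for name in ("n_haplotypes", "n_blocks", "block_size_bp", "sites_per_block",
                     "n_peaks", "n_peak_sets", "n_traits", "snps_per_trait_mean",
                     "planted_trait_snp_count", "motif_plant_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")

    @property
    def genome_length_bp(self) -> int:
        return self.n_blocks * self.block_size_bp


def sim_panel(cfg: SimConfig) -> HaplotypePanel:
    """Phased panel with block LD structure (see module docstring)."""
    rng = _rng(cfg.seed, "panel")
    n_sites = cfg.n_blocks * cfg.sites_per_block
    H = np.zeros((cfg.n_haplotypes, n_sites), dtype=np.uint8)
    sites: list[Site] = []
    lo, hi = cfg.founder_freq_range
    rs_counter = 1_000_000
    for b in range(cfg.n_blocks):
        p = rng.uniform(lo, hi)
        founder = (rng.random(cfg.n_haplotypes) < p).astype(np.uint8)
        cols = slice(b * cfg.sites_per_block, (b + 1) * cfg.sites_per_block)
        flips = rng.random((cfg.n_haplotypes, cfg.sites_per_block)) < cfg.mutation_rate
        H[:, cols] = founder[:, None] ^ flips.astype(np.uint8)
        positions = np.sort(
            rng.choice(cfg.block_size_bp, size=cfg.sites_per_block, replace=False)
        ) + b * cfg.block_size_bp
        for pos in positions:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(
                Site(
                    chrom=cfg.chrom,
                    pos=int(pos),
                    ref=str(_BASES[ref]),
                    alt=str(_BASES[alt]),
                    snp_id=f"rs{rs_counter + len(sites)}",
                )
            )
    return HaplotypePanel(sites, H)


def sim_catalog_and_peaks(cfg: SimConfig, panel: HaplotypePanel):
    """Trait catalog plus peak sets with one trait planted under peaks.

    Every panel site is assigned to exactly one trait; the planted trait
    receives ``planted_trait_snp_count`` sites, the remainder are spread
    uniformly over the other traits.  Background peaks fall uniformly on the
    genome; each planted-trait SNP additionally receives a covering peak with
    probability ``(enrichment_factor - 1) * background_coverage``, so its
    expected coverage is ``enrichment_factor`` times background.

    Returns ``(assocs, peak_sets, truth)`` where truth is a DataFrame
    (snp_id, trait, pos, covered) with exact coverage computed against the
    merged peaks — sufficient to derive every downstream expectation.
    """
    rng = _rng(cfg.seed, "catalog")
    n_sites = panel.n_sites
    if cfg.planted_trait_snp_count > n_sites:
        raise ValueError("planted trait larger than the panel")
    idx = rng.permutation(n_sites)
    planted_idx = idx[: cfg.planted_trait_snp_count]
    rest = idx[cfg.planted_trait_snp_count:]
    other_traits = [f"trait_{i:03d}" for i in range(cfg.n_traits - 1)]
    trait_of = {}
    for i in planted_idx:
        trait_of[int(i)] = cfg.planted_trait
    assignment = rng.integers(0, len(other_traits), size=rest.size)
    for i, t in zip(rest, assignment):
        trait_of[int(i)] = other_traits[int(t)]
    # one lead per trait: the lowest-position member; the rest are its LD set
    by_trait: dict[str, list[int]] = {}
    for i, t in trait_of.items():
        by_trait.setdefault(t, []).append(i)
    assocs: list[TraitAssociation] = []
    for t, members in sorted(by_trait.items()):
        members = sorted(members, key=lambda i: panel.sites[i].pos)
        lead = panel.sites[members[0]].snp_id
        for i in members:
            assocs.append(TraitAssociation(t, panel.sites[i].snp_id, lead))

    rng_peaks = _rng(cfg.seed, "peaks")
    genome = cfg.genome_length_bp
    widths = np.maximum(
        50, rng_peaks.normal(cfg.peak_width_mean, cfg.peak_width_sd, cfg.n_peaks)
    ).astype(np.int64)
    coverage = float(widths.sum()) / genome
    if cfg.enrichment_factor * coverage > 1:
        raise ValueError(
            "enrichment_factor x background coverage exceeds 1; "
            "reduce n_peaks, peak width or the factor"
        )
    starts = rng_peaks.integers(0, np.maximum(1, genome - widths))
    intervals = [
        GenomicInterval(cfg.chrom, int(s), int(s + w)) for s, w in zip(starts, widths)
    ]
    extra_p = (cfg.enrichment_factor - 1.0) * coverage
    for i in planted_idx:
        if rng_peaks.random() < extra_p:
            w = int(max(50, rng_peaks.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
            pos = panel.sites[int(i)].pos
            start = int(pos - rng_peaks.integers(0, w))
            start = max(0, min(start, genome - w))
            intervals.append(GenomicInterval(cfg.chrom, start, start + w))
    order = rng_peaks.permutation(len(intervals))
    peak_sets = [
        PeakSet(
            f"simset_{k + 1}",
            [intervals[j] for j in order[k :: cfg.n_peak_sets]],
        )
        for k in range(cfg.n_peak_sets)
    ]
    peak_sets = [ps for ps in peak_sets if len(ps)]
    merged = merge_consensus(peak_sets)
    starts_m = np.array([l.start for l in merged], dtype=np.int64)
    ends_m = np.array([l.end for l in merged], dtype=np.int64)
    truth_rows = []
    for i in range(n_sites):
        pos = panel.sites[i].pos
        j = int(np.searchsorted(starts_m, pos, side="right")) - 1
        covered = j >= 0 and pos < ends_m[j]
        truth_rows.append(
            {
                "snp_id": panel.sites[i].snp_id,
                "trait": trait_of[i],
                "pos": pos,
                "covered": bool(covered),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return assocs, peak_sets, truth


def sim_sequences_with_motifs(
    cfg: SimConfig,
    loci,
    model: Optional[MotifModel] = None,
    panel: Optional[HaplotypePanel] = None,
):
    """Genome sequence with exact consensus DR3 15-mers planted inside loci.

    The genome is i.i.d. background over the whole chromosome; panel site
    positions (when a panel is given) carry the site's reference allele so
    allele-aware rescoring is consistent.  Up to ``motif_plant_count`` loci
    receive one plant each (consensus half-sites around a random spacer) at a
    recorded position and strand; when a locus contains a panel SNP the plant
    is placed over it at a scored in-motif position when it fits.

    Returns ``(sequence, plants, site_overrides)``: plants is a DataFrame
    (chrom, start, end, strand, planted_sequence, over_snp); site_overrides
    maps snp_id -> (ref, alt) for panel sites whose base was overwritten by a
    plant (alleles re-anchored to the planted base).
    """
    if model is None:
        model = default_dr3_model()
    rng = _rng(cfg.seed, "sequence")
    genome = rng.choice(4, size=cfg.genome_length_bp)
    site_at: dict[int, Site] = {}
    if panel is not None:
        for s in panel.sites:
            genome[s.pos] = int(np.where(_BASES == s.ref)[0][0])
            site_at[s.pos] = s
    core = model.consensus_core()
    w = model.width
    plants = []
    overrides: dict[str, tuple] = {}
    loci = [l for l in loci if len(l) >= w]
    # SNP-bearing loci first so plants exercise the SNP-in-motif machinery;
    # plants sit near the locus midpoint, where summit-centred scans look.
    has_snp = [i for i, l in enumerate(loci)
               if any(p in site_at for p in range(l.start, l.end))]
    no_snp = [i for i in range(len(loci)) if i not in set(has_snp)]
    order = list(rng.permutation(has_snp)) + list(rng.permutation(no_snp))
    chosen = order[: cfg.motif_plant_count]
    for li in chosen:
        loc = loci[li]
        mid = (loc.start + loc.end) // 2
        spacer = "".join(rng.choice(list("ACGT"), size=model.spacer_len))
        motif = core + spacer + core
        strand = "+" if rng.random() < 0.5 else "-"
        # prefer planting over a near-midpoint SNP, at a scored column
        snp_positions = [p for p in range(loc.start, loc.end)
                         if p in site_at and abs(p - mid) <= 80]
        start = None
        if snp_positions:
            pos = int(rng.choice(snp_positions))
            offsets = [o for o in model.scored_offsets()
                       if loc.start <= pos - o and pos - o + w <= loc.end]
            if offsets:
                start = pos - int(rng.choice(offsets))
        if start is None:
            lo = max(loc.start, mid - 80)
            hi = min(loc.end - w, mid + 80 - w)
            if hi < lo:
                lo, hi = loc.start, loc.end - w
            start = int(rng.integers(lo, hi + 1))
        inserted = motif if strand == "+" else reverse_complement(motif)
        codes = np.array([int(np.where(_BASES == b)[0][0]) for b in inserted])
        genome[start : start + w] = codes
        over = ""
        for p in range(start, start + w):
            if p in site_at:
                s = site_at[p]
                new_ref = str(_BASES[genome[p]])
                alts = [b for b in "ACGT" if b != new_ref]
                new_alt = str(rng.choice(alts))
                overrides[s.snp_id] = (new_ref, new_alt)
                over = s.snp_id
        plants.append(
            {
                "chrom": cfg.chrom,
                "start": start,
                "end": start + w,
                "strand": strand,
                "planted_sequence": inserted,
                "over_snp": over,
            }
        )
    sequence = "".join(_BASES[genome])
    plants_df = pd.DataFrame(
        plants, columns=["chrom", "start", "end", "strand", "planted_sequence", "over_snp"]
    )
    return sequence, plants_df, overrides


def sim_genotype_binding(
    cfg: SimConfig,
    allele_freq: float = 0.3,
    n_samples: int = 12,
    base_signal: float = 10.0,
    noise_sd: float = 1.0,
):
    """Hardy-Weinberg genotypes and dosage-dependent binding signal.

    signal = base * (2 - alt_dosage) / 2 + Normal(0, noise_sd), so samples
    homozygous for the alternate allele lose binding entirely (up to noise).
    Returns (genotypes, signals) DataFrames keyed by sample id.
    """
    if not (0 <= allele_freq <= 1):
        raise ValueError("allele_freq must be in [0, 1]")
    rng = _rng(cfg.seed, "genotype")
    dosage = rng.binomial(2, allele_freq, size=n_samples)
    signal = base_signal * (2 - dosage) / 2.0 + rng.normal(0, noise_sd, size=n_samples)
    samples = [f"sample_{i:02d}" for i in range(n_samples)]
    genotypes = pd.DataFrame({"sample": samples, "genotype": dosage})
    signals = pd.DataFrame({"sample": samples, "signal": signal})
    return genotypes, signals


_TF_POOL = [
    "NFKB1", "POLR2A", "EBF1", "PAX5", "RUNX3", "BATF", "IRF4", "STAT3",
    "SP1", "CTCF", "GATA4", "HNF4A", "FOXO4", "RELA", "JUN", "MYC",
]
_GENE_POOL = ["TLR1", "TLR6", "TLR10", "LINC0299X", "RPS26", "CCDC88", "GENE_A", "GENE_B"]

_CATEGORY_WEIGHTS = {
    "1a": 0.4, "1b": 1.5, "1c": 0.2, "1d": 1.0, "1e": 0.2, "1f": 8.0,
    "2a": 2.0, "2b": 8.0, "2c": 1.0, "3a": 4.0, "3b": 4.0,
    "4": 25.0, "5": 25.0, "6": 20.0,
}


def sim_regdb(cfg: SimConfig, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Regulatory-score table with the standard category vocabulary.

    Category frequencies are skewed toward the uninformative classes (4-6)
    with a high-evidence tail, mimicking a genome-wide score distribution.
    Categories 1a-1f carry eQTL genes; likely-affecting categories carry
    bound TFs drawn from a fixed pool.
    """
    rng = _rng(cfg.seed, "regdb")
    cats = list(_CATEGORY_WEIGHTS)
    probs = np.array(list(_CATEGORY_WEIGHTS.values()))
    probs = probs / probs.sum()
    rows = []
    for snp in snp_ids:
        cat = str(rng.choice(cats, p=probs))
        tfs: list[str] = []
        genes: list[str] = []
        if cat in ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c"):
            k = int(rng.integers(1, 5))
            tfs = sorted(rng.choice(_TF_POOL, size=k, replace=False))
        if cat.startswith("1"):
            genes = sorted(rng.choice(_GENE_POOL, size=int(rng.integers(1, 3)), replace=False))
        rows.append(
            {
                "snp_id": snp,
                "category": cat,
                "tfs": ";".join(tfs),
                "eqtl_genes": ";".join(genes),
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "category", "tfs", "eqtl_genes"])


def sim_background_peaks(cfg: SimConfig, stream: str = "peaks_b", n_sets: int = 2):
    """Uniformly placed peak sets with no planted structure (a second factor's
    cistrome for intersection exercises)."""
    rng = _rng(cfg.seed, stream)
    genome = cfg.genome_length_bp
    widths = np.maximum(
        50, rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, cfg.n_peaks)
    ).astype(np.int64)
    starts = rng.integers(0, np.maximum(1, genome - widths))
    intervals = [
        GenomicInterval(cfg.chrom, int(s), int(s + w)) for s, w in zip(starts, widths)
    ]
    return [
        PeakSet(f"factorB_{k + 1}", intervals[k::n_sets]) for k in range(n_sets)
    ]


def write_fixtures(cfg: SimConfig, outdir) -> dict:
    """Generate every pipeline input for one seed and write it to disk.

    Emits panel.vcf, catalog.tsv, peaks_*.bed (primary factor),
    peaks_b_*.bed (second factor), genome.fa, regdb.tsv, genotypes.tsv,
    signal.tsv and ground-truth side files under truth/.  Returns a dict of
    paths shaped like the pipeline's ``inputs`` config section.
    """
    from dataclasses import replace as _replace
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    panel = sim_panel(cfg)
    assocs, peak_sets, truth = sim_catalog_and_peaks(cfg, panel)
    loci = merge_consensus(peak_sets)
    model = default_dr3_model()
    sequence, plants, overrides = sim_sequences_with_motifs(cfg, loci, model, panel)
    for i, site in enumerate(panel.sites):
        if site.snp_id in overrides:
            ref, alt = overrides[site.snp_id]
            panel.sites[i] = _replace(site, ref=ref, alt=alt)

    paths: dict = {}
    cio.write_panel_vcf(panel, outdir / "panel.vcf")
    paths["panel_vcf"] = str(outdir / "panel.vcf")

    pos_of = {s.snp_id: s.pos for s in panel.sites}
    catalog = pd.DataFrame(
        [
            {
                "snp_id": a.snp_id,
                "chrom": cfg.chrom,
                "pos": pos_of[a.snp_id],
                "trait": a.trait,
                "study": "SIM0001",
            }
            for a in assocs
        ]
    )
    catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    paths["gwas_catalog"] = str(outdir / "catalog.tsv")

    paths["peak_beds"] = []
    for ps in peak_sets:
        p = outdir / f"peaks_{ps.name}.bed"
        cio.write_bed(ps, p)
        paths["peak_beds"].append(str(p))
    paths["peak_beds_b"] = []
    for ps in sim_background_peaks(cfg):
        p = outdir / f"peaks_{ps.name}.bed"
        cio.write_bed(ps, p)
        paths["peak_beds_b"].append(str(p))

    cio.write_fasta({cfg.chrom: sequence}, outdir / "genome.fa")
    paths["genome_fasta"] = str(outdir / "genome.fa")

    regdb = sim_regdb(cfg, [s.snp_id for s in panel.sites])
    regdb.to_csv(outdir / "regdb.tsv", sep="\t", index=False)
    paths["regdb"] = str(outdir / "regdb.tsv")

    genotypes, signals = sim_genotype_binding(cfg)
    genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    signals.to_csv(outdir / "signal.tsv", sep="\t", index=False)
    paths["genotypes"] = str(outdir / "genotypes.tsv")
    paths["signal"] = str(outdir / "signal.tsv")

    truth.to_csv(outdir / "truth" / "snp_coverage.tsv", sep="\t", index=False)
    plants.to_csv(outdir / "truth" / "motif_plants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"snp_id": k, "ref": v[0], "alt": v[1]}
            for k, v in sorted(overrides.items())
        ],
        columns=["snp_id", "ref", "alt"],
    ).to_csv(outdir / "truth" / "allele_overrides.tsv", sep="\t", index=False)
    return paths
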