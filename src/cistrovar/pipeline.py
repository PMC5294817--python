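"""Pipeline driver: chain merge -> ld-expand -> overlap -> enrich ->
motif-scan -> annotate -> intersect and write TSV/BED outputs plus a run
manifest.

Every stage is deterministic given its inputs, so re-running from a manifest
reproduces outputs byte-identically.  The driver is restartable: a stage is
re-executed only when one of its outputs is missing or an upstream stage ran;
regenerated outputs are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as cio
from .annotation import (
    RegScoreRecord,
    binding_by_genotype,
    score_distribution,
    tf_cooccurrence,
)
from .enrichment import results_to_frame, trait_enrichment
from .intervals import fractional_intersect, merge_consensus, overlap_snps
from .ld import LdConfig, expand_leads
from .motif import MotifModel, default_dr3_model, delta_lod, scan, snp_in_motif
from .io import read_pwm

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


DEFAULT_PARAMS = {
    "r2_min": 0.8,
    "maf_min": 0.05,
    "window_bp": 500_000,
    "min_fraction": 0.25,
    "reciprocal": False,
    "motif_threshold": None,  # None -> 80% of the model's maximal score
    "scan_flank": 100,        # scan +/- flank around each locus midpoint
    "scan_whole_locus": False,
    "m_policy": "tested",
    "alpha": 0.05,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class _Stage:
    name: str
    outputs: list


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the full integration pipeline.

    ``config`` has two keys: ``inputs`` (paths: peak_beds, gwas_catalog,
    panel_vcf, genome_fasta, regdb, optional pwm, peak_beds_b, genotypes,
    signal) and ``params`` (thresholds; see DEFAULT_PARAMS).  Outputs and a
    JSON manifest land in ``outdir``; any stage failure raises PipelineError
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.get("inputs", {}))
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cistrovar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    ran_any = False

    def needs(*outs) -> bool:
        nonlocal ran_any
        if ran_any or any(not Path(o).exists() for o in outs):
            ran_any = True
            return True
        return False

    def stage(name):
        def wrap(fn):
            def run(*a, **kw):
                try:
                    return fn(*a, **kw)
                except Exception as exc:
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return run
        return wrap

    try:
        # ---- merge -------------------------------------------------------
        consensus_bed = outdir / "consensus.bed"
        peak_sets = [cio.read_bed(p) for p in inputs["peak_beds"]]
        loci = merge_consensus(peak_sets)
        if needs(consensus_bed):
            stage("merge")(cio.write_consensus_bed)(loci, consensus_bed)
        per_set_loci = {ps.name: merge_consensus([ps]) for ps in peak_sets}

        # ---- ld-expand ---------------------------------------------------
        snps_tsv = outdir / "snps.tsv"
        assocs, leads, n_dropped = stage("ld-expand")(cio.read_gwas_catalog)(
            inputs["gwas_catalog"]
        )
        panel, _stats = stage("ld-expand")(cio.read_panel_vcf)(inputs["panel_vcf"])
        cfg = LdConfig(
            r2_min=params["r2_min"],
            maf_min=params["maf_min"],
            window_bp=params["window_bp"],
        )
        records, unmatched = stage("ld-expand")(expand_leads)(leads, panel, cfg)
        if unmatched:
            logger.info("%d lead SNPs absent from the panel: %s", len(unmatched), unmatched[:10])
        if needs(snps_tsv):
            cio.write_snps_tsv(records, snps_tsv)
        # proxies inherit every trait of their lead
        lead_traits: dict[str, list] = {}
        for a in assocs:
            lead_traits.setdefault(a.snp_id, []).append(a.trait)
        from .enrichment import TraitAssociation

        full_assocs = list(assocs)
        for r in records:
            if r.provenance == "PROXY":
                for trait in lead_traits.get(r.lead_id, []):
                    full_assocs.append(TraitAssociation(trait, r.snp_id, r.lead_id))

        # ---- overlap -----------------------------------------------------
        hits_tsv = outdir / "snp_peak_assignments.tsv"
        assignments, n_under = stage("overlap")(overlap_snps)(records, loci)
        if needs(hits_tsv):
            assignments.to_csv(hits_tsv, sep="\t", index=False)
        logger.info("%d distinct SNPs under consensus loci", n_under)

        # ---- enrich ------------------------------------------------------
        enrich_tsv = outdir / "enrichment.tsv"
        snps_under = {"combined": set(assignments["snp_id"])}
        for name, sloci in per_set_loci.items():
            a, _ = overlap_snps(records, sloci)
            snps_under[name] = set(a["snp_id"])
        results = stage("enrich")(trait_enrichment)(
            full_assocs, snps_under, m_policy=params["m_policy"]
        )
        if needs(enrich_tsv):
            frame = results_to_frame(results)
            frame["p_raw"] = frame["p_raw"].map("{:.6g}".format)
            frame["p_lower"] = frame["p_lower"].map("{:.6g}".format)
            frame["p_corrected"] = frame["p_corrected"].map("{:.6g}".format)
            frame.to_csv(enrich_tsv, sep="\t", index=False)

        # ---- motif-scan --------------------------------------------------
        motif_hits_tsv = outdir / "motif_hits.tsv"
        motif_annot_tsv = outdir / "motif_annotations.tsv"
        if "genome_fasta" not in inputs:
            raise PipelineError("stage 'motif-scan' failed: no genome FASTA supplied")
        genome = stage("motif-scan")(cio.read_fasta)(inputs["genome_fasta"])
        if inputs.get("pwm"):
            model = MotifModel(half_site_pwm=read_pwm(inputs["pwm"]))
            model.score_threshold = (
                params["motif_threshold"]
                if params["motif_threshold"] is not None
                else 0.8 * model.max_score()
            )
        else:
            model = default_dr3_model(params["motif_threshold"])
        all_hits = []
        for loc in loci:
            if params["scan_whole_locus"]:
                lo, hi = loc.start, loc.end
            else:
                mid = (loc.start + loc.end) // 2
                lo, hi = mid - params["scan_flank"], mid + params["scan_flank"]
            lo = max(0, lo)
            chrom_len = len(genome[loc.chrom])
            hi = min(hi, chrom_len)
            if hi - lo < model.width:
                continue
            seq = str(genome[loc.chrom][lo:hi])
            all_hits.extend(
                stage("motif-scan")(scan)(seq, model, chrom=loc.chrom, origin=lo)
            )
        if needs(motif_hits_tsv):
            pd.DataFrame(
                [
                    {
                        "chrom": h.chrom, "start": h.start, "end": h.end,
                        "strand": h.strand, "score": f"{h.score:.4f}",
                        "sequence": h.sequence,
                    }
                    for h in all_hits
                ],
                columns=["chrom", "start", "end", "strand", "score", "sequence"],
            ).to_csv(motif_hits_tsv, sep="\t", index=False)
        under_ids = set(assignments["snp_id"])
        under_records = [r for r in records if r.snp_id in under_ids]
        dedup = {}
        for r in under_records:
            dedup.setdefault(r.snp_id, r)
        annots = stage("motif-scan")(snp_in_motif)(list(dedup.values()), all_hits)
        rows = []
        for ann in annots:
            r = dedup[ann.snp_id]
            h = ann.hit
            lo = max(0, h.start - 5)
            hi = min(len(genome[h.chrom]), h.end + 5)
            context = str(genome[h.chrom][lo:hi])
            dl = stage("motif-scan")(delta_lod)(model, context, r, h, context_origin=lo)
            rows.append(
                {
                    "snp_id": ann.snp_id, "chrom": h.chrom, "start": h.start,
                    "end": h.end, "strand": h.strand,
                    "ref": r.ref, "alt": r.alt,
                    "lead_id": r.lead_id or r.snp_id,
                    "score": f"{h.score:.4f}",
                    "sequence": h.sequence,
                    "position_in_motif": ann.position_in_motif,
                    "delta_lod": f"{dl:.4f}",
                }
            )
        if needs(motif_annot_tsv):
            pd.DataFrame(
                rows,
                columns=[
                    "snp_id", "chrom", "start", "end", "strand", "ref", "alt",
                    "lead_id", "score", "sequence", "position_in_motif", "delta_lod",
                ],
            ).to_csv(motif_annot_tsv, sep="\t", index=False)

        # ---- annotate ----------------------------------------------------
        dist_tsv = outdir / "score_distribution.tsv"
        tf_tsv = outdir / "tf_frequency.tsv"
        if inputs.get("regdb"):
            reg_df = pd.read_csv(inputs["regdb"], sep="\t", dtype=str).fillna("")
            reg_records = [
                RegScoreRecord(
                    snp_id=row["snp_id"],
                    category=row["category"],
                    bound_tfs=frozenset(t for t in row["tfs"].split(";") if t),
                    eqtl_genes=tuple(g for g in row["eqtl_genes"].split(";") if g),
                )
                for _, row in reg_df.iterrows()
            ]
            sig_traits = {
                r.trait for r in results if r.p_corrected < params["alpha"] and r.k > 0
            }
            sig_snps = {
                s
                for r in results
                if r.trait in sig_traits and r.k > 0
                for s, _ in r.snps_under_peaks
            }
            snp_sets = {
                "all_snps": {r.snp_id for r in records},
                "under_peaks": under_ids,
                "trait_enriched": sig_snps,
            }
            dist = stage("annotate")(score_distribution)(snp_sets, reg_records)
            if needs(dist_tsv):
                dist.to_tsv(dist_tsv)
            tf_table = stage("annotate")(tf_cooccurrence)(under_ids, reg_records)
            if needs(tf_tsv):
                tf_table.to_csv(tf_tsv, sep="\t", index=False)

        # ---- intersect ---------------------------------------------------
        cobind_tsv = outdir / "cobinding.tsv"
        if inputs.get("peak_beds_b"):
            sets_b = [cio.read_bed(p) for p in inputs["peak_beds_b"]]
            loci_b = merge_consensus(sets_b)
            summary = stage("intersect")(fractional_intersect)(
                loci, loci_b, params["min_fraction"], params["reciprocal"]
            )
            if needs(cobind_tsv):
                summary.to_frame().to_csv(cobind_tsv, sep="\t", index=False)

        # ---- genotype-binding -------------------------------------------
        gb_tsv = outdir / "genotype_binding.tsv"
        if inputs.get("genotypes") and inputs.get("signal"):
            g = pd.read_csv(inputs["genotypes"], sep="\t")
            s = pd.read_csv(inputs["signal"], sep="\t")
            summary = stage("genotype-binding")(binding_by_genotype)(
                dict(zip(g["sample"], g["genotype"])),
                dict(zip(s["sample"], s["signal"])),
            )
            if needs(gb_tsv):
                summary.to_tsv(gb_tsv)

        # ---- manifest ----------------------------------------------------
        manifest = {
            "tool": "cistrovar",
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "params": {k: v for k, v in params.items()},
            "inputs": {
                k: (
                    [str(p) for p in v] if isinstance(v, (list, tuple)) else str(v)
                )
                for k, v in inputs.items()
            },
            "input_checksums": {
                str(p): _sha256(Path(p))
                for v in inputs.values()
                for p in (v if isinstance(v, (list, tuple)) else [v])
                if Path(str(p)).exists()
            },
            "n_consensus_loci": len(loci),
            "n_snps_universe": len({r.snp_id for r in records}),
            "n_snps_under_peaks": int(n_under),
            "catalog_rows_dropped": int(n_dropped),
        }
        cio.write_manifest(manifest, outdir / "manifest.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def rerun_from_manifest(manifest_path, outdir) -> Path:
    """Re-execute the pipeline with the inputs and thresholds a manifest records."""
    m = cio.read_manifest(manifest_path)
    config = {"inputs": m["inputs"], "params": m["params"]}
    return run_pipeline(config, outdir)
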