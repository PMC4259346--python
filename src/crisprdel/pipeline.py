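"""End-to-end orchestration: simulate -> variant QC -> allele counting ->
expression signatures / genotyping / loop calling, from one configuration,
with a reproduction report and a deterministic run manifest.

All randomness flows from the single configuration seed; re-running with
the same configuration reproduces the manifest fingerprint exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import allelecount, exprsig, genotyping, loopcall, simhybrid, variantqc
from .simhybrid import (ALLELE_A, ALLELE_B, SCREEN_ROSTER, DiploidReference,
                        SimulationConfig, SimulatedClone)

logger = logging.getLogger("crisprdel")


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    metrics: Dict[str, object]
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def fingerprint(self) -> str:
        """Checksum of the deterministic content (timings excluded)."""
        payload = json.dumps(
            {"seed": self.seed, "config": self.config_hash,
             "metrics": self.metrics, "files": self.files},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self) | {"fingerprint": self.fingerprint()},
                          indent=2, sort_keys=True, default=str)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self) -> None:
        self.seconds: Dict[str, float] = {}
        self._t0 = time.perf_counter()

    def mark(self, stage: str) -> None:
        t = time.perf_counter()
        self.seconds[stage] = round(t - self._t0, 3)
        self._t0 = t


def run_experiment(config: SimulationConfig,
                   roster: Optional[Sequence] = None,
                   outdir: Optional[str] = None,
                   wt_clone: Optional[str] = None) -> Tuple[RunManifest, str]:
    """Run the full synthetic experiment and analysis.

    Returns (manifest, markdown report).  Headline metrics: deletion
    frequency, knockout-allele expression ratio, total focal-gene
    reduction per genotype class, signature sizes, and loop calls.
    """
    roster = list(roster) if roster is not None else list(SCREEN_ROSTER)
    timer = _StageTimer()

    ref = simhybrid.build_reference(config)
    logger.info("reference: %d variants planted across %d chromosomes",
                len(ref.variants), len(ref.haplotypes[ALLELE_A]))
    clones = simhybrid.simulate_clones(ref, roster, config)
    truth = {c.genotype.clone_id: c.genotype for c in clones}
    if wt_clone is None:
        wt_candidates = [cid for cid, gt in truth.items() if gt.true_label == "WT"]
        if not wt_candidates:
            raise ValueError("roster contains no WT clone to anchor the analysis")
        wt_clone = wt_candidates[0]
    timer.mark("simulate")

    # --- genotyping assays ------------------------------------------------
    ct = pd.concat([simhybrid.simulate_qpcr(c.genotype, ref, config) for c in clones],
                   ignore_index=True)
    amplicons = {c.genotype.clone_id: simhybrid.simulate_junctions(c, ref, config)
                 for c in clones}
    screens = {cid: genotyping.pcr_screen(amps) for cid, amps in amplicons.items()}
    n_product = sum(s["product_detected"] for s in screens.values())
    diag = simhybrid.diagnostic_variants(ref, config)
    calls = genotyping.genotype_clones(ct, wt_clone, amplicons, diag, ref)
    calls = calls.set_index("clone_id")
    n_mono = int((calls["call"] == "monoallelic").sum())
    n_bi = int((calls["call"] == "biallelic").sum())
    freq = genotyping.deletion_frequency(n_mono, n_bi, len(roster))
    logger.info("genotyping: %d/%d product-positive, %d monoallelic, %d biallelic, "
                "deletion frequency %.4f", n_product, len(roster), n_mono, n_bi, float(freq))
    timer.mark("genotyping")

    # --- variant QC -------------------------------------------------------
    dna = simhybrid.simulate_dna_counts(ref, config)
    qc_table, bias_report = variantqc.run_variant_qc(ref, dna, config.read_length)
    n_usable = int(qc_table["usable"].sum())
    logger.info("variantqc: %d/%d variants usable (%d mapping-bias, %d cnv, %d poor-het)",
                n_usable, len(qc_table), int(qc_table["mapping_bias"].sum()),
                int(qc_table["cnv_bias"].sum()), int(qc_table["poor_het"].sum()))
    timer.mark("variantqc")

    # --- RNA-seq, allele counting, expression ----------------------------
    matrices = []
    for clone in clones:
        reads = simhybrid.simulate_rnaseq(clone.genotype, ref, config)
        matrices.append(allelecount.count_reads(reads, ref, qc_table,
                                                clone.genotype.clone_id))
    matrix = pd.concat(matrices, ignore_index=True)
    specificity = allelecount.allele_specificity(matrix)
    focal = ref.focal_gene.name

    deleted_alleles = {
        cid: row["deleted_allele"] for cid, row in calls.iterrows()
        if row["call"] == "monoallelic" and row["deleted_allele"] in (ALLELE_A, ALLELE_B)}
    ko_ratio = (allelecount.knockout_allele_ratio(matrix, deleted_alleles, focal)
                if deleted_alleles else float("nan"))

    lengths = {g.name: g.length_bp for g in ref.genes}
    libs = matrix.groupby("clone")["total"].sum().to_dict()
    counts = matrix.rename(columns={"total": "count"})[["gene", "clone", "count"]]
    expr = exprsig.fpkm(counts, lengths, libs)
    wide = expr.pivot_table(index="gene", columns="clone", values="fpkm")
    wt_focal = wide.loc[focal, wt_clone]

    def _reduction(label: str) -> float:
        ids = [cid for cid, gt in truth.items() if gt.true_label == label]
        if not ids or wt_focal == 0:
            return float("nan")
        return float(np.mean([100.0 * (1.0 - wide.loc[focal, cid] / wt_focal)
                              for cid in ids]))

    reduction_bi = _reduction("biallelic")
    reduction_mono = float(np.mean([
        100.0 * (1.0 - wide.loc[focal, cid] / wt_focal)
        for cid, gt in truth.items() if gt.true_label.startswith("monoallelic")
    ])) if any(gt.true_label.startswith("monoallelic") for gt in truth.values()) else float("nan")

    bi_called = [cid for cid, row in calls.iterrows() if row["call"] == "biallelic"]
    if bi_called:
        sig_calls = exprsig.call_signature(expr, wt_clone, bi_called[0])
        up, down = exprsig.signature_lists(sig_calls)
    else:
        up, down = [], []
    logger.info("expression: knockout-allele ratio %.4f, %d up / %d down signature genes",
                ko_ratio, len(up), len(down))
    timer.mark("expression")

    # --- Hi-C loop profile ------------------------------------------------
    fragments, contacts = simhybrid.simulate_hic(ref, config)
    anchor = contacts["frag_i"].iloc[0]
    profile = loopcall.profile_fragments(fragments, contacts, anchor)
    enh_chrom, enh_s, enh_e = ref.enhancer
    overlaps_enh = ((profile["chrom"] == enh_chrom)
                    & (profile["start"] < enh_e) & (profile["end"] > enh_s))
    loop_at_enhancer = bool((profile["looping"] & overlaps_enh).any())
    n_loops = int(profile["looping"].sum())
    logger.info("loopcall: %d looping fragments; enhancer loop %s",
                n_loops, "detected" if loop_at_enhancer else "not detected")
    timer.mark("hic")

    metrics = {
        "n_clones": len(roster),
        "n_product_positive": n_product,
        "n_monoallelic": n_mono,
        "n_biallelic": n_bi,
        "deletion_frequency": float(freq),
        "knockout_allele_ratio": ko_ratio,
        "focal_reduction_biallelic_pct": reduction_bi,
        "focal_reduction_monoallelic_pct": reduction_mono,
        "n_signature_up": len(up),
        "n_signature_down": len(down),
        "n_variants": len(qc_table),
        "n_variants_usable": n_usable,
        "n_looping_fragments": n_loops,
        "loop_at_enhancer": loop_at_enhancer,
    }

    report = _report(truth, calls, screens, specificity, wide, focal, wt_clone, metrics)

    files: Dict[str, str] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        ref_out = dataclasses.replace(ref)
        ref_out.variants = qc_table
        written = {
            "haplotype_CAST.fa": lambda p: simhybrid.write_fasta(ref.haplotypes[ALLELE_A], p),
            "haplotype_129.fa": lambda p: simhybrid.write_fasta(ref.haplotypes[ALLELE_B], p),
            "variants.vcf": lambda p: simhybrid.write_vcf(ref_out, p),
            "genes.bed": lambda p: open(p, "w").write(simhybrid.genes_bed(ref.genes)),
            "ct.tsv": lambda p: ct.to_csv(p, sep="\t", index=False),
            "allele_counts.tsv": lambda p: matrix.to_csv(p, sep="\t", index=False),
            "specificity.tsv": lambda p: specificity.to_csv(p, sep="\t", index=False),
            "genotype_calls.tsv": lambda p: calls.to_csv(p, sep="\t"),
            "loop_profile.tsv": lambda p: profile.to_csv(p, sep="\t", index=False),
            "report.md": lambda p: open(p, "w").write(report),
        }
        for name, writer in written.items():
            path = os.path.join(outdir, name)
            writer(path)
            files[name] = _sha256(path)

    manifest = RunManifest(
        seed=config.seed,
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        metrics=metrics, stage_seconds=timer.seconds, files=files)
    if outdir is not None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    return manifest, report


def _report(truth, calls, screens, specificity, wide, focal, wt_clone, metrics) -> str:
    s_focal = specificity[specificity["gene"] == focal].set_index("clone")["s"]
    lines = [
        "# Synthetic enhancer-deletion experiment: reproduction report", "",
        f"- clones screened: {metrics['n_clones']}",
        f"- junction-PCR product-positive: {metrics['n_product_positive']}",
        f"- copy-number calls: {metrics['n_monoallelic']} monoallelic, "
        f"{metrics['n_biallelic']} biallelic",
        f"- deletion frequency: {metrics['deletion_frequency']:.4f} "
        f"({100 * metrics['deletion_frequency']:.2f}%)",
        f"- knockout-allele / intact-allele focal expression: "
        f"{metrics['knockout_allele_ratio']:.4f}",
        f"- total focal reduction: biallelic "
        f"{metrics['focal_reduction_biallelic_pct']:.1f}%, monoallelic "
        f"{metrics['focal_reduction_monoallelic_pct']:.1f}%",
        f"- signature genes (biallelic vs {wt_clone}): "
        f"{metrics['n_signature_up']} up, {metrics['n_signature_down']} down",
        f"- looping fragments: {metrics['n_looping_fragments']} "
        f"(enhancer loop detected: {metrics['loop_at_enhancer']})",
        "",
        "| clone | true label | product | copy number | call | deleted allele "
        "| focal FPKM vs WT | focal specificity s |",
        "|---|---|---|---|---|---|---|---|",
    ]
    wt_focal = wide.loc[focal, wt_clone]
    for cid, gt in truth.items():
        row = calls.loc[cid]
        rel = wide.loc[focal, cid] / wt_focal if wt_focal else float("nan")
        lines.append(
            f"| {cid} | {gt.true_label} | {screens[cid]['product_detected']} "
            f"| {row['relative_copy_number']:.2f} | {row['call']} "
            f"| {row['deleted_allele']} | {rel:.3f} | {s_focal.get(cid, float('nan')):.2f} |")
    return "\n".join(lines) + "\n"


def make_fixtures(outdir: str, config: Optional[SimulationConfig] = None) -> RunManifest:
    """Write a small frozen dataset (reference pair, VCF, reads, Ct table,
    contacts, junction amplicons) for the test suite; regenerates
    byte-identically from the pinned seed."""
    if config is None:
        config = SimulationConfig(seed=7, n_reads_per_clone=2_000, snp_density=1.0)
    os.makedirs(outdir, exist_ok=True)
    ref = simhybrid.build_reference(config)
    roster = [("MutA", "biallelic"), ("MutC", "monoallelic_129"), ("WT1", "WT")]
    clones = simhybrid.simulate_clones(ref, roster, config)

    simhybrid.write_fasta(ref.haplotypes[ALLELE_A], os.path.join(outdir, "haplotype_CAST.fa"))
    simhybrid.write_fasta(ref.haplotypes[ALLELE_B], os.path.join(outdir, "haplotype_129.fa"))
    simhybrid.write_vcf(ref, os.path.join(outdir, "variants.vcf"))
    with open(os.path.join(outdir, "genes.bed"), "w") as fh:
        fh.write(simhybrid.genes_bed(ref.genes))

    n_reads = {}
    ct_tables = []
    amp_records = {}
    for clone in clones:
        cid = clone.genotype.clone_id
        reads = simhybrid.simulate_rnaseq(clone.genotype, ref, config)
        simhybrid.write_fastq(reads, os.path.join(outdir, f"reads_{cid}.fastq"))
        reads.drop(columns="seq").to_csv(
            os.path.join(outdir, f"truth_{cid}.tsv"), sep="\t", index=False)
        n_reads[cid] = len(reads)
        ct_tables.append(simhybrid.simulate_qpcr(clone.genotype, ref, config))
        amp_records[cid] = simhybrid.simulate_junctions(clone, ref, config)
    pd.concat(ct_tables, ignore_index=True).to_csv(
        os.path.join(outdir, "ct.tsv"), sep="\t", index=False)
    simhybrid.write_fasta(
        {name: seq for amps in amp_records.values() for name, seq in amps},
        os.path.join(outdir, "junctions.fa"))
    fragments, contacts = simhybrid.simulate_hic(ref, config)
    fragments.to_csv(os.path.join(outdir, "fragments.tsv"), sep="\t", index=False)
    contacts.to_csv(os.path.join(outdir, "contacts.tsv"), sep="\t", index=False)

    files = {name: _sha256(os.path.join(outdir, name)) for name in sorted(os.listdir(outdir))}
    manifest = RunManifest(
        seed=config.seed,
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        metrics={"n_reads": n_reads, "n_variants": len(ref.variants)},
        files=files)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest
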