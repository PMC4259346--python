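"""Allele-specific read counting in the CAST x 129 hybrid.

Each RNA-seq read is placed on its gene (placements are exact in this
pipeline — from simulation ground truth or an exact-match table) and
compared with both haplotype sequences over its window.  Reads matching
exactly one haplotype are assigned to that allele; ties, windows without
a usable (QC-passing) variant, or conflicting evidence leave the read
unassigned.  When neither haplotype matches exactly (sequencing errors),
a per-SNP majority vote over the usable SNPs in the window decides, with
ties again unassigned.

Per-gene counts feed the allele-specificity statistic

    s = log2((c_CAST + 10) / (c_129 + 10)),

a pseudo-count-10 log ratio: 0 for balanced genes, positive for
CAST-specific expression, and exactly antisymmetric under swapping the
haplotype labels.  The pseudo-count applies only to this statistic, never
to the stored counts.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .simhybrid import ALLELE_A, ALLELE_B, DiploidReference, GeneModel

UNASSIGNED = "unassigned"
COUNT_COLUMNS = ["gene", "clone", "c_CAST", "c_129", "c_unassigned", "total"]


class UsableVariantIndex:
    """Fast overlap queries against the usable variants, on either
    coordinate frame (A = CAST/reference, B = 129/alternate)."""

    def __init__(self, variants: pd.DataFrame):
        usable = variants[variants["usable"]]
        self._by_chrom: Dict[str, dict] = {}
        for chrom, sub in usable.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            a0 = sub["pos"].to_numpy() - 1
            b0 = sub["pos_b"].to_numpy() - 1
            self._by_chrom[chrom] = {
                "a_start": a0, "a_end": a0 + sub["ref"].str.len().to_numpy(),
                "b_start": b0, "b_end": b0 + sub["alt"].str.len().to_numpy(),
                "ref": sub["ref"].to_numpy(), "alt": sub["alt"].to_numpy(),
                "is_snp": (sub["kind"] == "SNP").to_numpy(),
            }

    def overlapping(self, chrom: str, lo: int, hi: int, frame: str) -> np.ndarray:
        """Indices of usable variants whose span on ``frame`` intersects [lo, hi)."""
        tab = self._by_chrom.get(chrom)
        if tab is None:
            return np.empty(0, dtype=int)
        starts, ends = tab[f"{frame}_start"], tab[f"{frame}_end"]
        i = np.searchsorted(starts, lo - 8, side="left")  # spans are <= 4 bp
        j = np.searchsorted(starts, hi, side="left")
        cand = np.arange(i, j)
        return cand[(ends[cand] > lo) & (starts[cand] < hi)]

    def table(self, chrom: str) -> Optional[dict]:
        return self._by_chrom.get(chrom)


def assign_read(seq: str, chrom: str, start_a: int, start_b: int,
                haplotypes: Dict[str, Dict[str, str]],
                index: UsableVariantIndex) -> str:
    """Assign one genomic-orientation read placed at ``start_a`` (CAST frame)
    / ``start_b`` (129 frame) to an allele, or leave it unassigned."""
    L = len(seq)
    ov_a = index.overlapping(chrom, start_a, start_a + L, "a")
    ov_b = index.overlapping(chrom, start_b, start_b + L, "b")
    if len(ov_a) == 0 and len(ov_b) == 0:
        return UNASSIGNED
    win_a = haplotypes[ALLELE_A][chrom][start_a:start_a + L]
    win_b = haplotypes[ALLELE_B][chrom][start_b:start_b + L]
    match_a, match_b = seq == win_a, seq == win_b
    if match_a and not match_b:
        return ALLELE_A
    if match_b and not match_a:
        return ALLELE_B
    if match_a and match_b:
        return UNASSIGNED
    # neither window matches exactly: tolerate sequencing errors with a
    # per-SNP majority vote; sites matching neither haplotype are ignored
    tab = index.table(chrom)
    votes = 0
    n_sites = 0
    for i in np.union1d(ov_a, ov_b):
        if not tab["is_snp"][i]:
            continue
        vote_a = vote_b = False
        off_a = tab["a_start"][i] - start_a
        if 0 <= off_a < L:
            vote_a = seq[off_a] == tab["ref"][i]
        off_b = tab["b_start"][i] - start_b
        if 0 <= off_b < L:
            vote_b = seq[off_b] == tab["alt"][i]
        if vote_a == vote_b:
            continue
        n_sites += 1
        votes += 1 if vote_a else -1
    if n_sites == 0 or votes == 0:
        return UNASSIGNED
    return ALLELE_A if votes > 0 else ALLELE_B


def _distinct_loci(placements: List[Tuple[str, str, int]], ref: DiploidReference,
                   tol: int = 10) -> int:
    """Number of distinct reference-frame loci among mapper placements
    (homologous placements on the two haplotypes count once)."""
    loci: List[Tuple[str, int]] = []
    for hap, chrom, pos in placements:
        pos_a = pos if hap == ALLELE_A else ref.lift_to_a(chrom, pos)
        if not any(c == chrom and abs(p - pos_a) <= tol for c, p in loci):
            loci.append((chrom, pos_a))
    return len(loci)


def count_reads(reads: pd.DataFrame, ref: DiploidReference, variants: pd.DataFrame,
                clone_id: str, genes: Optional[List[GeneModel]] = None,
                mapper: Optional[Callable] = None) -> pd.DataFrame:
    """Assign every read and aggregate per-gene allele counts for one clone.

    ``reads`` is the placement table (read_id, gene, tstart, strand, seq).
    With ``mapper`` given, reads whose sequence has multiple distinct
    genome placements are treated as conflicting evidence (unassigned),
    emulating an aligner's unique-mapping requirement.
    """
    genes = genes if genes is not None else ref.genes
    gene_by_name = {g.name: g for g in genes}
    index = UsableVariantIndex(variants)
    bounds = {}
    for g in genes:
        bounds[g.name] = (
            g.start, ref.lift_to_b(g.chrom, g.start),
            g.end, ref.lift_to_b(g.chrom, g.end))
    counts = {g.name: {ALLELE_A: 0, ALLELE_B: 0, UNASSIGNED: 0} for g in genes}

    for row in reads.itertuples():
        g = gene_by_name[row.gene]
        if row.strand != g.strand:
            continue  # dUTP protocol: antisense placements are discarded
        L = len(row.seq)
        ga, gb, ea, eb = bounds[g.name]
        if g.strand == "+":
            gseq = row.seq
            start_a, start_b = ga + row.tstart, gb + row.tstart
        else:
            gseq = reverse_complement(row.seq)
            start_a, start_b = ea - row.tstart - L, eb - row.tstart - L
        if mapper is not None and _distinct_loci(mapper(gseq), ref) > 1:
            counts[g.name][UNASSIGNED] += 1
            continue
        counts[g.name][assign_read(gseq, g.chrom, start_a, start_b,
                                   ref.haplotypes, index)] += 1

    rows = [
        {"gene": name, "clone": clone_id,
         "c_CAST": c[ALLELE_A], "c_129": c[ALLELE_B],
         "c_unassigned": c[UNASSIGNED],
         "total": c[ALLELE_A] + c[ALLELE_B] + c[UNASSIGNED]}
        for name, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def allele_specificity(matrix: pd.DataFrame, pseudo: float = 10.0) -> pd.DataFrame:
    """Per (gene, clone) allele-specificity s = log2((c_CAST+10)/(c_129+10))."""
    out = matrix[["gene", "clone"]].copy()
    # difference of logs rather than log of ratio: label-swap antisymmetry
    # then holds exactly, not merely to rounding
    out["s"] = np.log2(matrix["c_CAST"] + pseudo) - np.log2(matrix["c_129"] + pseudo)
    return out


def knockout_allele_ratio(matrix: pd.DataFrame, deleted_alleles: Dict[str, str],
                          focal_gene: str) -> float:
    """Mean (deleted-allele count) / (intact-allele count) of the focal gene
    across monoallelic clones.  ``deleted_alleles`` maps each monoallelic
    clone id to its deleted allele ("CAST" or "129")."""
    if not deleted_alleles:
        raise ValueError("no monoallelic clones supplied")
    ratios = []
    focal = matrix[matrix["gene"] == focal_gene].set_index("clone")
    for clone, allele in deleted_alleles.items():
        row = focal.loc[clone]
        deleted = row["c_CAST"] if allele == ALLELE_A else row["c_129"]
        intact = row["c_129"] if allele == ALLELE_A else row["c_CAST"]
        if intact == 0:
            raise ValueError(f"{clone}: intact-allele count is zero; ratio undefined")
        ratios.append(deleted / intact)
    return float(np.mean(ratios))
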