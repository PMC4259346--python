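"""Variant blacklisting for allele-specific analysis.

Three independent screens remove variants whose allelic evidence is
untrustworthy before any read is assigned to a haplotype:

1. **Dummy-read mapping bias** — error-free reads are tiled across each
   SNP/indel from both haplotypes and mapped back to the combined diploid
   index; a variant whose two haplotypes recover unequal numbers of
   uniquely-and-correctly-mapped reads is reference-biased.  SNPs with
   bias > 5% and indels with bias > 10% are flagged (strict inequality).
2. **Allelic copy-number balance** — genomic DNA should cover both
   haplotypes equally; a two-sided exact binomial test against 1:1,
   Benjamini-Hochberg corrected at 5% FDR, flags imbalanced variants.
3. **Heterozygous-call quality** — a one-sided binomial test that the
   minor-allele fraction in genomic DNA reaches ``min_minor_frac``
   (default 0.15); rejection at 5% FDR flags the variant as a poor
   heterozygous call.

``bias`` is defined as |m_A - m_B| / max(m_A, m_B) over correctly and
uniquely mapped dummy reads (1 when nothing maps): symmetric, in [0, 1],
and directly comparable to percent thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simhybrid import ALLELE_A, ALLELE_B, ALLELES, DiploidReference

SNP_BIAS_THRESHOLD = 0.05
INDEL_BIAS_THRESHOLD = 0.10

BIAS_REPORT_COLUMNS = ["chrom", "pos", "n_dummy_A", "n_dummy_B", "m_A", "m_B", "bias_score"]


class DummyRead(NamedTuple):
    seq: str
    haplotype: str
    locus: Tuple[str, str, int]  # (haplotype, chrom, 0-based start) of origin


# ---------------------------------------------------------------------------
# dummy-read generation
# ---------------------------------------------------------------------------

def _affected_span(variant, haplotype: str) -> Tuple[int, int]:
    """0-based half-open span of the variant's allele on one haplotype."""
    if haplotype == ALLELE_A:
        return variant.pos - 1, variant.pos - 1 + len(variant.ref)
    return variant.pos_b - 1, variant.pos_b - 1 + len(variant.alt)


def generate_dummy_reads(variant, ref: DiploidReference, read_length: int) -> List[DummyRead]:
    """Every ``read_length``-mer from each haplotype whose window overlaps
    the variant's affected span (truncated to windows that fit on the
    chromosome).  ``variant`` is a row of the variant table (itertuples or
    Series with chrom/pos/pos_b/ref/alt attributes).
    """
    reads: List[DummyRead] = []
    chrom = variant.chrom
    for hap in ALLELES:
        seq = ref.haplotypes[hap][chrom]
        if read_length > len(seq):
            raise ValueError("read_length exceeds chromosome length")
        span_s, span_e = _affected_span(variant, hap)
        lo = max(0, span_s - read_length + 1)
        hi = min(span_e - 1, len(seq) - read_length)
        for s in range(lo, hi + 1):
            reads.append(DummyRead(seq[s:s + read_length], hap, (hap, chrom, s)))
    return reads


# ---------------------------------------------------------------------------
# default mapper: exact-match lookup over both haplotypes
# ---------------------------------------------------------------------------

class ExactMatchMapper:
    """Deterministic mapping contract: all exact full-length occurrences of
    a read across the combined diploid index, found via a k-mer-seeded
    dictionary.  Any real aligner honouring the same return signature
    (list of (haplotype, chrom, 0-based pos)) can be substituted.
    """

    def __init__(self, haplotypes: Dict[str, Dict[str, str]], k: int = 16):
        self.k = k
        self.haplotypes = haplotypes
        index: Dict[str, list] = {}
        for hap, chroms in haplotypes.items():
            for chrom, seq in chroms.items():
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i:i + k], []).append((hap, chrom, i))
        self._index = index

    def map(self, seq: str) -> List[Tuple[str, str, int]]:
        if len(seq) < self.k:
            raise ValueError("query shorter than the index k-mer size")
        hits = []
        for hap, chrom, pos in self._index.get(seq[:self.k], ()):
            target = self.haplotypes[hap][chrom]
            if target[pos:pos + len(seq)] == seq:
                hits.append((hap, chrom, pos))
        return hits

    __call__ = map


# ---------------------------------------------------------------------------
# bias assessment and filtering
# ---------------------------------------------------------------------------

def assess_mapping_bias(reads: Sequence[DummyRead],
                        mapper: Callable[[str], List[Tuple[str, str, int]]]) -> dict:
    """Bias report for one variant's dummy reads.

    A read counts toward m_h iff it maps uniquely (a single placement in
    the combined diploid index) and that placement is its true locus.
    """
    if not reads:
        raise ValueError("empty dummy-read set")
    n = {ALLELE_A: 0, ALLELE_B: 0}
    m = {ALLELE_A: 0, ALLELE_B: 0}
    for read in reads:
        n[read.haplotype] += 1
        placements = mapper(read.seq)
        if len(placements) == 1 and placements[0] == read.locus:
            m[read.haplotype] += 1
    top = max(m[ALLELE_A], m[ALLELE_B])
    bias = abs(m[ALLELE_A] - m[ALLELE_B]) / top if top > 0 else 1.0
    return {"n_dummy_A": n[ALLELE_A], "n_dummy_B": n[ALLELE_B],
            "m_A": m[ALLELE_A], "m_B": m[ALLELE_B], "bias_score": bias}


def assess_variants(ref: DiploidReference, read_length: int,
                    mapper: Optional[Callable] = None) -> pd.DataFrame:
    """BiasReport over the whole variant table (one row per variant)."""
    if mapper is None:
        mapper = ExactMatchMapper(ref.haplotypes, k=min(16, read_length))
    rows = []
    for variant in ref.variants.itertuples():
        rep = assess_mapping_bias(generate_dummy_reads(variant, ref, read_length), mapper)
        rows.append({"chrom": variant.chrom, "pos": variant.pos, **rep})
    return pd.DataFrame(rows, columns=BIAS_REPORT_COLUMNS)


def filter_mapping_bias(variants: pd.DataFrame, report: pd.DataFrame,
                        snp_thresh: float = SNP_BIAS_THRESHOLD,
                        indel_thresh: float = INDEL_BIAS_THRESHOLD) -> pd.DataFrame:
    """Set the mapping_bias flag where bias_score strictly exceeds the
    kind-specific threshold.  Returns an updated copy."""
    merged = variants.merge(report[["chrom", "pos", "bias_score"]],
                            on=["chrom", "pos"], how="left", validate="1:1")
    if merged["bias_score"].isna().any():
        raise ValueError("bias report does not cover all variants")
    thresh = np.where(merged["kind"] == "SNP", snp_thresh, indel_thresh)
    out = variants.copy()
    out["mapping_bias"] = (merged["bias_score"].to_numpy() > thresh)
    return update_usable(out)


def cnv_balance_filter(variants: pd.DataFrame, dna_counts: pd.DataFrame,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Flag cnv_bias where a two-sided exact binomial test of the genomic
    DNA allele split against 1:1 rejects at BH-adjusted ``fdr``.  Variants
    with zero DNA coverage are untestable and flagged poor_het instead."""
    merged = variants.merge(dna_counts, on=["chrom", "pos"], how="left", validate="1:1")
    c_a = merged["c_A"].to_numpy()
    c_b = merged["c_B"].to_numpy()
    total = c_a + c_b
    testable = total > 0
    pvals = np.array([
        stats.binomtest(int(a), int(t), 0.5).pvalue
        for a, t in zip(c_a[testable], total[testable])
    ])
    out = variants.copy()
    flags = np.zeros(len(out), dtype=bool)
    if pvals.size:
        rejected = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
        flags[np.flatnonzero(testable)] = rejected
    out["cnv_bias"] = out["cnv_bias"].to_numpy() | flags
    out["poor_het"] = out["poor_het"].to_numpy() | ~testable
    return update_usable(out)


def het_quality_filter(variants: pd.DataFrame, dna_counts: pd.DataFrame,
                       fdr: float = 0.05, min_minor_frac: float = 0.15) -> pd.DataFrame:
    """Flag poor_het where a one-sided binomial test rejects that the
    minor-allele fraction reaches ``min_minor_frac`` (BH at ``fdr``)."""
    merged = variants.merge(dna_counts, on=["chrom", "pos"], how="left", validate="1:1")
    c_a = merged["c_A"].to_numpy()
    c_b = merged["c_B"].to_numpy()
    total = c_a + c_b
    minor = np.minimum(c_a, c_b)
    testable = total > 0
    pvals = stats.binom.cdf(minor[testable], total[testable], min_minor_frac)
    out = variants.copy()
    flags = np.zeros(len(out), dtype=bool)
    if pvals.size:
        rejected = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
        flags[np.flatnonzero(testable)] = rejected
    out["poor_het"] = out["poor_het"].to_numpy() | flags | ~testable
    return update_usable(out)


def update_usable(variants: pd.DataFrame) -> pd.DataFrame:
    variants = variants.copy()
    variants["usable"] = ~(
        variants["mapping_bias"] | variants["cnv_bias"] | variants["poor_het"])
    return variants


def run_variant_qc(ref: DiploidReference, dna_counts: pd.DataFrame,
                   read_length: int = 100, fdr: float = 0.05,
                   min_minor_frac: float = 0.15,
                   mapper: Optional[Callable] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All three screens in sequence; returns (variant table, bias report)."""
    report = assess_variants(ref, read_length, mapper=mapper)
    table = filter_mapping_bias(ref.variants, report)
    table = cnv_balance_filter(table, dna_counts, fdr=fdr)
    table = het_quality_filter(table, dna_counts, fdr=fdr, min_minor_frac=min_minor_frac)
    return table, report


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (the same procedure the filters use)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
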