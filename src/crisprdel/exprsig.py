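"""Expression quantification, signature calling and enrichment tests.

FPKM is computed as count * 1e9 / (exonic_length_bp * mapped_reads).
Signature genes between a knockout and a wild-type clone are called with
a pseudo-count-4 three-fold rule:

    fold = (FPKM_mut + 4) / (FPKM_wt + 4)
    up   if fold >= 3,   down if fold <= 1/3,   none otherwise

(the boundary value 3 is inclusive).  The calls are invariant under any
common rescaling of both libraries, and the up-list of (A, B) equals the
down-list of (B, A).

Two exact-binomial set statistics accompany the calls: an enrichment test
for transcription-factor binding among down- vs up-regulated genes
(two-sided, null = pooled bound fraction of both lists), and a
directional overlap test between two signatures against the expectation
|A||B|/U from a gene universe of size U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

PSEUDO_FPKM = 4.0
FOLD_CUTOFF = 3.0


def fpkm(counts: pd.DataFrame, gene_lengths: Mapping[str, int],
         library_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Add an FPKM column to a (gene, clone, count) table.

    ``library_sizes`` maps clone -> total mapped reads; zero is an error.
    """
    for clone, n in library_sizes.items():
        if n <= 0:
            raise ValueError(f"library size for {clone} must be > 0")
    out = counts.copy()
    lengths = out["gene"].map(gene_lengths)
    if lengths.isna().any():
        missing = sorted(out.loc[lengths.isna(), "gene"].unique())
        raise KeyError(f"missing gene lengths: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    libs = out["clone"].map(library_sizes)
    out["fpkm"] = out["count"] * 1e9 / (lengths * libs)
    return out


def call_signature(expr: pd.DataFrame, wt_clone: str, mut_clone: str,
                   pseudo: float = PSEUDO_FPKM, fold: float = FOLD_CUTOFF) -> pd.DataFrame:
    """Per-gene fold change and signature call for one mutant vs one
    wild-type clone, from a (gene, clone, fpkm) table."""
    wide = expr.pivot_table(index="gene", columns="clone", values="fpkm")
    for clone in (wt_clone, mut_clone):
        if clone not in wide.columns:
            raise KeyError(f"clone {clone!r} absent from expression table")
    ratio = (wide[mut_clone] + pseudo) / (wide[wt_clone] + pseudo)
    call = np.where(ratio >= fold, "up", np.where(ratio <= 1.0 / fold, "down", "none"))
    return pd.DataFrame({
        "gene": wide.index, "fpkm_wt": wide[wt_clone].to_numpy(),
        "fpkm_mut": wide[mut_clone].to_numpy(),
        "fold_change": ratio.to_numpy(), "signature_call": call,
    }).reset_index(drop=True)


def signature_lists(calls: pd.DataFrame) -> Tuple[list, list]:
    """(up, down) gene lists from a call_signature table."""
    up = sorted(calls.loc[calls["signature_call"] == "up", "gene"])
    down = sorted(calls.loc[calls["signature_call"] == "down", "gene"])
    return up, down


@dataclass(frozen=True)
class EnrichmentResult:
    k_down_bound: int
    n_down: int
    k_up_bound: int
    n_up: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k_down_bound <= self.n_down and 0 <= self.k_up_bound <= self.n_up):
            raise ValueError("bound counts must satisfy 0 <= k <= n")


def promoter_binding_enrichment(down_genes: Sequence[str], up_genes: Sequence[str],
                                bound_genes: Iterable[str]) -> EnrichmentResult:
    """Two-sided exact binomial test of the bound fraction among
    down-regulated genes against the pooled bound fraction of both lists."""
    if not down_genes or not up_genes:
        raise ValueError("both signature lists must be non-empty")
    bound: Set[str] = set(bound_genes)
    k_down = sum(g in bound for g in down_genes)
    k_up = sum(g in bound for g in up_genes)
    n_down, n_up = len(down_genes), len(up_genes)
    p0 = (k_down + k_up) / (n_down + n_up)
    p_value = stats.binomtest(k_down, n_down, p0, alternative="two-sided").pvalue
    return EnrichmentResult(k_down, n_down, k_up, n_up, float(p_value))


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    n_a: int
    n_b: int
    expected: float
    p_enrichment: float  # upper binomial tail P(X >= overlap)


def signature_overlap_test(sig_a: Tuple[Sequence[str], Sequence[str]],
                           sig_b: Tuple[Sequence[str], Sequence[str]],
                           universe_size: int) -> Dict[Tuple[str, str], OverlapResult]:
    """Directional overlap of two signatures (each an (up, down) pair).

    For every quadrant the observed overlap |A_d1 & B_d2| is compared with
    the binomial expectation |A||B|/U: X ~ Binomial(|A|, |B|/U), reporting
    the enrichment tail P(X >= k).
    """
    sets_a = {"up": set(sig_a[0]), "down": set(sig_a[1])}
    sets_b = {"up": set(sig_b[0]), "down": set(sig_b[1])}
    union = sets_a["up"] | sets_a["down"] | sets_b["up"] | sets_b["down"]
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of the gene lists")
    out = {}
    for da, sa in sets_a.items():
        for db, sb in sets_b.items():
            k = len(sa & sb)
            p_hit = len(sb) / universe_size
            p = float(stats.binom.sf(k - 1, len(sa), p_hit)) if sa else 1.0
            out[(da, db)] = OverlapResult(k, len(sa), len(sb),
                                          len(sa) * p_hit, p)
    return out
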