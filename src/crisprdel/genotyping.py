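"""Genotyping of CRISPR double-cut deletion clones.

Three assays are combined, mirroring the screen used for a 13-kb
enhancer excision:

1. **Deletion-spanning PCR** — primers flanking the two cut sites give a
   ~420 bp product only when at least one allele fused its cut sites;
   the intact span is too long to amplify.
2. **qPCR copy number (delta-delta-Ct)** — the target assay sits inside
   the deleted region, normalized to a two-copy control region on another
   chromosome.  Relative copy number = 2 * 2^-(dCt_clone - dCt_WT), so
   the wild-type reference reads exactly 2.  Classification thresholds
   (0.5, 1.5) are midpoints between the ideal copy numbers {0, 1, 2}.
   All-missing target wells are the no-amplification sentinel for a
   biallelic deletion: copy number 0.
3. **Junction sequencing** — diagnostic SNPs in the amplicon's 3' flank
   reveal which parental allele was cut, by majority vote over the
   SNP contexts found in the amplicon.

The overall deletion frequency is the allele-level rate

    (n_monoallelic + 2 * n_biallelic) / (2 * n_total),

evaluated in exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simhybrid import ALLELE_A, ALLELE_B, DiploidReference

MAX_AMPLIFIABLE_LENGTH = 3_000
COPY_NUMBER_THRESHOLDS = (0.5, 1.5)


@dataclass
class GenotypeCall:
    clone_id: str
    relative_copy_number: float
    call: str                 # WT | monoallelic | biallelic
    deleted_allele: str       # CAST | 129 | both | none | NA

    def __post_init__(self) -> None:
        if self.call == "biallelic" and self.deleted_allele != "both":
            raise ValueError("biallelic calls imply deleted_allele='both'")
        if self.call == "WT" and self.deleted_allele != "none":
            raise ValueError("WT calls imply deleted_allele='none'")


# ---------------------------------------------------------------------------
# deletion-spanning PCR screen
# ---------------------------------------------------------------------------

def pcr_screen(amplicons: Sequence, max_amplifiable_length: int = MAX_AMPLIFIABLE_LENGTH) -> dict:
    """Screen one clone's junction PCR.

    ``amplicons`` holds the observed products ((name, seq) pairs or plain
    sequences/lengths); a product is detected iff any amplicon is short
    enough to amplify.  Detection implies at least one deleted or
    inverted allele.
    """
    lengths = []
    for amp in amplicons:
        if isinstance(amp, tuple):
            amp = amp[1]
        lengths.append(amp if isinstance(amp, int) else len(amp))
    detectable = [n for n in lengths if n <= max_amplifiable_length]
    return {
        "product_detected": bool(detectable),
        "approx_length": min(detectable) if detectable else None,
    }


# ---------------------------------------------------------------------------
# delta-delta-Ct copy number
# ---------------------------------------------------------------------------

def _delta_ct(ct: pd.DataFrame, clone: str) -> Optional[float]:
    """mean Ct(target) - mean Ct(control) for one clone; None encodes the
    no-amplification sentinel (all target wells missing)."""
    sub = ct[ct["clone_id"] == clone]
    if sub.empty:
        raise ValueError(f"clone {clone!r} absent from Ct table")
    control = sub.loc[sub["assay"] == "control", "Ct"]
    if control.empty or control.isna().any():
        raise ValueError(f"clone {clone!r}: missing control wells")
    target = sub.loc[sub["assay"] == "target", "Ct"]
    if target.empty:
        raise ValueError(f"clone {clone!r}: no target wells")
    if target.isna().all():
        return None
    return float(target.mean() - control.mean())


def ddct_copy_number(ct: pd.DataFrame, wt_reference: str) -> pd.Series:
    """Relative copy number per clone: 2 * 2^-(dCt_clone - dCt_WT).

    The WT reference clone therefore reports exactly 2.  Clones whose
    target wells all failed to amplify report 0.
    """
    dct_wt = _delta_ct(ct, wt_reference)
    if dct_wt is None:
        raise ValueError("WT reference clone has no target amplification")
    out = {}
    for clone in ct["clone_id"].unique():
        dct = _delta_ct(ct, clone)
        out[clone] = 0.0 if dct is None else 2.0 * 2.0 ** -(dct - dct_wt)
    return pd.Series(out, name="relative_copy_number")


def classify_genotype(copy_number: float,
                      thresholds: Tuple[float, float] = COPY_NUMBER_THRESHOLDS) -> str:
    """Map a relative copy number to WT / monoallelic / biallelic."""
    lo, hi = thresholds
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if copy_number >= hi:
        return "WT"
    if copy_number >= lo:
        return "monoallelic"
    return "biallelic"


# ---------------------------------------------------------------------------
# junction-SNP allele calling
# ---------------------------------------------------------------------------

def call_junction_allele(amplicon: str, diagnostic_variants: pd.DataFrame,
                         ref: DiploidReference, context: int = 10) -> str:
    """Which parental allele does a junction amplicon come from?

    For every diagnostic SNP, the (2*context+1)-mer around the SNP is
    extracted from each haplotype and searched in the amplicon; each hit
    votes for its haplotype.  Majority wins, a tie is ambiguous, and an
    amplicon matching no context at all cannot be aligned.
    """
    if diagnostic_variants.empty:
        raise ValueError("at least one diagnostic variant is required")
    votes = {ALLELE_A: 0, ALLELE_B: 0}
    for v in diagnostic_variants.itertuples():
        a0, b0 = v.pos - 1, v.pos_b - 1
        ctx_a = ref.haplotypes[ALLELE_A][v.chrom][a0 - context:a0 + context + 1]
        ctx_b = ref.haplotypes[ALLELE_B][v.chrom][b0 - context:b0 + context + 1]
        in_a, in_b = ctx_a in amplicon, ctx_b in amplicon
        if in_a and not in_b:
            votes[ALLELE_A] += 1
        elif in_b and not in_a:
            votes[ALLELE_B] += 1
    if votes[ALLELE_A] == votes[ALLELE_B] == 0:
        raise ValueError("amplicon aligns to neither haplotype flank")
    if votes[ALLELE_A] == votes[ALLELE_B]:
        return "ambiguous"
    return ALLELE_A if votes[ALLELE_A] > votes[ALLELE_B] else ALLELE_B


# ---------------------------------------------------------------------------
# combined per-clone genotyping and the deletion-frequency statistic
# ---------------------------------------------------------------------------

def genotype_clones(ct: pd.DataFrame, wt_reference: str,
                    amplicons_by_clone: Optional[Dict[str, Sequence]] = None,
                    diagnostic: Optional[pd.DataFrame] = None,
                    ref: Optional[DiploidReference] = None) -> pd.DataFrame:
    """Copy-number classification for every clone in the Ct table, plus a
    junction-allele call for monoallelic clones when amplicons and
    diagnostic variants are supplied."""
    copy_numbers = ddct_copy_number(ct, wt_reference)
    rows = []
    for clone, cn in copy_numbers.items():
        call = classify_genotype(cn)
        if call == "biallelic":
            allele = "both"
        elif call == "WT":
            allele = "none"
        else:
            allele = "NA"
            if amplicons_by_clone is not None and diagnostic is not None and ref is not None:
                amps = amplicons_by_clone.get(clone, [])
                calls = {call_junction_allele(seq, diagnostic, ref)
                         for _, seq in amps} if amps else set()
                calls.discard("ambiguous")
                if len(calls) == 1:
                    allele = calls.pop()
        rows.append({"clone_id": clone, "relative_copy_number": float(cn),
                     "call": call, "deleted_allele": allele})
    return pd.DataFrame(rows)


def deletion_frequency(n_mono: int, n_bi: int, n_total: int) -> Fraction:
    """Allele-level deletion frequency (n_mono + 2*n_bi) / (2*n_total),
    as an exact rational number."""
    if min(n_mono, n_bi, n_total) < 0:
        raise ValueError("counts must be >= 0")
    if n_total == 0:
        raise ValueError("n_total must be > 0")
    if n_mono + n_bi > n_total:
        raise ValueError("monoallelic + biallelic clones exceed total clones")
    return Fraction(n_mono + 2 * n_bi, 2 * n_total)
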