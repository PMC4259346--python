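"""Shared fixtures: one default synthetic experiment reused across tests."""

import pandas as pd
import pytest

from crisprdel import simhybrid as sh
from crisprdel import variantqc as vq


@pytest.fixture(scope="session")
def config():
    return sh.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def reference(config):
    return sh.build_reference(config)


@pytest.fixture(scope="session")
def clones(reference, config):
    return sh.simulate_clones(reference, sh.SCREEN_ROSTER, config)


@pytest.fixture(scope="session")
def qc_variants(reference, config):
    """Variant table after the full QC chain on simulated DNA counts."""
    dna = sh.simulate_dna_counts(reference, config)
    table, _ = vq.run_variant_qc(reference, dna, config.read_length)
    return table


@pytest.fixture(scope="session")
def ct_table(reference, clones, config):
    return pd.concat(
        [sh.simulate_qpcr(c.genotype, reference, config) for c in clones],
        ignore_index=True)


def make_toy_reference(seq_a: str, variants: list, chrom: str = "chrT",
                       genes: list | None = None) -> sh.DiploidReference:
    """Hand-built diploid reference for unit tests.

    ``variants`` is a list of (pos_1based, ref, alt) on the A frame;
    the B haplotype and B-frame positions are derived.
    """
    rows, parts, cur, offset = [], [], 0, 0
    for pos, ref_allele, alt_allele in sorted(variants):
        p0 = pos - 1
        assert seq_a[p0:p0 + len(ref_allele)] == ref_allele
        parts.append(seq_a[cur:p0])
        parts.append(alt_allele)
        kind = "SNP" if len(ref_allele) == len(alt_allele) == 1 else "indel"
        rows.append((chrom, pos, ref_allele, alt_allele, kind, p0 + offset + 1,
                     False, False, False, True))
        offset += len(alt_allele) - len(ref_allele)
        cur = p0 + len(ref_allele)
    parts.append(seq_a[cur:])
    table = pd.DataFrame(rows, columns=sh.VARIANT_COLUMNS)
    return sh.DiploidReference(
        haplotypes={sh.ALLELE_A: {chrom: seq_a}, sh.ALLELE_B: {chrom: "".join(parts)}},
        variants=table, genes=genes or [])
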