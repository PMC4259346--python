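"""Synthetic hybrid-ESC CRISPR enhancer-deletion experiment generator.

Emulates an F1-hybrid (CAST x 129) mouse ESC line in which a distal
super-enhancer downstream of a focal pluripotency gene is excised by a
double-CRISPR cut.  The generator produces, with known ground truth:

* a diploid reference — two haplotype genomes differing only at planted
  phased SNPs/indels (CAST is the reference frame, 129 the alternate);
* edited clone genomes (wild type, monoallelic or biallelic deletion,
  optional full-segment inversion) with NHEJ-style junction indels;
* strand-specific, allele-tagged RNA-seq reads with a cis-only residual
  effect on the deleted allele and trans effects on signature genes;
* genotyping qPCR Ct tables (triplicates, Gaussian Ct noise);
* restriction-fragment Hi-C contact tables with distance decay and a
  planted promoter-enhancer loop;
* deletion-junction PCR amplicons carrying allele-diagnostic SNPs.

Everything is deterministic given the configuration seed.  Distances are
desk-scaled (200 kb chromosome, enhancer 20 kb downstream) so the whole
experiment simulates in seconds while preserving the topology of the
real locus; all distances are configurable.
"""

from __future__ import annotations

import dataclasses
import io
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import reverse_complement

ALLELE_A = "CAST"  # reference haplotype in the phased VCF (GT 0|1)
ALLELE_B = "129"
ALLELES = (ALLELE_A, ALLELE_B)
HINDIII_SITE = "AAGCTT"

# stage tags folded into the seed sequence so each simulate_* operation
# draws from an independent, reproducible stream
_STAGE_REFERENCE = 1
_STAGE_CLONES = 2
_STAGE_RNASEQ = 3
_STAGE_QPCR = 4
_STAGE_HIC = 5
_STAGE_DNA = 6

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "kind", "pos_b",
    "mapping_bias", "cnv_bias", "poor_het", "usable",
]


def _clone_stream(config: "SimulationConfig", stage: int, clone_id: str = "") -> np.random.Generator:
    tag = zlib.crc32(clone_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng((config.seed, stage, tag))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The defaults encode the study conditions: a ~7% cis residual on the
    deleted allele, 2x100 bp-style read length, triplicate qPCR with
    modest Ct noise, and a planted promoter-enhancer loop enriched
    5-fold over the distance-decay background.
    """

    seed: int = 0
    read_length: int = 100
    n_reads_per_clone: int = 20_000
    snp_density: float = 2.0          # variants per kb
    indel_fraction: float = 0.10      # fraction of variants that are indels
    cis_residual: float = 0.07        # focal-gene activity left on a deleted allele
    trans_down_factor: float = 0.2    # fold applied to signature_down genes (biallelic)
    trans_up_factor: float = 5.0      # fold applied to signature_up genes (biallelic)
    nb_dispersion: float = 0.005      # NB dispersion alpha (var = mu + alpha mu^2)
    ct_sd: float = 0.15               # per-well qPCR Ct noise SD (cycles)
    hic_decay_exponent: float = 1.0   # contact mean ~ distance^-exponent
    loop_enrichment: float = 5.0      # fold enrichment at enhancer fragments
    hic_n_contacts: int = 2_500       # expected anchor-incident contact pairs
    dna_depth: float = 50.0           # mean genomic-DNA depth per variant
    # genome geometry (desk scale)
    chrom_main: str = "chr3"
    chrom_aux: str = "chr6"
    len_main: int = 200_000
    len_aux: int = 100_000
    enhancer_gap: int = 20_000        # enhancer start relative to focal gene end
    enhancer_length: int = 1_300
    primer_up_flank: int = 200        # junction PCR primer distances from the cut sites
    primer_down_flank: int = 220
    ct0_target: float = 24.0          # primer-specific Ct at one template copy
    ct0_control: float = 23.0

    def validate(self) -> None:
        if not 0.0 <= self.cis_residual <= 1.0:
            raise ValueError("cis_residual must be in [0, 1]")
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25")
        for name in ("n_reads_per_clone", "hic_n_contacts", "len_main", "len_aux",
                     "enhancer_gap", "enhancer_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.snp_density < 0:
            raise ValueError("snp_density must be >= 0")

    def __post_init__(self) -> None:
        self.validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-exon gene; the whole interval is treated as exonic."""

    name: str
    chrom: str
    start: int            # 0-based half-open genomic interval
    end: int
    strand: str
    role: str             # focal | signature_down | signature_up | neutral | control
    base_expression: float  # relative transcript abundance (arbitrary units)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length_bp < 200:
            raise ValueError(f"gene {self.name}: exonic length must be >= 200 bp")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def default_genes(config: SimulationConfig) -> List[GeneModel]:
    """The default gene roster: a highly expressed focal gene on the main
    chromosome (with two neutral bystanders), and a control gene plus
    trans-responsive signature genes on the auxiliary chromosome."""
    cm, ca = config.chrom_main, config.chrom_aux
    genes = [
        GeneModel("Sox2", cm, 60_000, 64_000, "+", "focal", 40.0),
        GeneModel("Neut3a", cm, 10_000, 13_000, "+", "neutral", 10.0),
        GeneModel("Neut3b", cm, 120_000, 123_000, "-", "neutral", 10.0),
        GeneModel("Gapdh", ca, 10_000, 14_000, "+", "control", 30.0),
    ]
    pos = 20_000
    for i in range(4):
        genes.append(GeneModel(f"SigDn{i+1}", ca, pos, pos + 3_000,
                               "+" if i % 2 == 0 else "-", "signature_down", 10.0))
        pos += 6_000
    for i in range(4):
        genes.append(GeneModel(f"SigUp{i+1}", ca, pos, pos + 3_000,
                               "+" if i % 2 == 0 else "-", "signature_up", 10.0))
        pos += 6_000
    for i in range(4):
        genes.append(GeneModel(f"Neut6{chr(ord('a')+i)}", ca, pos, pos + 3_000,
                               "+" if i % 2 == 0 else "-", "neutral", 10.0))
        pos += 6_000
    return genes


@dataclass
class DiploidReference:
    """Two haplotype genomes plus the phased variants that separate them.

    ``haplotypes[allele][chrom]`` holds the DNA string; all interval
    fields are 0-based half-open on the CAST (haplotype A) frame.
    """

    haplotypes: Dict[str, Dict[str, str]]
    variants: pd.DataFrame
    genes: List[GeneModel]
    enhancer: Optional[Tuple[str, int, int]] = None
    control_interval: Optional[Tuple[str, int, int]] = None

    # per-chrom lift tables, built lazily
    _lift: Optional[dict] = field(default=None, repr=False, compare=False)

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def focal_gene(self) -> GeneModel:
        (g,) = [g for g in self.genes if g.role == "focal"]
        return g

    def _lift_tables(self) -> dict:
        if self._lift is None:
            tables = {}
            for chrom, sub in self.variants.groupby("chrom", sort=False):
                sub = sub.sort_values("pos")
                delta = sub["alt"].str.len().to_numpy() - sub["ref"].str.len().to_numpy()
                ends_a = (sub["pos"].to_numpy() - 1) + sub["ref"].str.len().to_numpy()
                ends_b = (sub["pos_b"].to_numpy() - 1) + sub["alt"].str.len().to_numpy()
                tables[chrom] = (ends_a, ends_b, np.cumsum(delta))
            self._lift = tables
        return self._lift

    def lift_to_b(self, chrom: str, pos: int) -> int:
        """Map a 0-based position from the CAST frame to the 129 frame."""
        tab = self._lift_tables().get(chrom)
        if tab is None:
            return pos
        ends_a, _, cum = tab
        i = int(np.searchsorted(ends_a, pos, side="right"))
        return pos + (int(cum[i - 1]) if i > 0 else 0)

    def lift_to_a(self, chrom: str, pos: int) -> int:
        """Map a 0-based position from the 129 frame to the CAST frame."""
        tab = self._lift_tables().get(chrom)
        if tab is None:
            return pos
        _, ends_b, cum = tab
        i = int(np.searchsorted(ends_b, pos, side="right"))
        return pos - (int(cum[i - 1]) if i > 0 else 0)

    def lift(self, allele: str, chrom: str, pos: int) -> int:
        """Map a CAST-frame position into the coordinate frame of ``allele``."""
        return pos if allele == ALLELE_A else self.lift_to_b(chrom, pos)


@dataclass
class CloneGenotype:
    """Ground-truth genotype of one CRISPR-targeted clone."""

    clone_id: str
    allele_status: Dict[str, str]     # allele -> intact | deleted | inverted
    junction_edit: Dict[str, int]     # allele -> signed junction indel (bp), deleted alleles
    true_label: str                   # WT | monoallelic_CAST | monoallelic_129 | biallelic

    def __post_init__(self) -> None:
        for edit in self.junction_edit.values():
            if abs(edit) > 50:
                raise ValueError("junction edits are limited to +/-50 bp")
        deleted = sorted(a for a, s in self.allele_status.items() if s != "intact")
        expected = {
            "WT": [], "biallelic": sorted(ALLELES),
            "monoallelic_CAST": [ALLELE_A], "monoallelic_129": [ALLELE_B],
        }[self.true_label]
        if deleted != expected:
            raise ValueError(f"{self.clone_id}: allele_status inconsistent with {self.true_label}")


@dataclass
class SimulatedClone:
    genotype: CloneGenotype
    genomes: Dict[str, Dict[str, str]]  # allele -> chrom -> edited sequence


#: genotype roster matching the published screen of 16 clones: two biallelic
#: deletions, five monoallelic deletions on the 129 allele, one on the CAST
#: allele, and eight untargeted clones.
SCREEN_ROSTER: List[Tuple[str, str]] = (
    [("MutA", "biallelic"), ("MutB", "biallelic")]
    + [(f"Mut{c}", "monoallelic_129") for c in "CDEFH"]
    + [("MutG", "monoallelic_CAST")]
    + [(f"WT{i}", "WT") for i in range(1, 9)]
)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _plant_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                     reserved: Sequence[int], min_gap: int = 10) -> List[int]:
    """Choose n variant anchor positions in [lo, hi) at least min_gap apart."""
    if n == 0:
        return []
    if n * min_gap > (hi - lo) * 0.8:
        raise ValueError(
            "snp_density too high: planted variants would collide; "
            "lower snp_density or enlarge the chromosome")
    taken = sorted(reserved)
    out: List[int] = []
    candidates = rng.choice(np.arange(lo, hi), size=min(4 * n, hi - lo), replace=False)
    for p in candidates:
        p = int(p)
        i = np.searchsorted(taken, p)
        ok = True
        if i > 0 and p - taken[i - 1] < min_gap:
            ok = False
        if i < len(taken) and taken[i] - p < min_gap:
            ok = False
        if ok:
            taken.insert(i, p)
            out.append(p)
            if len(out) == n:
                return out
    raise ValueError("snp_density too high: planted variants would collide")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(len(choices)))]


def build_reference(config: SimulationConfig,
                    genes: Optional[List[GeneModel]] = None) -> DiploidReference:
    """Build the diploid reference: random chromosomes, planted phased
    variants, the focal gene with its downstream enhancer, and a copy-number
    control interval on the other chromosome.

    Two diagnostic SNPs are always planted inside the downstream junction
    primer flank so deletion amplicons reveal their allele of origin.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, _STAGE_REFERENCE))
    genes = list(genes) if genes is not None else default_genes(config)
    focal = [g for g in genes if g.role == "focal"]
    if len(focal) != 1:
        raise ValueError("exactly one gene must have role=focal")
    focal = focal[0]

    chrom_lengths = {config.chrom_main: config.len_main, config.chrom_aux: config.len_aux}
    seqs_a = {c: _random_seq(rng, n) for c, n in chrom_lengths.items()}

    enh_start = focal.end + config.enhancer_gap
    enh_end = enh_start + config.enhancer_length
    if enh_end + config.primer_down_flank >= config.len_main:
        raise ValueError("chromosome too short for the enhancer and primer flanks")
    enhancer = (config.chrom_main, enh_start, enh_end)
    for g in genes:
        if g.chrom == config.chrom_main and not (g.end <= enh_start or g.start >= enh_end):
            raise ValueError(f"enhancer interval overlaps gene body of {g.name}")
    control = [g for g in genes if g.role == "control"]
    if not control or control[0].chrom == config.chrom_main:
        raise ValueError("a control gene on the auxiliary chromosome is required")
    ctrl = control[0]
    control_interval = (ctrl.chrom, ctrl.start + 1_000, ctrl.start + 1_800)

    # allele-diagnostic SNPs in the downstream primer flank (3' end of the
    # junction amplicon); kept >=10 bp from the flank edges so their k-mer
    # context stays inside the amplicon.  A variant-free genome stays
    # genuinely variant-free (junction genotyping then refuses to run).
    diag_anchors = [enh_end + 60, enh_end + 140] if config.snp_density > 0 else []

    records = []
    for chrom, length in chrom_lengths.items():
        n = int(rng.poisson(config.snp_density * length / 1_000))
        reserved = diag_anchors if chrom == config.chrom_main else []
        anchors = _plant_positions(rng, n, 50, length - 50, reserved)
        if chrom == config.chrom_main:
            anchors = sorted(anchors + diag_anchors)
        for p0 in sorted(anchors):
            is_diag = chrom == config.chrom_main and p0 in diag_anchors
            if not is_diag and rng.random() < config.indel_fraction:
                d = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # deletion on the 129 haplotype
                    ref_allele = seqs_a[chrom][p0:p0 + 1 + d]
                    alt_allele = seqs_a[chrom][p0]
                else:
                    ref_allele = seqs_a[chrom][p0]
                    alt_allele = seqs_a[chrom][p0] + _random_seq(rng, d)
                kind = "indel"
            else:
                ref_allele = seqs_a[chrom][p0]
                alt_allele = _other_base(rng, ref_allele)
                kind = "SNP"
            records.append((chrom, p0 + 1, ref_allele, alt_allele, kind))

    variants = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "kind"])
    variants = variants.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # haplotype B: apply alternate alleles; track B-frame positions
    seqs_b: Dict[str, str] = {}
    pos_b = np.zeros(len(variants), dtype=int)
    for chrom in chrom_lengths:
        idx = variants.index[variants["chrom"] == chrom]
        parts, cur, offset = [], 0, 0
        for i in idx:
            p0 = int(variants.at[i, "pos"]) - 1
            ref_allele, alt_allele = variants.at[i, "ref"], variants.at[i, "alt"]
            assert seqs_a[chrom][p0:p0 + len(ref_allele)] == ref_allele
            parts.append(seqs_a[chrom][cur:p0])
            parts.append(alt_allele)
            pos_b[i] = p0 + offset + 1
            offset += len(alt_allele) - len(ref_allele)
            cur = p0 + len(ref_allele)
        parts.append(seqs_a[chrom][cur:])
        seqs_b[chrom] = "".join(parts)

    variants["pos_b"] = pos_b
    for flag in ("mapping_bias", "cnv_bias", "poor_het"):
        variants[flag] = False
    variants["usable"] = True

    return DiploidReference(
        haplotypes={ALLELE_A: seqs_a, ALLELE_B: seqs_b},
        variants=variants, genes=genes,
        enhancer=enhancer, control_interval=control_interval,
    )


def diagnostic_variants(ref: DiploidReference, config: SimulationConfig) -> pd.DataFrame:
    """Usable SNPs inside the downstream junction primer flank."""
    chrom, _, enh_end = ref.enhancer
    v = ref.variants
    mask = (
        (v["chrom"] == chrom) & (v["kind"] == "SNP") & v["usable"]
        & (v["pos"] - 1 >= enh_end + 10)
        & (v["pos"] - 1 < enh_end + config.primer_down_flank - 10)
    )
    return v[mask]


# ---------------------------------------------------------------------------
# clone genome editing
# ---------------------------------------------------------------------------

def _draw_junction_edit(rng: np.random.Generator) -> int:
    size = min(int(rng.geometric(0.3)), 50)
    return -size if rng.random() < 2 / 3 else size  # NHEJ scars are deletion-biased


def _edit_haplotype(seq: str, start: int, end: int, status: str, edit: int,
                    rng: np.random.Generator) -> str:
    if status == "intact":
        return seq
    if status == "inverted":
        return seq[:start] + reverse_complement(seq[start:end]) + seq[end:]
    if status != "deleted":
        raise ValueError(f"unknown allele status {status!r}")
    left, right = seq[:start], seq[end:]
    if edit < 0:
        right = right[-edit:]
    elif edit > 0:
        left = left + _random_seq(rng, edit)
    return left + right


_LABEL_STATUS = {
    "WT": {},
    "monoallelic_CAST": {ALLELE_A: "deleted"},
    "monoallelic_129": {ALLELE_B: "deleted"},
    "biallelic": {ALLELE_A: "deleted", ALLELE_B: "deleted"},
}


def simulate_clones(ref: DiploidReference, roster: Sequence, config: SimulationConfig,
                    junction_edits: Optional[Dict[str, Dict[str, int]]] = None,
                    inversions: Optional[Dict[str, str]] = None) -> List[SimulatedClone]:
    """Excise (or invert) the enhancer on the alleles dictated by each roster
    entry and apply an NHEJ junction indel drawn from a geometric distribution.

    ``roster`` entries are true labels or ``(clone_id, label)`` pairs.
    ``junction_edits`` overrides the drawn edit per clone/allele (0 = clean
    fusion); ``inversions[clone_id] = allele`` converts that deletion into a
    full-segment inversion.
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    chrom, start_a, end_a = ref.enhancer
    clones: List[SimulatedClone] = []
    for i, entry in enumerate(roster):
        if isinstance(entry, str):
            clone_id, label = f"clone{i + 1:02d}", entry
        else:
            clone_id, label = entry
        if label not in _LABEL_STATUS:
            raise ValueError(f"unknown true_label {label!r}")
        rng = _clone_stream(config, _STAGE_CLONES, clone_id)
        status = {a: _LABEL_STATUS[label].get(a, "intact") for a in ALLELES}
        if inversions and clone_id in inversions:
            status[inversions[clone_id]] = "inverted"
        edits: Dict[str, int] = {}
        genomes: Dict[str, Dict[str, str]] = {}
        for allele in ALLELES:
            if status[allele] == "deleted":
                override = (junction_edits or {}).get(clone_id, {})
                edits[allele] = override[allele] if allele in override \
                    else _draw_junction_edit(rng)
            s = ref.lift(allele, chrom, start_a)
            e = ref.lift(allele, chrom, end_a)
            genome = dict(ref.haplotypes[allele])
            genome[chrom] = _edit_haplotype(
                genome[chrom], s, e, status[allele], edits.get(allele, 0), rng)
            genomes[allele] = genome
        genotype = CloneGenotype(clone_id, status, edits, label)
        clones.append(SimulatedClone(genotype, genomes))
    return clones


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def transcript_sequence(ref: DiploidReference, gene: GeneModel, allele: str) -> str:
    """Sense-strand transcript of ``gene`` on one haplotype (gene bodies are
    never touched by the enhancer excision, so the reference suffices)."""
    s = ref.lift(allele, gene.chrom, gene.start)
    e = ref.lift(allele, gene.chrom, gene.end)
    seq = ref.haplotypes[allele][gene.chrom][s:e]
    return reverse_complement(seq) if gene.strand == "-" else seq


def _deletion_dosage(label: str) -> float:
    return {"WT": 0.0, "monoallelic_CAST": 0.5, "monoallelic_129": 0.5, "biallelic": 1.0}[label]


def expected_read_means(clone: CloneGenotype, ref: DiploidReference,
                        config: SimulationConfig) -> Dict[Tuple[str, str], float]:
    """Closed-form expected read count per (gene, allele) for one clone.

    mu(g, h) = n_reads * base_g / (2 * sum(base)) * allele_factor * trans_factor,
    where the allele factor is the cis residual for the focal gene on a
    deleted allele, and trans factors act on both alleles of signature genes
    with exponent equal to the deletion dosage (0 / 0.5 / 1), i.e. the
    monoallelic trans effect is the geometric mean of WT and biallelic.
    """
    total = sum(g.base_expression for g in ref.genes)
    dosage = _deletion_dosage(clone.true_label)
    mu = {}
    for g in ref.genes:
        if g.role == "signature_down":
            trans = config.trans_down_factor ** dosage
        elif g.role == "signature_up":
            trans = config.trans_up_factor ** dosage
        else:
            trans = 1.0
        for allele in ALLELES:
            cis = 1.0
            if g.role == "focal" and clone.allele_status.get(allele) != "intact":
                cis = config.cis_residual
            mu[(g.name, allele)] = (
                config.n_reads_per_clone * g.base_expression / (2 * total) * cis * trans)
    return mu


def _nb_draw(rng: np.random.Generator, mu: float, alpha: float) -> int:
    if mu <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / alpha
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def simulate_rnaseq(clone: CloneGenotype, ref: DiploidReference,
                    config: SimulationConfig) -> pd.DataFrame:
    """Draw negative-binomial counts per (gene, allele) and emit sense-strand
    reads as uniform substrings of the corresponding haplotype transcript.

    Returns the ground-truth tag table, one row per read:
    read_id, gene, allele, tstart (offset in the origin transcript),
    strand, seq.
    """
    rng = _clone_stream(config, _STAGE_RNASEQ, clone.clone_id)
    mu = expected_read_means(clone, ref, config)
    rows = []
    L = config.read_length
    k = 0
    for g in ref.genes:
        for allele in ALLELES:
            tseq = transcript_sequence(ref, g, allele)
            if len(tseq) < L:
                raise ValueError(f"gene {g.name} transcript shorter than read_length")
            c = _nb_draw(rng, mu[(g.name, allele)], config.nb_dispersion)
            starts = rng.integers(0, len(tseq) - L + 1, size=c)
            for t in starts:
                rows.append((f"{clone.clone_id}:{k}", g.name, allele, int(t),
                             g.strand, tseq[t:t + L]))
                k += 1
    return pd.DataFrame(rows, columns=["read_id", "gene", "allele", "tstart", "strand", "seq"])


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(clone: CloneGenotype, ref: DiploidReference,
                  config: SimulationConfig) -> pd.DataFrame:
    """Triplicate Ct values for the enhancer-internal target assay and the
    two-copy control assay: Ct = Ct0 - log2(copies) + N(0, ct_sd).

    A biallelic deletion leaves no template; its target wells carry the
    no-amplification sentinel (missing Ct).
    """
    rng = _clone_stream(config, _STAGE_QPCR, clone.clone_id)
    copies_target = sum(
        1 for s in clone.allele_status.values() if s in ("intact", "inverted"))
    rows = []
    for assay, copies, ct0 in (
            ("target", copies_target, config.ct0_target),
            ("control", 2, config.ct0_control)):
        for w in range(1, 4):
            if copies == 0:
                ct = np.nan
            else:
                ct = ct0 - np.log2(copies) + rng.normal(0.0, config.ct_sd)
            rows.append((clone.clone_id, f"w{w}", assay, ct))
    return pd.DataFrame(rows, columns=["clone_id", "well", "assay", "Ct"])


# ---------------------------------------------------------------------------
# Hi-C simulation
# ---------------------------------------------------------------------------

def simulate_hic(ref: DiploidReference, config: SimulationConfig
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Digest the main chromosome at HindIII sites and draw Poisson contact
    counts from the anchor fragment (focal promoter) to every other fragment,
    with mean proportional to fragment length times distance^-exponent and a
    ``loop_enrichment``-fold boost at fragments overlapping the enhancer.

    Returns (fragments, contacts): BED-like fragment table and a
    (frag_i, frag_j, count) contact table.
    """
    from . import loopcall  # local import: loopcall owns digestion

    rng = np.random.default_rng((config.seed, _STAGE_HIC))
    chrom = config.chrom_main
    seq = ref.haplotypes[ALLELE_A][chrom]
    frags = loopcall.digest(seq, HINDIII_SITE)
    if len(frags) < 2:
        raise ValueError("no restriction site in sequence; cannot simulate contacts")
    focal = ref.focal_gene
    tss = focal.start if focal.strand == "+" else focal.end - 1
    anchor = next(i for i, (s, e) in enumerate(frags) if s <= tss < e)

    mids = np.array([(s + e) / 2 for s, e in frags])
    dist = np.abs(mids - mids[anchor])
    weights = np.maximum(dist, 1.0) ** (-config.hic_decay_exponent)
    weights[anchor] = 0.0
    means = config.hic_n_contacts * weights / weights.sum()
    enh_chrom, enh_s, enh_e = ref.enhancer
    assert enh_chrom == chrom
    for i, (s, e) in enumerate(frags):
        if i != anchor and not (e <= enh_s or s >= enh_e):
            means[i] *= config.loop_enrichment
    counts = rng.poisson(means)

    fragments = pd.DataFrame({
        "fragment_id": [f"F{i}" for i in range(len(frags))],
        "chrom": chrom,
        "start": [s for s, _ in frags],
        "end": [e for _, e in frags],
    })
    contacts = pd.DataFrame({
        "frag_i": f"F{anchor}",
        "frag_j": [f"F{i}" for i in range(len(frags)) if i != anchor],
        "count": [int(c) for i, c in enumerate(counts) if i != anchor],
    })
    return fragments, contacts


# ---------------------------------------------------------------------------
# junction amplicons
# ---------------------------------------------------------------------------

def simulate_junctions(clone: SimulatedClone, ref: DiploidReference,
                       config: SimulationConfig) -> List[Tuple[str, str]]:
    """Deletion-spanning PCR amplicons, one per deleted or inverted allele.

    The amplicon is the primer-flanked fusion sequence sliced from the
    clone's edited haplotype, so it carries the junction indel and the
    allele-diagnostic SNPs in the downstream flank.  Intact alleles (the
    13-kb-scale span is not amplifiable) yield nothing; WT clones return
    an empty list.
    """
    if diagnostic_variants(ref, config).empty:
        raise ValueError(
            "no diagnostic SNP in the junction primer flanks; "
            "build_reference must plant one")
    chrom, start_a, end_a = ref.enhancer
    up, down = config.primer_up_flank, config.primer_down_flank
    amplicons = []
    gt = clone.genotype
    for allele in ALLELES:
        status = gt.allele_status[allele]
        if status == "intact":
            continue
        s = ref.lift(allele, chrom, start_a)
        e = ref.lift(allele, chrom, end_a)
        edited = clone.genomes[allele][chrom]
        if status == "deleted":
            edit = gt.junction_edit.get(allele, 0)
            amp = edited[s - up: s + down + edit]
        else:  # inverted: the segment is retained, reversed
            amp = edited[s - up: e + down]
        amplicons.append((f"{gt.clone_id}|{allele}|junction", amp))
    return amplicons


# ---------------------------------------------------------------------------
# genomic-DNA allele counts (input to the variant QC balance filters)
# ---------------------------------------------------------------------------

def simulate_dna_counts(ref: DiploidReference, config: SimulationConfig) -> pd.DataFrame:
    """Per-variant genomic-DNA allele depths: total ~ Poisson(dna_depth),
    split Binomial(total, 1/2) between the haplotypes."""
    rng = np.random.default_rng((config.seed, _STAGE_DNA))
    n = len(ref.variants)
    total = rng.poisson(config.dna_depth, size=n)
    c_a = rng.binomial(total, 0.5)
    return pd.DataFrame({
        "chrom": ref.variants["chrom"], "pos": ref.variants["pos"],
        "c_A": c_a, "c_B": total - c_a,
    })


# ---------------------------------------------------------------------------
# writers (plain-text external formats)
# ---------------------------------------------------------------------------

def write_fasta(seqs: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for row in reads.itertuples():
            fh.write(f"@{row.read_id}\n{row.seq}\n+\n{'I' * len(row.seq)}\n")


def vcf_text(ref: DiploidReference) -> str:
    """Phased VCF 4.2 with CAST as the REF haplotype (GT 0|1); QC flags are
    emitted in FILTER (MAPBIAS/CNVBIAS/POORHET, PASS when usable)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    for chrom in sorted({g for g in ref.haplotypes[ALLELE_A]}):
        buf.write(f"##contig=<ID={chrom},length={len(ref.haplotypes[ALLELE_A][chrom])}>\n")
    for fid, desc in (("MAPBIAS", "dummy-read mapping bias above threshold"),
                      ("CNVBIAS", "allelic copy-number imbalance at 5% FDR"),
                      ("POORHET", "poor heterozygous call at 5% FDR")):
        buf.write(f'##FILTER=<ID={fid},Description="{desc}">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF123\n")
    for row in ref.variants.itertuples():
        flags = [n for n, f in (("MAPBIAS", row.mapping_bias),
                                ("CNVBIAS", row.cnv_bias),
                                ("POORHET", row.poor_het)) if f]
        filt = ";".join(flags) if flags else "PASS"
        buf.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\t.\tGT\t0|1\n")
    return buf.getvalue()


def write_vcf(ref: DiploidReference, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(vcf_text(ref))


def genes_bed(genes: Iterable[GeneModel]) -> str:
    lines = [f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}" for g in genes]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# loaders (file-based CLI entry points)
# ---------------------------------------------------------------------------

def read_genes_bed(path: str) -> List[GeneModel]:
    """BED6 genes; role and base_expression are not encoded in BED and
    default to neutral / 1.0 (analysis operations only need intervals)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            genes.append(GeneModel(name, chrom, int(start), int(end), strand,
                                   "neutral", 1.0))
    return genes


def load_reference(fasta_a: str, fasta_b: str, vcf_path: str,
                   genes_path: Optional[str] = None) -> DiploidReference:
    """Rebuild a DiploidReference from its on-disk representation
    (two haplotype FASTAs plus the phased VCF; CAST is REF).

    B-frame variant positions are recomputed from the cumulative
    indel offsets; FILTER fields populate the QC flags.
    """
    from Bio import SeqIO
    import pysam

    haps = {
        ALLELE_A: {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_a, "fasta")},
        ALLELE_B: {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_b, "fasta")},
    }
    records = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else rec.ref
            kind = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
            filters = set(rec.filter.keys())
            records.append((rec.chrom, rec.pos, rec.ref, alt, kind,
                            "MAPBIAS" in filters, "CNVBIAS" in filters,
                            "POORHET" in filters))
    variants = pd.DataFrame(records, columns=[
        "chrom", "pos", "ref", "alt", "kind", "mapping_bias", "cnv_bias", "poor_het"])
    variants = variants.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    pos_b = np.zeros(len(variants), dtype=int)
    for chrom in variants["chrom"].unique():
        offset = 0
        for i in variants.index[variants["chrom"] == chrom]:
            pos_b[i] = variants.at[i, "pos"] + offset
            offset += len(variants.at[i, "alt"]) - len(variants.at[i, "ref"])
    variants["pos_b"] = pos_b
    variants["usable"] = ~(variants["mapping_bias"] | variants["cnv_bias"]
                           | variants["poor_het"])
    variants = variants[VARIANT_COLUMNS]
    genes = read_genes_bed(genes_path) if genes_path else []
    return DiploidReference(haplotypes=haps, variants=variants, genes=genes)
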