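"""Allele assignment, per-gene counting, specificity and cis-parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from crisprdel import allelecount as ac
from crisprdel import simhybrid as sh
from crisprdel import variantqc as vq
from crisprdel.simhybrid import ALLELE_A, ALLELE_B

from conftest import make_toy_reference


def _toy_gene_ref(seed=0, snps=((150, ), (230, ))):
    """400-bp reference with one + strand gene [100, 400) and SNPs."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    variants = [(pos[0], seq[pos[0] - 1], other[seq[pos[0] - 1]]) for pos in snps]
    gene = sh.GeneModel("G1", "chrT", 100, 400, "+", "focal", 10.0)
    ref = make_toy_reference(seq, variants, genes=[gene])
    return ref, gene


class TestAssignRead:
    def test_single_snp_read_assigned_to_matching_haplotype(self):
        ref, _ = _toy_gene_ref()
        index = ac.UsableVariantIndex(ref.variants)
        for allele in (ALLELE_A, ALLELE_B):
            win = ref.haplotypes[allele]["chrT"][120:170]
            assert ac.assign_read(win, "chrT", 120, 120, ref.haplotypes, index) == allele

    def test_conflicting_snps_leave_read_unassigned(self):
        ref, _ = _toy_gene_ref(snps=((150,), (160,)))
        a = ref.haplotypes[ALLELE_A]["chrT"]
        b = ref.haplotypes[ALLELE_B]["chrT"]
        # chimeric window: CAST base at the first SNP, 129 base at the second
        chimera = a[120:155] + b[155:180]
        assert chimera[29] == a[149] and chimera[39] == b[159]
        index = ac.UsableVariantIndex(ref.variants)
        assert ac.assign_read(chimera, "chrT", 120, 120, ref.haplotypes,
                              index) == ac.UNASSIGNED

    def test_no_usable_variant_in_window_is_unassigned(self):
        ref, _ = _toy_gene_ref()
        win = ref.haplotypes[ALLELE_A]["chrT"][0:60]
        index = ac.UsableVariantIndex(ref.variants)
        assert ac.assign_read(win, "chrT", 0, 0, ref.haplotypes, index) == ac.UNASSIGNED

    def test_sequencing_error_tolerated_via_snp_vote(self):
        ref, _ = _toy_gene_ref()
        win = list(ref.haplotypes[ALLELE_B]["chrT"][120:170])
        pos_err = 10  # not a variant site
        win[pos_err] = {"A": "C", "C": "G", "G": "T", "T": "A"}[win[pos_err]]
        index = ac.UsableVariantIndex(ref.variants)
        assert ac.assign_read("".join(win), "chrT", 120, 120,
                              ref.haplotypes, index) == ALLELE_B

    def test_flagged_variant_carries_no_evidence(self):
        ref, _ = _toy_gene_ref()
        ref.variants.loc[:, ["mapping_bias", "usable"]] = [[True, False]] * len(ref.variants)
        win = ref.haplotypes[ALLELE_A]["chrT"][120:170]
        index = ac.UsableVariantIndex(ref.variants)
        assert ac.assign_read(win, "chrT", 120, 120, ref.haplotypes, index) == ac.UNASSIGNED

    def test_simulated_assignment_is_exact_without_errors(self, reference, qc_variants):
        cfg = sh.SimulationConfig(seed=29, nb_dispersion=0.0, n_reads_per_clone=10_000)
        (mono,) = sh.simulate_clones(reference, ["monoallelic_129"], cfg)
        reads = sh.simulate_rnaseq(mono.genotype, reference, cfg)
        index = ac.UsableVariantIndex(qc_variants)
        wrong = 0
        assigned = 0
        for row in reads.itertuples():
            g = reference.gene(row.gene)
            L = len(row.seq)
            if g.strand == "+":
                seq = row.seq
                sa = g.start + row.tstart
                sb = reference.lift_to_b(g.chrom, g.start) + row.tstart
            else:
                from Bio.Seq import reverse_complement
                seq = reverse_complement(row.seq)
                sa = g.end - row.tstart - L
                sb = reference.lift_to_b(g.chrom, g.end) - row.tstart - L
            call = ac.assign_read(seq, g.chrom, sa, sb, reference.haplotypes, index)
            if call != ac.UNASSIGNED:
                assigned += 1
                wrong += call != row.allele
        assert wrong == 0
        assert assigned > 0.05 * len(reads)


class TestCountReads:
    def test_empty_read_set_gives_zero_matrix(self, reference, qc_variants):
        empty = pd.DataFrame(columns=["read_id", "gene", "allele", "tstart",
                                      "strand", "seq"])
        matrix = ac.count_reads(empty, reference, qc_variants, "c0")
        assert (matrix[["c_CAST", "c_129", "c_unassigned", "total"]] == 0).all().all()

    def test_counts_conserved_per_gene(self, reference, qc_variants, clones, config):
        clone = clones[2]
        reads = sh.simulate_rnaseq(clone.genotype, reference, config)
        matrix = ac.count_reads(reads, reference, qc_variants,
                                clone.genotype.clone_id)
        per_gene = reads.groupby("gene").size()
        for row in matrix.itertuples():
            assert row.total == per_gene.get(row.gene, 0)
            assert row.c_CAST + row.c_129 + row.c_unassigned == row.total

    def test_wt_counts_symmetric(self, reference, qc_variants):
        cfg = sh.SimulationConfig(seed=31, nb_dispersion=0.0, n_reads_per_clone=100_000)
        (wt,) = sh.simulate_clones(reference, ["WT"], cfg)
        reads = sh.simulate_rnaseq(wt.genotype, reference, cfg)
        matrix = ac.count_reads(reads, reference, qc_variants, "wt")
        assigned = matrix["c_CAST"] + matrix["c_129"]
        imbalance = (matrix["c_CAST"] - matrix["c_129"]).abs() / assigned.clip(lower=1)
        assert (imbalance[assigned > 500] < 0.15).all()


class TestAlleleSpecificity:
    def test_pseudocount_examples(self):
        matrix = pd.DataFrame([
            {"gene": "a", "clone": "c", "c_CAST": 0, "c_129": 0,
             "c_unassigned": 0, "total": 0},
            {"gene": "b", "clone": "c", "c_CAST": 90, "c_129": 0,
             "c_unassigned": 0, "total": 90}])
        s = ac.allele_specificity(matrix)["s"]
        assert s.iloc[0] == 0.0
        assert s.iloc[1] == pytest.approx(np.log2(10), abs=1e-12)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame({
            "gene": [f"g{i}" for i in range(50)], "clone": "c",
            "c_CAST": rng.integers(0, 500, 50), "c_129": rng.integers(0, 500, 50)})
        matrix["c_unassigned"] = 0
        matrix["total"] = matrix["c_CAST"] + matrix["c_129"]
        swapped = matrix.rename(columns={"c_CAST": "c_129", "c_129": "c_CAST"})
        s = ac.allele_specificity(matrix)["s"].to_numpy()
        s_swapped = ac.allele_specificity(swapped)["s"].to_numpy()
        np.testing.assert_array_equal(s, -s_swapped)

    def test_focal_gene_reproduces_allelic_pattern(self, reference, qc_variants):
        # monoallelic-129 clone: focal gene expressed CAST-specifically
        # (s > 0); mono-CAST: s < 0; neutral genes stay near balance
        cfg = sh.SimulationConfig(seed=37, n_reads_per_clone=40_000)
        pair = sh.simulate_clones(
            reference, [("m129", "monoallelic_129"), ("mCAST", "monoallelic_CAST")], cfg)
        focal = reference.focal_gene.name
        for clone, sign in zip(pair, (1, -1)):
            reads = sh.simulate_rnaseq(clone.genotype, reference, cfg)
            matrix = ac.count_reads(reads, reference, qc_variants,
                                    clone.genotype.clone_id)
            s = ac.allele_specificity(matrix).set_index("gene")["s"]
            assert sign * s[focal] > 2.0
            neutral = [g.name for g in reference.genes if g.role != "focal"]
            assert s[neutral].abs().max() < 1.0


@pytest.fixture(scope="module")
def dense_reference():
    # a SNP-dense reference keeps the assigned-read depth high enough that
    # the Monte-Carlo SE condition in the recovery test is met at 3e5 reads
    return sh.build_reference(sh.SimulationConfig(seed=43, snp_density=6.0))


class TestKnockoutAlleleRatio:
    def test_arithmetic_examples(self):
        matrix = pd.DataFrame([
            {"gene": "F", "clone": "m1", "c_CAST": 100, "c_129": 7,
             "c_unassigned": 0, "total": 107},
            {"gene": "F", "clone": "m2", "c_CAST": 50, "c_129": 50,
             "c_unassigned": 0, "total": 100}])
        assert ac.knockout_allele_ratio(matrix, {"m1": ALLELE_B}, "F") == pytest.approx(0.07)
        assert ac.knockout_allele_ratio(matrix, {"m2": ALLELE_B}, "F") == pytest.approx(1.0)

    def test_zero_intact_count_is_an_error(self):
        matrix = pd.DataFrame([{"gene": "F", "clone": "m", "c_CAST": 0,
                                "c_129": 5, "c_unassigned": 0, "total": 5}])
        with pytest.raises(ValueError, match="intact"):
            ac.knockout_allele_ratio(matrix, {"m": ALLELE_B}, "F")

    @pytest.mark.parametrize("eps", [0.0, 0.07, 0.5, 1.0])
    def test_cis_parameter_recovery(self, dense_reference, eps):
        # Poisson limit at a read depth where the Monte-Carlo SE of the
        # ratio estimate is < 0.01; the bias bound (0.01) is tested on
        # top of a 3-sigma allowance for the remaining sampling noise
        reference = dense_reference
        cfg = sh.SimulationConfig(seed=41 + int(eps * 100), cis_residual=eps,
                                  nb_dispersion=0.0, n_reads_per_clone=300_000)
        clones = sh.simulate_clones(reference, ["monoallelic_129"] * 6, cfg)
        focal = reference.focal_gene.name
        mats = []
        for c in clones:
            reads = sh.simulate_rnaseq(c.genotype, reference, cfg)
            reads = reads[reads["gene"] == focal]
            mats.append(ac.count_reads(reads, reference, reference.variants,
                                       c.genotype.clone_id))
        matrix = pd.concat(mats, ignore_index=True)
        deleted = {c.genotype.clone_id: ALLELE_B for c in clones}
        est = ac.knockout_allele_ratio(matrix, deleted, focal)
        if eps == 0.0:
            assert est == 0.0
        else:
            per_clone = [ac.knockout_allele_ratio(matrix, {cid: allele}, focal)
                         for cid, allele in deleted.items()]
            se = np.std(per_clone, ddof=1) / np.sqrt(len(per_clone))
            assert se < 0.01
            assert abs(est - eps) < 0.01 + 3 * se


class TestMappingBiasInteraction:
    def test_planted_repeat_skews_specificity_until_variant_blacklisted(self):
        # A CAST-context repeat makes CAST reads multi-map (discarded by
        # the unique-placement screen) while 129 reads stay unique: the
        # gene drifts 129-specific.  Dummy-read QC flags the SNP, after
        # which neither allele draws evidence from it and balance returns.
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), size=500))
        seq = core + "".join(rng.choice(list("ACGT"), size=100)) + core[180:320]
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}
        pos = 250
        gene = sh.GeneModel("G1", "chrT", 100, 400, "+", "focal", 10.0)
        ref = make_toy_reference(seq, [(pos, seq[pos - 1], other[seq[pos - 1]])],
                                 genes=[gene])
        mapper = vq.ExactMatchMapper(ref.haplotypes)

        variant = next(ref.variants.itertuples())
        bias = vq.assess_mapping_bias(
            vq.generate_dummy_reads(variant, ref, 50), mapper)
        assert bias["bias_score"] > 0.5  # QC would blacklist this SNP

        reads = []
        for allele in (ALLELE_A, ALLELE_B):
            hap = ref.haplotypes[allele]["chrT"]
            for t in range(0, 250, 5):
                reads.append((f"{allele}:{t}", "G1", allele, t, "+",
                              hap[100 + t:150 + t]))
        reads = pd.DataFrame(reads, columns=["read_id", "gene", "allele",
                                             "tstart", "strand", "seq"])

        biased = ac.count_reads(reads, ref, ref.variants, "c", mapper=mapper)
        s_biased = ac.allele_specificity(biased)["s"].iloc[0]
        assert s_biased < -0.5

        flagged = ref.variants.copy()
        flagged.loc[:, ["mapping_bias", "usable"]] = [[True, False]]
        clean = ac.count_reads(reads, ref, flagged, "c", mapper=mapper)
        s_clean = ac.allele_specificity(clean)["s"].iloc[0]
        assert abs(s_clean) < 0.2
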