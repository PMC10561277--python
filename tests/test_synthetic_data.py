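"""Generator contracts: determinism, planted statistics, truth consistency."""

import math

import numpy as np
import pytest

from nappan import synthetic_data as sd
from nappan.core_model import Thresholds
from nappan.nap_identify import validate_hits


def small_spec(seed=0, **kwargs):
    defaults = dict(
        lineages=[sd.LineageSpec("L1", 10)],
        families=[sd.FamilySpec("HU", 1.0, (1, 1))],
        seed=seed)
    defaults.update(kwargs)
    return sd.PangenomeSpec(**defaults)


class TestGeneratePangenome:
    def test_seed_determinism_byte_identical(self):
        spec = small_spec(seed=9, mge_rate=1.0, flexible_in_mge_fraction=0.5,
                          families=[sd.FamilySpec("HU", 0.7, (1, 3), flexible=True)])
        a = sd.generate_pangenome(spec)
        b = sd.generate_pangenome(spec)
        assert [g.genome_id for g in a[0]] == [g.genome_id for g in b[0]]
        assert a[1] == b[1]
        assert a[2].copy_numbers == b[2].copy_numbers
        assert {g: [f.gene_id for f in v] for g, v in a[2].genes.items()} == \
               {g: [f.gene_id for f in v] for g, v in b[2].genes.items()}

    def test_full_presence_single_dose(self):
        genomes, hits, truth = sd.generate_pangenome(small_spec(seed=1))
        assert len(genomes) == 10
        assert all(truth.copy_numbers[g.genome_id]["HU"] == 1 for g in genomes)
        assert sum(1 for h in hits if h.profile_id == "HU") == 10

    def test_half_presence_binomially_distributed(self):
        spec = small_spec(seed=2, lineages=[sd.LineageSpec("L1", 200)],
                          families=[sd.FamilySpec("Fis", 0.5, (1, 1))])
        _, _, truth = sd.generate_pangenome(spec)
        total = sum(v["Fis"] for v in truth.copy_numbers.values())
        sdev = math.sqrt(200 * 0.5 * 0.5)
        assert abs(total - 100) <= 3 * sdev

    def test_truth_and_hits_mutually_consistent(self, thresholds):
        spec = small_spec(seed=3, mge_rate=1.0, flexible_in_mge_fraction=0.6,
                          families=[sd.FamilySpec("HU", 0.8, (1, 2), flexible=True),
                                    sd.FamilySpec("Fis", 1.0, (1, 1))])
        genomes, hits, truth = sd.generate_pangenome(spec)
        cands = validate_hits(hits, thresholds, genome_of=truth.genome_of)
        # every planted NAP validates, no decoy survives
        assert {c.protein_id for c in cands} == set(truth.genome_of)
        planted = sum(sum(v.values()) for v in truth.copy_numbers.values())
        assert len(cands) == planted
        # each planted NAP appears exactly once as a gene
        gene_ids = {g.gene_id for gid in truth.genes for g in truth.genes[gid]}
        assert set(truth.gene_of.values()) <= gene_ids

    def test_mge_members_lie_inside_their_regions(self):
        spec = small_spec(seed=4, mge_rate=2.0, flexible_in_mge_fraction=1.0,
                          families=[sd.FamilySpec("IHF_A", 1.0, (2, 3), flexible=True)])
        _, _, truth = sd.generate_pangenome(spec)
        regions = {r.element_id: r for gid in truth.regions for r in truth.regions[gid]}
        placed = [(p, e) for p, e in truth.mge_membership.items() if e]
        assert placed, "expected some MGE-resident NAPs"
        for protein, element in placed:
            genome = truth.genome_of[protein]
            gene = next(g for g in truth.genes[genome] if g.gene_id == protein)
            region = regions[element]
            assert region.start <= gene.midpoint <= region.end

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            small_spec(mge_rate=-1)
        with pytest.raises(ValueError):
            sd.PangenomeSpec(lineages=[sd.LineageSpec("L", 0)], families=[])
        with pytest.raises(ValueError):
            sd.generate_pangenome(small_spec(
                families=[sd.FamilySpec("HU", 1.5, (1, 1))]))


class TestTable1Spec:
    def test_lineages_sum_to_93(self):
        spec = sd.table1_spec()
        assert len(spec.lineages) == 16
        assert sum(l.n_genomes for l in spec.lineages) == 93

    def test_afe_ebfc_full_presence(self):
        spec = sd.table1_spec()
        ebfc = next(f for f in spec.families if f.family == "EbfC")
        assert ebfc.presence("AFE") == 1.0 and ebfc.dose("AFE") == (1, 1)

    def test_fca_lrp_absent(self):
        spec = sd.table1_spec()
        lrp = next(f for f in spec.families if f.family == "Lrp")
        assert lrp.presence("FCA") == 0.0


class TestMarkerSequences:
    TREE = "((A:0.05,B:0.05):0.02,(C:0.05,D:0.05):0.02);"

    def test_zero_rate_identical_leaves(self):
        seqs = sd.generate_marker_sequences(self.TREE, 60, 0.0, seed=0)
        assert len(set(seqs.values())) == 1

    def test_seed_determinism(self):
        a = sd.generate_marker_sequences(self.TREE, 100, 1.0, seed=5)
        b = sd.generate_marker_sequences(self.TREE, 100, 1.0, seed=5)
        assert a == b

    def test_pairwise_distance_matches_analytic_expectation(self):
        # leaves at patristic distance 0.1; per-branch replacement model gives
        # identity = a + (1 - a)/20 with a the product of per-branch
        # (1 - 20 p / 19) factors
        tree = "(A:0.05,B:0.05):0.0;"
        L = 10_000
        seqs = sd.generate_marker_sequences(tree, L, 1.0, seed=11)
        p_branch = 1 - math.exp(-0.05)
        alpha = (1 - 20 * p_branch / 19) ** 2
        expected_diff = 1 - (alpha + (1 - alpha) / 20)
        a = np.frombuffer(seqs["A"].encode(), dtype="S1")
        b = np.frombuffer(seqs["B"].encode(), dtype="S1")
        observed = float((a != b).mean())
        sdev = math.sqrt(expected_diff * (1 - expected_diff) / L)
        assert abs(observed - expected_diff) <= 3 * sdev

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.generate_marker_sequences(self.TREE, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            sd.generate_marker_sequences(self.TREE, 100, -0.5, seed=0)


class TestCoverage:
    def _genome(self, length=20_000):
        from nappan.core_model import GenomeRecord, Replicon
        rep = Replicon("chr", length)
        return GenomeRecord("G", "L", length, replicons=(rep,))

    def test_uniform_multipliers_recover_mean_depth(self):
        from nappan.core_model import GeneFeature
        genome = self._genome()
        genes = [GeneFeature("g1", "chr", 1_000, 2_000)]
        tracks = sd.generate_coverage(genome, genes, {"g1": 1.0}, mean_depth=30, seed=0)
        depth = tracks["chr"]
        sdev = math.sqrt(30 / depth.size)
        assert abs(float(depth.mean()) - 30) <= 3 * sdev

    def test_planted_multiplier_scales_gene_mean(self):
        from nappan.core_model import GeneFeature
        genome = self._genome()
        genes = [GeneFeature("hot", "chr", 5_001, 7_000)]
        tracks = sd.generate_coverage(genome, genes, {"hot": 12.0}, mean_depth=20, seed=1)
        depth = tracks["chr"]
        gene_mean = float(depth[5_000:7_000].mean())
        background = float(np.concatenate([depth[:5_000], depth[7_000:]]).mean())
        assert gene_mean / background == pytest.approx(12.0, rel=0.1)

    def test_seed_determinism(self):
        genome = self._genome(2_000)
        a = sd.generate_coverage(genome, [], {}, mean_depth=10, seed=7)
        b = sd.generate_coverage(genome, [], {}, mean_depth=10, seed=7)
        np.testing.assert_array_equal(a["chr"], b["chr"])

    def test_negative_parameters_rejected(self):
        genome = self._genome(1_000)
        with pytest.raises(ValueError):
            sd.generate_coverage(genome, [], {}, mean_depth=-1, seed=0)
        with pytest.raises(ValueError):
            sd.generate_coverage(genome, [], {"g": -2.0}, mean_depth=5, seed=0)
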