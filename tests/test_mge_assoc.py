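"""Element classification, NAP-element mapping, covariation and IR detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from oracles import ir_oracle

from nappan.core_model import DomainHit, GeneFeature, NAPCandidate
from nappan.mge_assoc import (MGERegion, classify_element, covariation,
                              find_inverted_repeats, map_naps_to_mges,
                              role_from_product)


def candidate(gid, family="HU"):
    return NAPCandidate(protein_id=gid, genome_id="G", family=family,
                        best_hit=DomainHit(gid, family, 1e-20, 99.0), gene_id=gid)


def region(eid, start=1, end=1, whole=False, roles=()):
    return MGERegion(element_id=eid, replicon_id="chr", start=start, end=end,
                     whole_replicon=whole,
                     hallmark_genes=[(f"h{i}", r) for i, r in enumerate(roles)])


class TestClassifyElement:
    @pytest.mark.parametrize("roles,expected", [
        (("t4ss", "integrase"), "ICE"),
        (("t4ss", "integrase", "relaxase"), "ICE"),
        (("relaxase", "integrase"), "IME"),
        (("transposase",), "island"),
        ((), "island"),
        (("relaxase",), "island"),
    ])
    def test_rule_table(self, roles, expected):
        assert classify_element(region("e", 1, 10_000, roles=roles)) == expected

    def test_whole_replicon_is_plasmid(self):
        assert classify_element(region("p", whole=True)) == "plasmid"

    def test_keyword_role_mapper(self):
        assert role_from_product("Type IV secretion system protein VirB1") == "t4ss"
        assert role_from_product("MobM relaxase family protein") == "relaxase"
        assert role_from_product("integrase/recombinase XerD") == "integrase"
        assert role_from_product("ribosomal protein S1") is None


class TestMapNapsToMges:
    def test_midpoint_containment(self):
        genes = [GeneFeature("n1", "chr", 50, 950)]
        out = map_naps_to_mges([candidate("n1")], genes, [region("e1", 1, 10_000)])
        assert [c.protein_id for c in out["e1"]] == ["n1"]

    def test_outside_region_unassigned(self):
        genes = [GeneFeature("n1", "chr", 20_000, 21_000)]
        out = map_naps_to_mges([candidate("n1")], genes, [region("e1", 1, 10_000)])
        assert out["e1"] == []

    def test_plasmid_replicon_assignment(self):
        genes = [GeneFeature("n1", "pX", 10, 500)]
        plasmid = MGERegion(element_id="pX_el", replicon_id="pX", whole_replicon=True)
        out = map_naps_to_mges([candidate("n1")], genes, [plasmid])
        assert len(out["pX_el"]) == 1

    def test_nested_regions_resolve_to_innermost(self):
        genes = [GeneFeature("n1", "chr", 4_900, 5_100)]
        outer, inner = region("outer", 1, 50_000), region("inner", 4_000, 6_000)
        out = map_naps_to_mges([candidate("n1")], genes, [outer, inner])
        assert [c.protein_id for c in out["inner"]] == ["n1"] and out["outer"] == []


class TestCovariation:
    def test_proportional_counts_give_r_one(self):
        naps = {f"g{i}": {"HU": i, "IHF_A": i} for i in range(1, 6)}
        marks = {f"g{i}": 2 * i for i in range(1, 6)}
        assert covariation(naps, marks).pearson_r == pytest.approx(1.0)

    def test_independent_counts_near_zero(self, rng):
        naps = {f"g{i}": {"HU": int(rng.poisson(3))} for i in range(200)}
        marks = {f"g{i}": int(rng.poisson(3)) for i in range(200)}
        assert abs(covariation(naps, marks).pearson_r) < 0.2

    def test_genome_set_mismatch(self):
        with pytest.raises(ValueError):
            covariation({"g1": {"HU": 1}}, {"g2": 1})


REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(REVCOMP)[::-1]


class TestInvertedRepeats:
    def test_planted_stem8_loop4(self):
        s = "GACGTTCA"
        seq = "TTTTTT" + s + "AATA" + rc(s) + "TTTTTT"
        hits = find_inverted_repeats(seq, min_stem=6, max_loop=10, max_mismatch=0)
        assert [(h.stem_len, h.loop_len) for h in hits] == [(8, 4)]

    def test_planted_stem10_loop4(self):
        s = "CTAGGTACGA"
        seq = "TTTTTT" + s + "ATAA" + rc(s) + "TTTTTT"
        hits = find_inverted_repeats(seq, min_stem=6, max_loop=10, max_mismatch=0)
        assert [(h.stem_len, h.loop_len) for h in hits] == [(10, 4)]

    def test_n_never_matches(self):
        s = "GACGTTCA"
        broken = s[:4] + "N" + s[5:]  # N in the left arm breaks the 8-bp stem
        seq = "TTTTTT" + broken + "AATA" + rc(s) + "TTTTTT"
        hits = find_inverted_repeats(seq, min_stem=4, max_loop=10, max_mismatch=0)
        assert all(h.stem_len < 8 for h in hits)

    @pytest.mark.parametrize("bad_kwargs", [
        dict(min_stem=3, max_loop=4), dict(min_stem=4, max_loop=-1),
    ])
    def test_parameter_validation(self, bad_kwargs):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGTACGTACGT", max_mismatch=0, **bad_kwargs)

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGU", 4, 4)

    def test_random_kilobase_matches_oracle_at_long_stems(self, rng):
        seq = random_dna(rng, 1000)
        hits = find_inverted_repeats(seq, min_stem=12, max_loop=10, max_mismatch=0)
        assert max((h.stem_len for h in hits), default=0) < 40
        assert ir_oracle(seq, 12, 10, 0, k_max=40) == sorted(astuple(h) for h in hits)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGTN", min_size=20, max_size=120),
           min_stem=st.integers(4, 7), max_loop=st.integers(0, 8),
           max_mismatch=st.integers(0, 2))
    def test_matches_brute_force_oracle(self, seq, min_stem, max_loop, max_mismatch):
        got = [astuple(h) for h in find_inverted_repeats(seq, min_stem, max_loop, max_mismatch)]
        assert sorted(got) == ir_oracle(seq, min_stem, max_loop, max_mismatch)

    def test_no_duplicate_arm_coordinates(self, rng):
        seq = random_dna(rng, 400, with_n=True)
        hits = find_inverted_repeats(seq, 4, 8, 1)
        coords = [(h.left_start, h.left_end, h.right_start, h.right_end) for h in hits]
        assert len(coords) == len(set(coords))


def astuple(h):
    return (h.left_start, h.left_end, h.right_start, h.right_end,
            h.stem_len, h.loop_len, h.mismatches)
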