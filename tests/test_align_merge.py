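import numpy as np
import pytest

from conftest import make_random_record
from oracles import compose_pairs_oracle, random_monotone_pairs

from issalign.align_merge import (
    aligned_region_length,
    alignment_from_map,
    build_merged,
    chain_to_alignment,
    compose_maps,
    select_alignment,
)
from issalign.errors import CompositionError, InputError
from issalign.iss_search import IssConfig
from issalign.localalign import smith_waterman
from issalign.seqcore import (
    GAP,
    PairwiseAlignment,
    Region,
    ResidueMap,
    SearchHit,
    SearchPath,
    SequenceRecord,
    identity_map,
    matched_pairs,
    residue_map_from_alignment,
)
from issalign.synthfam import generate_family


class TestComposeMaps:
    def test_identity_law(self):
        m = ResidueMap("a", "b", ((0, 2), (1, 3), (4, 5)))
        ident = identity_map("b", 10, "b")
        assert compose_maps(m, ident).pairs == m.pairs

    def test_definition_example(self):
        m1 = ResidueMap("a", "b", ((0, 2), (1, 3), (4, 5)))
        m2 = ResidueMap("b", "c", ((2, 0), (5, 1)))
        assert compose_maps(m1, m2).pairs == ((0, 0), (4, 1))

    def test_id_mismatch(self):
        m1 = ResidueMap("a", "b", ((0, 0),))
        m2 = ResidueMap("c", "d", ((0, 0),))
        with pytest.raises(CompositionError):
            compose_maps(m1, m2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p1 = random_monotone_pairs(rng, 40, 20)
            p2 = random_monotone_pairs(rng, 40, 20)
            m1 = ResidueMap("a", "b", p1)
            m2 = ResidueMap("b", "c", p2)
            got = sorted(compose_maps(m1, m2).pairs)
            assert got == compose_pairs_oracle(p1, p2)

    def test_associativity(self, rng):
        for _ in range(100):
            a = ResidueMap("a", "b", random_monotone_pairs(rng, 30, 15))
            b = ResidueMap("b", "c", random_monotone_pairs(rng, 30, 15))
            c = ResidueMap("c", "d", random_monotone_pairs(rng, 30, 15))
            left = compose_maps(compose_maps(a, b), c)
            right = compose_maps(a, compose_maps(b, c))
            assert left.pairs == right.pairs


class TestAlignedRegionLength:
    def test_empty(self):
        assert aligned_region_length(PairwiseAlignment("a", "b", 0, 0, "", "")) == 0

    def test_full_identity(self):
        row = "A" * 40
        assert aligned_region_length(PairwiseAlignment("a", "b", 0, 0, row, row)) == 40

    def test_gap_columns_excluded(self):
        row_a = "A" * 30 + "C" * 10
        row_b = "A" * 30 + GAP * 10
        assert aligned_region_length(PairwiseAlignment("a", "b", 0, 0, row_a, row_b)) == 30


class TestSelectAlignment:
    def _aln(self, n_matched, n_gaps=0):
        return PairwiseAlignment(
            "q", "t", 0, 0, "A" * n_matched + "C" * n_gaps,
            "A" * n_matched + GAP * n_gaps,
        )

    def test_longer_via_wins(self):
        via, direct = self._aln(50), self._aln(30)
        chosen, flag = select_alignment(via, direct)
        assert chosen is via and flag == "intermediate"

    def test_longer_direct_wins(self):
        via, direct = self._aln(10), self._aln(40)
        chosen, flag = select_alignment(via, direct)
        assert chosen is direct and flag == "direct"

    def test_tie_goes_to_intermediates(self):
        via, direct = self._aln(20), self._aln(20)
        chosen, flag = select_alignment(via, direct)
        assert chosen is via and flag == "intermediate"

    def test_mismatched_pair_rejected(self):
        other = PairwiseAlignment("x", "y", 0, 0, "A", "A")
        with pytest.raises(InputError):
            select_alignment(self._aln(5), other)


class TestAlignmentFromMap:
    def test_gap_ordering_and_trim(self):
        a = SequenceRecord("a", "MACDEFK")
        b = SequenceRecord("b", "MAWDEFK")
        m = ResidueMap("a", "b", ((1, 1), (4, 4)))
        aln = alignment_from_map(m, a, b)
        # trimmed to anchors; a-insertions before b-insertions between them
        assert aln.row_a == "ACD--E"
        assert aln.row_b == "A--WDE"
        assert aln.start_a == 1 and aln.start_b == 1
        assert residue_map_from_alignment(aln).pairs == m.pairs

    def test_empty_map(self):
        a = SequenceRecord("a", "MACD")
        b = SequenceRecord("b", "MACD")
        aln = alignment_from_map(ResidueMap("a", "b"), a, b)
        assert aln.is_empty


def _chain_path(ids, regions, layer0_query="Q"):
    hits = []
    for k, (sid, reg) in enumerate(zip(ids[1:], regions)):
        hits.append(
            SearchHit(ids[k], sid, Region(ids[k], 0, 1), reg, 1e-5, 10.0, k)
        )
    return SearchPath(tuple(hits))


class TestChainToAlignment:
    def test_identity_chain(self, scheme):
        res = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        seqs = {
            "Q": SequenceRecord("Q", res),
            "I": SequenceRecord("I", res),
            "T": SequenceRecord("T", res),
        }
        path = _chain_path(
            ["Q", "I", "T"],
            [Region("I", 0, len(res)), Region("T", 0, len(res))],
        )
        cfg = IssConfig(n_intermediate_layers=1, extension_lengths=(0, 0))
        pairwise, merged = chain_to_alignment(path, seqs, cfg)
        assert pairwise.row_a == res and pairwise.row_b == res
        assert merged.ids == ("Q", "I", "T")
        assert all(text == res for _, text in merged.rows)

    def test_identity_intermediate_projects_direct_alignment(self, scheme, rng):
        # I is an exact copy of Q: matched pairs equal direct SW of Q vs T
        fam = generate_family(seed=11, ancestor_length=120, n_intermediates=1,
                              branch_identity=0.6, indel_rate=0.02)
        q, t = fam.query, fam.template
        seqs = {"Q": q, "QC": SequenceRecord("QC", q.residues), "T": t}
        path = _chain_path(
            ["Q", "QC", "T"],
            [Region("QC", 0, q.length), Region("T", 0, t.length)],
        )
        cfg = IssConfig(n_intermediate_layers=1, extension_lengths=(0, 0))
        pairwise, _ = chain_to_alignment(path, seqs, cfg)
        direct = smith_waterman(q, t, cfg.scheme).alignment
        assert matched_pairs(pairwise) == matched_pairs(direct)

    def test_composition_equals_edgewise_oracle(self, scheme):
        fam = generate_family(seed=5, ancestor_length=150, n_intermediates=2,
                              branch_identity=0.6, indel_rate=0.02)
        seqs = fam.sequences()
        ids = [r.id for r in fam.chain]
        regions = [Region(i, 0, seqs[i].length) for i in ids[1:]]
        path = _chain_path(ids, regions)
        cfg = IssConfig(n_intermediate_layers=2, extension_lengths=(0, 0, 0))
        pairwise, merged = chain_to_alignment(path, seqs, cfg)
        # oracle: full-sequence SW per edge, brute-force composition
        edge_pairs = []
        for a, b in zip(ids, ids[1:]):
            aln = smith_waterman(seqs[a], seqs[b], cfg.scheme).alignment
            edge_pairs.append(matched_pairs(aln))
        acc = edge_pairs[0]
        for nxt in edge_pairs[1:]:
            acc = compose_pairs_oracle(acc, nxt)
        assert sorted(matched_pairs(pairwise)) == sorted(acc)

    def test_merged_preserves_every_edge_alignment(self, scheme):
        fam = generate_family(seed=8, ancestor_length=140, n_intermediates=2,
                              branch_identity=0.6, indel_rate=0.02)
        seqs = fam.sequences()
        ids = [r.id for r in fam.chain]
        regions = [Region(i, 0, seqs[i].length) for i in ids[1:]]
        path = _chain_path(ids, regions)
        cfg = IssConfig(n_intermediate_layers=2, extension_lengths=(0, 0, 0))
        _, merged = chain_to_alignment(path, seqs, cfg)
        for a, b in zip(ids, ids[1:]):
            edge = smith_waterman(seqs[a], seqs[b], cfg.scheme).alignment
            assert merged.restricted_pairs(a, b) == matched_pairs(edge)
        # every row ungapped is a contiguous sub-sequence
        for rid, text in merged.rows:
            assert text.replace(GAP, "") in seqs[rid].residues

    def test_edge_pairs_surviving_composition_are_unchanged(self, scheme):
        fam = generate_family(seed=21, ancestor_length=130, n_intermediates=1,
                              branch_identity=0.6, indel_rate=0.02)
        seqs = fam.sequences()
        ids = [r.id for r in fam.chain]
        regions = [Region(i, 0, seqs[i].length) for i in ids[1:]]
        cfg = IssConfig(n_intermediate_layers=1, extension_lengths=(0, 0))
        pairwise, _ = chain_to_alignment(_chain_path(ids, regions), seqs, cfg)
        final_pairs = set(matched_pairs(pairwise))
        e1 = matched_pairs(smith_waterman(seqs[ids[0]], seqs[ids[1]], cfg.scheme).alignment)
        e2 = dict(matched_pairs(smith_waterman(seqs[ids[1]], seqs[ids[2]], cfg.scheme).alignment))
        for i, j in e1:
            if j in e2:
                assert (i, e2[j]) in final_pairs

    def test_unresolvable_id_raises(self, scheme):
        path = _chain_path(["Q", "T"], [Region("T", 0, 10)])
        with pytest.raises(InputError):
            chain_to_alignment(path, {"Q": SequenceRecord("Q", "ACDEFGHIKL")},
                               IssConfig(n_intermediate_layers=0))

    def test_disjoint_chain_yields_empty_alignment(self, scheme):
        # no residue of Q scores positive against all-W I: the first edge map
        # is empty, so the composed map is empty
        q = SequenceRecord("Q", "ACDEGHIKLN" * 3)
        i = SequenceRecord("I", "W" * 30)
        t = SequenceRecord("T", "ACDEGHIKLN" * 3)
        path = _chain_path(["Q", "I", "T"], [Region("I", 0, 30), Region("T", 0, 30)])
        cfg = IssConfig(n_intermediate_layers=1, extension_lengths=(0, 0))
        pairwise, merged = chain_to_alignment(path, {"Q": q, "I": i, "T": t}, cfg)
        assert pairwise.is_empty


class TestBuildMerged:
    def test_simple_stack(self):
        seqs = {
            "a": SequenceRecord("a", "ACDEF"),
            "b": SequenceRecord("b", "ACDEF"),
            "c": SequenceRecord("c", "ACDEF"),
        }
        maps = [identity_map("a", 5, "b"), identity_map("b", 5, "c")]
        merged = build_merged(["a", "b", "c"], seqs, maps)
        assert [t for _, t in merged.rows] == ["ACDEF"] * 3

    def test_insertion_threading(self):
        # b has an extra residue unmatched in both neighbours
        seqs = {
            "a": SequenceRecord("a", "ACD"),
            "b": SequenceRecord("b", "ACWD"),
            "c": SequenceRecord("c", "ACD"),
        }
        m_ab = ResidueMap("a", "b", ((0, 0), (1, 1), (2, 3)))
        m_bc = ResidueMap("b", "c", ((0, 0), (1, 1), (3, 2)))
        merged = build_merged(["a", "b", "c"], seqs, [m_ab, m_bc])
        assert merged.row("b").replace(GAP, "") == "ACWD"
        assert merged.restricted_pairs("a", "b") == list(m_ab.pairs)
        assert merged.restricted_pairs("b", "c") == list(m_bc.pairs)

    def test_empty_edge_map_gives_empty_merge(self):
        seqs = {"a": SequenceRecord("a", "ACD"), "b": SequenceRecord("b", "ACD")}
        merged = build_merged(["a", "b"], seqs, [ResidueMap("a", "b")])
        assert merged.n_columns == 0

    def test_guarantee_selected_at_least_direct(self, scheme):
        # by construction the selection can never lose to the direct aligner
        for seed in (2, 9, 14):
            fam = generate_family(seed=seed, ancestor_length=120,
                                  n_intermediates=2, branch_identity=0.55,
                                  indel_rate=0.02)
            seqs = fam.sequences()
            ids = [r.id for r in fam.chain]
            regions = [Region(i, 0, seqs[i].length) for i in ids[1:]]
            cfg = IssConfig(n_intermediate_layers=2, extension_lengths=(0, 0, 0))
            via, _ = chain_to_alignment(_chain_path(ids, regions), seqs, cfg)
            direct = smith_waterman(fam.query, fam.template, cfg.scheme).alignment
            chosen, _ = select_alignment(via, direct)
            assert aligned_region_length(chosen) >= aligned_region_length(direct)
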