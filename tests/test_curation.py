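import itertools
from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famkit.curation import (
    CurationConfig,
    assign_names,
    filter_redundant,
    pairwise_identity,
)
from famkit.io import GeneModel, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def nw_score_oracle(a: str, b: str) -> int:
    """Recursive Needleman-Wunsch score (match=1/mismatch=0/gap=-1)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == 0:
            return -j
        if j == 0:
            return -i
        return max(
            best(i - 1, j - 1) + (1 if a[i - 1] == b[j - 1] else 0),
            best(i - 1, j) - 1,
            best(i, j - 1) - 1,
        )

    return best(len(a), len(b))


class TestPairwiseIdentity:
    def test_identical(self):
        r = ProteinRecord("a", "MKVLW")
        assert pairwise_identity(r, r) == 1.0

    def test_three_quarters(self):
        assert pairwise_identity(
            ProteinRecord("a", "AAAA"), ProteinRecord("b", "AAAT")
        ) == 0.75

    def test_symmetric(self):
        a, b = ProteinRecord("a", "MKVLWAAG"), ProteinRecord("b", "MKLWAG")
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    @settings(max_examples=40, deadline=None)
    @given(st.text(AA, min_size=1, max_size=20), st.text(AA, min_size=1, max_size=20))
    def test_matches_dp_oracle_on_random_sequences(self, s1, s2):
        """The traceback's (matches, length) must realize the optimal NW score.

        With match=1/mismatch=0/gap=-1 the score of any alignment equals
        matches - gap columns = matches - (2*length - len(a) - len(b)).
        """
        from famkit.curation import _needleman_wunsch

        matches, aligned, length = _needleman_wunsch(s1, s2)
        gaps = 2 * length - len(s1) - len(s2)
        assert matches - gaps == nw_score_oracle(s1, s2)
        assert aligned == length - gaps
        assert 0.0 <= matches / aligned <= 1.0


class TestFilterRedundant:
    def test_keeps_longest_of_identical_pair(self):
        long = ProteinRecord("long", "MKVLW" * 20)
        short = ProteinRecord("short", "MKVLW" * 16)
        kept, removed = filter_redundant([short, long])
        assert [r.id for r in kept] == ["long"]
        assert removed[0][:2] == ("short", "long")

    def test_dissimilar_pair_both_kept(self):
        a = ProteinRecord("a", "MKVLWMKVLW")
        b = ProteinRecord("b", "GGDEFGGDEF")
        kept, removed = filter_redundant([a, b])
        assert {r.id for r in kept} == {"a", "b"}
        assert removed == []

    def test_identical_triple_keeps_longest_only(self):
        """Greedy longest-first equals the brute-force-optimal keep set.

        A(10) ~ B(9) ~ C(8) all pairwise-identical: every valid keep set
        must cover B and C with a longer keeper, so {A} is the unique
        maximal result; brute force over all keep-subsets confirms it.
        """
        a = ProteinRecord("A", "MKVLWAAGGE")
        b = ProteinRecord("B", "MKVLWAAGG")
        c = ProteinRecord("C", "MKVLWAAG")
        records = [a, b, c]
        cfg = CurationConfig(identity_threshold=0.79)
        idents = {
            (x.id, y.id): pairwise_identity(x, y)
            for x, y in itertools.permutations(records, 2)
        }
        assert all(v >= 0.79 for v in idents.values())
        valid_keep_sets = []
        for mask in range(1, 8):
            keep = [r for k, r in enumerate(records) if mask >> k & 1]
            removed = [r for r in records if r not in keep]
            ok = all(
                any(
                    idents[(rm.id, kp.id)] >= 0.79 and len(kp) >= len(rm)
                    for kp in keep
                )
                for rm in removed
            )
            if ok:
                valid_keep_sets.append({r.id for r in keep})
        smallest = min(valid_keep_sets, key=len)
        kept, _ = filter_redundant(records, cfg)
        assert {r.id for r in kept} == smallest == {"A"}

    def test_idempotent(self, tiny_records):
        kept1, _ = filter_redundant(tiny_records)
        kept2, _ = filter_redundant(kept1)
        assert kept1 == kept2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_redundant([])


def _gene(gid: str, chrom: str, start: int) -> GeneModel:
    return GeneModel(gid, chrom, "+", ((start, start + 299),))


class TestAssignNames:
    def test_chromosome_then_start_order(self):
        genes = [
            _gene("x", "chr1", 100),
            _gene("y", "chr1", 50),
            _gene("z", "chr2", 10),
        ]
        names = assign_names(genes)
        assert names == {"y": "VdbHLH001", "x": "VdbHLH002", "z": "VdbHLH003"}

    def test_unplaced_numbered_last(self):
        genes = [_gene("u", "UNPLACED", 5), _gene("p", "chr19", 999)]
        names = assign_names(genes)
        assert names["p"] == "VdbHLH001"
        assert names["u"] == "VdbHLH002"

    def test_chr10_sorts_after_chr2(self):
        genes = [_gene("a", "chr10", 1), _gene("b", "chr2", 1)]
        names = assign_names(genes)
        assert names["b"] == "VdbHLH001"

    @settings(max_examples=20, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_input_order_invariance(self, rnd):
        genes = [
            _gene(f"g{i}", f"chr{1 + i % 3}", 10 * i + 1) for i in range(8)
        ] + [_gene("u1", "UNPLACED", 7)]
        reference = assign_names(genes)
        shuffled = list(genes)
        rnd.shuffle(shuffled)
        assert assign_names(shuffled) == reference

    def test_naming_is_bijective_onto_consecutive_range(self):
        genes = [_gene(f"g{i}", "chr3", 1000 + i) for i in range(12)]
        names = assign_names(genes)
        assert sorted(names.values()) == [f"VdbHLH{i:03d}" for i in range(1, 13)]
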