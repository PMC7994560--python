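import itertools

import numpy as np
import pytest

from famkit.domain import (
    BindingCategory,
    BindingRuleSet,
    ConsensusCategory,
    DomainAlignment,
    build_profile,
    classify_alignment,
    classify_binding,
    count_basic,
    plant_vs_animal_report,
)
from famkit.io import AlignedBlock
from famkit.simulate import SimSpec, sim_alignment
from tests.conftest import make_domain_row


class TestBuildProfile:
    def test_identical_rows_fully_conserved(self):
        row = make_domain_row()
        block = AlignedBlock(tuple(f"m{i}" for i in range(10)), (row,) * 10)
        profile = build_profile(block)
        assert all(
            c.category is ConsensusCategory.CONSERVED90 and c.consensus_rate == 1.0
            for c in profile.columns
        )

    def test_seven_of_ten_is_conserved50_only(self):
        rows = tuple("R" if i < 7 else "K" for i in range(10))
        block = AlignedBlock(tuple(f"m{i}" for i in range(10)), rows)
        (col,) = build_profile(block).columns
        assert col.consensus_residue == "R"
        assert col.consensus_rate == pytest.approx(0.7)
        assert col.category is ConsensusCategory.CONSERVED50

    def test_gaps_excluded_from_denominator(self):
        block = AlignedBlock(("a", "b", "c", "d"), ("R", "R", "R", "-"))
        (col,) = build_profile(block).columns
        assert col.consensus_rate == 1.0

    def test_all_gap_column_has_no_category(self):
        block = AlignedBlock(("a", "b"), ("-A", "-A"))
        profile = build_profile(block)
        assert profile.columns[0].category is ConsensusCategory.NONE
        assert profile.columns[0].consensus_residue is None

    def test_planted_frequencies_recovered_within_3_se(self):
        """Recovered per-column frequencies track planted rates (3 binomial SEs)."""
        spec = SimSpec(rng_seed=7, n_members=115, default_rate=0.7)
        block, truth = sim_alignment(spec)
        profile = build_profile(block)
        n = spec.n_members
        for col, (residue, rate) in truth.items():
            se = np.sqrt(rate * (1 - rate) / n)
            observed = profile.columns[col - 1].frequencies.get(residue, 0.0)
            assert abs(observed - rate) <= 3 * se


class TestCountBasic:
    def test_six_basics_padded(self):
        row = "RRKHRK" + "A" * 59
        assert count_basic(row) == 6

    def test_all_gap_basic_region(self):
        row = "-" * 17 + "A" * 48
        assert count_basic(row) == 0

    def test_matches_scan_oracle_on_random_rows(self):
        rng = np.random.default_rng(11)
        symbols = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(50):
            row = "".join(rng.choice(symbols, size=65))
            oracle = sum(1 for ch in row[:17] if ch in "RKH")
            assert count_basic(row) == oracle


def oracle_classify(row: str) -> BindingCategory:
    """Independent transliteration of the basic-region residue rules."""
    basic = sum(1 for ch in row[:17] if ch in "RKH")
    c9, c13, c16, c17 = row[8], row[12], row[15], row[16]
    if basic < 6:
        return BindingCategory.NON_DNA_BINDING
    if c9 in "HK" and c13 == "E" and c17 == "R":
        return BindingCategory.G_BOX
    if c13 == "E" and c16 == "R":
        return BindingCategory.E_BOX_NON_G
    return BindingCategory.NON_E_BOX


class TestClassifyBinding:
    def test_g_box(self):
        call = classify_binding(make_domain_row("H", "E", "R", "R", extra_basic=4))
        assert call.category is BindingCategory.G_BOX
        assert call.basic_count >= 6

    def test_e_box_non_g(self):
        call = classify_binding(make_domain_row("A", "E", "R", "K", extra_basic=5))
        assert call.category is BindingCategory.E_BOX_NON_G

    def test_low_basic_count_overrides_rule_columns(self):
        call = classify_binding(make_domain_row("H", "E", "R", "R", extra_basic=0))
        assert call.basic_count == 3
        assert call.category is BindingCategory.NON_DNA_BINDING

    def test_gap_at_rule_column_fails_that_rule(self):
        call = classify_binding(make_domain_row("-", "E", "R", "R", extra_basic=6))
        assert call.category is BindingCategory.E_BOX_NON_G

    def test_exhaustive_truth_table(self):
        """Rule classifier agrees with brute-force enumeration over all
        residue/gap combinations at columns 9/13/16/17 x basic fillers."""
        choices = {
            9: ["H", "K", "A", "-"],
            13: ["E", "A", "-"],
            16: ["R", "A", "-"],
            17: ["R", "A", "-"],
        }
        n_cases = 0
        for c9, c13, c16, c17 in itertools.product(*choices.values()):
            for extra in range(14):
                row = make_domain_row(c9, c13, c16, c17, extra_basic=extra)
                call = classify_binding(row)
                assert call.category is oracle_classify(row), row[:17]
                n_cases += 1
        assert n_cases == 4 * 3 * 3 * 3 * 14

    def test_categories_partition_members(self):
        spec = SimSpec(rng_seed=3, n_members=40)
        block, _ = sim_alignment(spec)
        calls = classify_alignment(block)
        assert len(calls) == block.n_rows
        assert {c.member_id for c in calls} == set(block.ids)


class TestDomainAlignment:
    def test_regions_must_partition_columns(self):
        block = AlignedBlock(("a", "b"), ("A" * 65, "A" * 65))
        with pytest.raises(ValueError, match="partition"):
            DomainAlignment(block, regions={"basic": (1, 17), "rest": (19, 65)})

    def test_region_lookup(self):
        block = AlignedBlock(("a", "b"), ("A" * 65, "A" * 65))
        aln = DomainAlignment(block)
        assert aln.region_of(9) == "basic"
        assert aln.region_of(65) == "helix2"


class TestPlantVsAnimalReport:
    def _profile(self):
        block = AlignedBlock(
            tuple(f"m{i}" for i in range(10)),
            tuple("RR" for _ in range(9)) + ("RK",),
        )
        return build_profile(block)

    def test_higher_rate_flagged(self):
        report = plant_vs_animal_report(self._profile(), {1: 0.5})
        assert report.loc[0, "more_conserved"]

    def test_equal_rate_not_flagged(self):
        report = plant_vs_animal_report(self._profile(), {2: 0.9})
        assert not report.loc[0, "more_conserved"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plant_vs_animal_report(self._profile(), {})
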