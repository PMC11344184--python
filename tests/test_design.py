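"""Design module: full factorials, orthogonal arrays, blocking, sample size."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxdce as vd
from vaxdce.design import (
    AttributeSpec,
    ChoiceDesign,
    ChoiceTask,
    Profile,
    StudyDesignSpec,
    design_diagnostics,
    johnson_orme_min_n,
    minimum_run_size,
)
from vaxdce.errors import DesignInfeasibleError, InvalidSpecError


def _spec_with_levels(level_counts):
    attrs = tuple(
        AttributeSpec(f"a{i}", tuple(str(j) for j in range(L)))
        for i, L in enumerate(level_counts)
    )
    return StudyDesignSpec(attrs, n_tasks=2, n_blocks=1)


class TestFullFactorial:
    def test_hz_universe_has_4096_profiles(self, hz_spec):
        profiles = vd.enumerate_full_factorial(hz_spec)
        assert len(profiles) == 4096
        assert len(set(profiles)) == 4096

    @pytest.mark.parametrize("level_counts", [(2,), (3, 2), (2, 2, 2), (4, 3)])
    def test_count_matches_brute_force(self, level_counts):
        spec = _spec_with_levels(level_counts)
        profiles = vd.enumerate_full_factorial(spec)
        brute = list(itertools.product(*(a.levels for a in spec.attributes)))
        assert len(profiles) == len(brute) == np.prod(level_counts)
        assert len(set(profiles)) == len(profiles)

    @given(st.lists(st.integers(2, 4), min_size=1, max_size=5))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_count_is_product_of_level_counts(self, level_counts):
        spec = _spec_with_levels(level_counts)
        assert len(vd.enumerate_full_factorial(spec)) == np.prod(level_counts)

    def test_invalid_attribute_rejected(self):
        with pytest.raises(InvalidSpecError):
            AttributeSpec("empty", ())
        with pytest.raises(InvalidSpecError):
            AttributeSpec("single", ("only",))


class TestChoiceDesign:
    def test_auto_run_size_is_32_for_hz_structure(self, hz_spec):
        # five 4-level attributes need 15 main-effect dof, two 2-level need
        # 2 more; 16 runs offer only 15, so the smallest power of two is 32
        assert minimum_run_size(hz_spec) == 32

    def test_auto_design_has_32_tasks(self, hz_design, hz_spec):
        assert hz_design.n_tasks == 32
        assert all(len(t.profiles) == hz_spec.n_alternatives_per_task
                   for t in hz_design.tasks)

    def test_no_task_pairs_identical_profiles(self, hz_design):
        for t in hz_design.tasks:
            assert len(set(t.profiles)) == len(t.profiles)

    def test_two_level_full_factorial_is_orthogonal(self):
        spec = _spec_with_levels((2,))
        d = vd.build_choice_design(spec, run_size=2, seed=1)
        assert d.n_tasks == 2
        firsts = [t.profiles[0].level("a0") for t in d.tasks]
        assert sorted(firsts) == ["0", "1"]

    def test_infeasible_run_size_names_degrees_of_freedom(self, hz_spec):
        with pytest.raises(DesignInfeasibleError, match="degrees of freedom"):
            vd.build_choice_design(hz_spec, run_size=16, seed=1)

    def test_random_pairing_also_avoids_degenerate_tasks(self, hz_spec):
        d = vd.build_choice_design(hz_spec, "auto", seed=99, pairing="random")
        for t in d.tasks:
            assert len(set(t.profiles)) == len(t.profiles)

    def test_identical_profiles_in_task_rejected(self):
        p = Profile((("x", "a"),))
        with pytest.raises(InvalidSpecError):
            ChoiceDesign((ChoiceTask(1, 1, (p, p)),))


class TestBlocking:
    def test_32_tasks_into_4_blocks_of_8(self, hz_design):
        sizes = [len(hz_design.tasks_in_block(b)) for b in hz_design.block_ids]
        assert sizes == [8, 8, 8, 8]

    def test_single_block_is_identity_partition(self, hz_spec):
        d = vd.build_choice_design(_spec_with_levels((2, 2, 2)), "auto", seed=1)
        b = vd.block_design(d, 1, seed=1)
        assert [t.task_id for t in b.tasks_in_block(1)] == [t.task_id for t in d.tasks]

    def test_blocks_partition_tasks(self):
        spec = _spec_with_levels((2, 2, 2))
        d = vd.build_choice_design(spec, run_size=8, seed=5)
        # take 6 tasks into 3 blocks: partition check
        d6 = ChoiceDesign(d.tasks[:6], d.provenance)
        b = vd.block_design(d6, 3, seed=5)
        ids = [t.task_id for t in b.tasks]
        by_block = [sorted(t.task_id for t in b.tasks_in_block(k)) for k in b.block_ids]
        assert sorted(len(g) for g in by_block) == [2, 2, 2]
        assert sorted(x for g in by_block for x in g) == sorted(ids)

    def test_non_divisible_blocking_is_error(self, hz_design):
        with pytest.raises(InvalidSpecError):
            vd.block_design(hz_design, 5)


class TestDiagnostics:
    def test_full_factorial_two_by_two_perfectly_orthogonal(self):
        spec = _spec_with_levels((2, 2))
        profiles = vd.enumerate_full_factorial(spec)
        tasks = tuple(ChoiceTask(i + 1, 1, (p, profiles[(i + 1) % 4]))
                      for i, p in enumerate(profiles))
        diag = design_diagnostics(ChoiceDesign(tasks), spec)
        assert diag.max_abs_correlation == pytest.approx(0.0, abs=1e-12)
        assert diag.balanced and diag.passed

    def test_oa_levels_balanced_eight_times_among_first_alternatives(
            self, hz_design, hz_spec):
        for a in hz_spec.attributes:
            if a.n_levels != 4:
                continue
            counts = {lv: 0 for lv in a.levels}
            for t in hz_design.tasks:
                counts[t.profiles[0].level(a.name)] += 1
            assert all(c == 8 for c in counts.values())

    def test_hz_design_passes_orthogonality(self, hz_design, hz_spec):
        diag = design_diagnostics(hz_design, hz_spec, tolerance=1e-8)
        assert diag.passed

    def test_collinear_design_flagged(self):
        spec = _spec_with_levels((2, 2))
        # two attributes always co-varying
        tasks = []
        for i in range(4):
            lv = str(i % 2)
            other = str((i + 1) % 2)
            tasks.append(ChoiceTask(i + 1, 1, (
                Profile((("a0", lv), ("a1", lv))),
                Profile((("a0", other), ("a1", other))),
            )))
        diag = design_diagnostics(ChoiceDesign(tuple(tasks)), spec)
        assert diag.max_abs_correlation == pytest.approx(1.0)
        assert not diag.passed


class TestJohnsonOrme:
    @pytest.mark.parametrize("c,t,a,expected", [
        (4, 8, 3, 83),    # the HZ study configuration
        (5, 10, 2, 125),  # 500*5/20
        (1, 500, 1, 1),   # boundary
    ])
    def test_rule_of_thumb(self, c, t, a, expected):
        assert johnson_orme_min_n(c, t, a) == expected

    @given(st.integers(1, 10), st.integers(1, 30), st.integers(1, 5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotonicity(self, c, t, a):
        n = johnson_orme_min_n(c, t, a)
        assert johnson_orme_min_n(c + 1, t, a) >= n
        assert johnson_orme_min_n(c, t + 1, a) <= n
        assert johnson_orme_min_n(c, t, a + 1) <= n

    @pytest.mark.parametrize("bad", [(0, 8, 3), (4, -1, 3), (4, 8, 0)])
    def test_domain_errors(self, bad):
        with pytest.raises(InvalidSpecError):
            johnson_orme_min_n(*bad)
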