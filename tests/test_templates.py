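"""Template library construction, assignment and binomial enrichment."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronopattern import (assign_profiles, assign_template,
                           build_template_library, classify_drug_effect,
                           template_enrichment)
from chronopattern.anova import AnovaRecord
from chronopattern.templates import DRUG_CLASSES, TemplateAssignment

from oracles import binom_upper_tail

T6 = [1, 2, 3, 4, 5, 6]


class TestLibrary:
    def test_six_timepoints_give_21_shapes_63_patterns(self, lib6):
        assert len(lib6.shapes) == 21
        assert len(lib6.patterns) == 63
        assert len(set(lib6.patterns)) == 63

    def test_flat_shape_constant_and_ramp_increasing(self, lib6):
        assert set(lib6.shape("00").vector) == {0.0}
        ramp = np.array(lib6.shape("10a").vector)
        assert np.all(np.diff(ramp) > 0)

    def test_b_is_elementwise_negation_of_a(self, lib6):
        for code in ["01", "02", "03", "04", "05", "06", "07", "08", "09", "10"]:
            a = np.array(lib6.shape(code + "a").vector)
            b = np.array(lib6.shape(code + "b").vector)
            assert np.array_equal(b, -a)

    def test_canonical_vectors(self, lib6):
        assert lib6.shape("01a").vector == (1, 0, 0, 0, 0, 0)
        assert lib6.shape("02a").vector == (0, 0.5, 1, 1, 1, 1)
        assert lib6.shape("04a").vector == (0, 0, 0, 0.5, 1, 1)
        assert lib6.shape("05a").vector == (0, 0, 0, 0, 0, 1)
        assert lib6.shape("07a").vector == (0, 0, 1, 0, 0, 0)

    def test_no_two_shapes_are_collinear(self, lib6):
        """Pearson matching can separate every pair of library shapes (a
        shape's own reflection sits at r = -1 and never competes for max r)."""
        zs = [s.zscored() for s in lib6.shapes if not s.is_flat]
        for i in range(len(zs)):
            for j in range(i + 1, len(zs)):
                assert float(zs[i] @ zs[j]) / 6 < 0.95

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            build_template_library([1, 2])

    def test_generalizes_to_other_grid_sizes(self):
        lib5 = build_template_library([1, 2, 3, 4, 5])
        # 2 endpoint changes + (T-3) plateaus + (T-2) spikes + ramp, x2, + flat
        assert len(lib5.shapes) == 4 * 5 - 3


class TestAssignment:
    def test_self_correlation_is_one(self, lib6):
        a = assign_template(lib6.shape("04a").zscored(), lib6)
        assert a.shape == "04a"
        assert a.r == pytest.approx(1.0)

    def test_negated_profile_maps_to_reflection(self, lib6):
        a = assign_template(-lib6.shape("04a").zscored(), lib6)
        assert a.shape == "04b"
        assert a.r == pytest.approx(1.0)

    def test_weak_profile_unassigned_with_bruteforce_max_r(self, lib6):
        rng = np.random.default_rng(123)
        # find a seeded white-noise profile whose best correlation is < 0.85
        for _ in range(100):
            prof = rng.normal(size=6)
            rs = [np.corrcoef(prof, s.vector)[0, 1]
                  for s in lib6.shapes if not s.is_flat]
            if max(rs) < 0.85:
                break
        else:
            pytest.fail("no sub-threshold noise profile found")
        a = assign_template(prof, lib6)
        assert a.shape is None
        assert a.r == pytest.approx(max(rs), abs=1e-12)

    def test_zero_variance_profile_routes_to_flat(self, lib6):
        a = assign_template(np.full(6, 3.3), lib6)
        assert a.shape == "00"

    def test_wrong_length_rejected(self, lib6):
        with pytest.raises(ValueError, match="length"):
            assign_template(np.zeros(5), lib6)

    def test_reflection_consistency_on_random_profiles(self, lib6):
        """Negating every value maps each a-assignment to its b-counterpart."""
        rng = np.random.default_rng(77)
        profs = rng.normal(size=(200, 6))
        s1, r1 = assign_profiles(profs, lib6)
        s2, r2 = assign_profiles(-profs, lib6)
        for a, b in zip(s1, s2):
            if a is None:
                assert b is None
            else:
                flip = {"a": "b", "b": "a"}
                assert b == a[:-1] + flip[a[-1]]
        assert np.allclose(r1, r2)


def _rec(p_drug, veh_mean, drug_mean):
    cm = np.vstack([np.full(6, veh_mean), np.full(6, drug_mean)])
    return AnovaRecord("g", 0.5, p_drug, 0.5, 1, 1, 1, cm, 1.0, 24, 3)


class TestDrugEffect:
    def test_significant_higher_drug_mean_is_up(self):
        assert classify_drug_effect(_rec(0.001, 1.0, 2.0)) == "up"

    def test_significant_lower_drug_mean_is_down(self):
        assert classify_drug_effect(_rec(0.001, 2.0, 1.0)) == "down"

    def test_nonsignificant_is_unchanged_regardless_of_means(self):
        assert classify_drug_effect(_rec(0.5, 1.0, 100.0)) == "unchanged"

    def test_exact_tie_resolves_to_unchanged(self):
        assert classify_drug_effect(_rec(0.001, 2.0, 2.0)) == "unchanged"


def _assignments(counts: dict[str, int]) -> list[TemplateAssignment]:
    out = []
    for pattern, n in counts.items():
        shape, cls = pattern.split("(")
        for i in range(n):
            out.append(TemplateAssignment(f"{pattern}_{i}", shape, 0.99, cls[:-1]))
    return out


class TestEnrichment:
    def test_uniform_one_per_pattern_flags_nothing(self, lib6):
        res = template_enrichment(_assignments({p: 1 for p in lib6.patterns}), lib6)
        assert not any(e.flagged for e in res)
        assert sum(e.observed for e in res) == 63

    def test_total_concentration_flags_the_pattern(self, lib6):
        res = template_enrichment(_assignments({"04a(up)": 8}), lib6)
        hit = next(e for e in res if e.pattern == "04a(up)")
        assert hit.flagged
        assert hit.p == pytest.approx(float(Fraction(1, 63) ** 8), rel=1e-9)

    def test_exact_tail_matches_rational_enumeration(self, lib6):
        res = template_enrichment(
            _assignments({"01a(up)": 10, "02a(down)": 53}), lib6)
        by_pat = {e.pattern: e for e in res}
        for pat, obs in [("01a(up)", 10), ("02a(down)", 53)]:
            exact = binom_upper_tail(obs, 63, Fraction(1, 63))
            assert by_pat[pat].p == pytest.approx(float(exact), rel=1e-9)
        assert by_pat["01a(up)"].expected == pytest.approx(1.0)

    def test_no_assigned_genes_rejected(self, lib6):
        with pytest.raises(ValueError, match="assigned"):
            template_enrichment([TemplateAssignment("g", None, 0.2)], lib6)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
def test_assignment_r_is_a_valid_correlation(profile):
    lib = build_template_library(T6)
    a = assign_template(np.array(profile), lib)
    assert -1.0 - 1e-12 <= a.r <= 1.0 + 1e-12
    if a.assigned and a.shape != "00":
        assert a.r > 0.85
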