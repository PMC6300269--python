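"""Per-airway mechanics: worked values, algebraic identities, properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bronchmech.airway_mechanics import (
    CLAMPED_ABOVE,
    NO_CLOSURE,
    RD_NONPOSITIVE,
    VALID_OK,
    compute_airway_mechanics,
    critical_expansion_fvc,
    critical_expansion_mlv,
    isovolume_lumen,
    isovolume_outer_area,
    relative_distensibility,
    subject_min_lumen,
)


class TestRelativeDistensibility:
    @pytest.mark.parametrize(
        "a_p, a_t, e_p, e_t, expected",
        [
            # 0.512^(2/3) = 0.64; RD = 0.18/0.36
            (0.82, 1.0, 0.512, 1.0, 0.5),
            # unchanged outer area
            (1.0, 1.0, 0.5, 1.0, 0.0),
            # airway tracks parenchyma: a_p = e_ratio^(2/3)
            (0.6 ** (2 / 3), 1.0, 0.6, 1.0, 1.0),
        ],
    )
    def test_worked_values(self, a_p, a_t, e_p, e_t, expected):
        assert relative_distensibility(a_p, a_t, e_p, e_t) == pytest.approx(
            expected, abs=1e-12
        )

    def test_raw_areas_normalised_internally(self):
        assert relative_distensibility(16.4, 20.0, 0.512, 1.0) == pytest.approx(0.5)

    def test_equal_expansions_undefined(self):
        with pytest.raises(ValueError):
            relative_distensibility(0.8, 1.0, 2.0, 2.0)

    @given(
        rd=st.floats(-1.0, 3.0),
        e_p=st.floats(0.2, 0.95),
    )
    def test_round_trip_on_known_line(self, rd, e_p):
        """Points generated on a line of slope RD return exactly that slope."""
        a_p = 1.0 - rd * (1.0 - e_p ** (2 / 3))
        assert relative_distensibility(a_p, 1.0, e_p, 1.0) == pytest.approx(
            rd, abs=1e-10
        )


class TestIsovolumeExtrapolation:
    def test_worked_value(self):
        # ratios^(2/3) of 0.64 and 0.49 -> 0.82 - 0.5*0.15 = 0.745
        got = isovolume_outer_area(0.82, 1.0, 0.5, 0.343, 0.512, 1.0)
        assert got == pytest.approx(0.745, abs=1e-12)

    def test_no_extrapolation_when_baseline_equals_post(self):
        assert isovolume_outer_area(0.82, 1.0, 0.5, 0.6, 0.6, 1.0) == pytest.approx(0.82)

    def test_rigid_airway(self):
        assert isovolume_outer_area(0.82, 1.0, 0.0, 0.3, 0.6, 1.0) == pytest.approx(0.82)

    @pytest.mark.parametrize(
        "a_star_o, wall_frac, expected",
        [(0.745, 0.5, 0.245), (0.745, 0.8, -0.055), (0.6, 0.6, 0.0)],
    )
    def test_lumen_subtraction(self, a_star_o, wall_frac, expected):
        assert isovolume_lumen(a_star_o, wall_frac, 1.0) == pytest.approx(
            expected, abs=1e-12
        )


class TestCriticalExpansion:
    def test_closes_only_at_zero_expansion(self):
        e, flag = critical_expansion_mlv(0.343, 0.245, 0.5)
        assert flag == VALID_OK
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_closed_at_baseline_airway(self):
        # x = 0.49 + 0.055/0.5 = 0.6 -> 0.6^(3/2)
        e, flag = critical_expansion_mlv(0.343, -0.055, 0.5)
        assert flag == VALID_OK
        assert e == pytest.approx(0.6 * np.sqrt(0.6), abs=1e-12)

    def test_zero_isovolume_lumen_closes_at_baseline(self):
        e, flag = critical_expansion_mlv(0.343, 0.0, 0.7)
        assert e == pytest.approx(0.343, abs=1e-12)

    def test_nonpositive_rd_flagged(self):
        assert critical_expansion_mlv(0.5, 0.1, 0.0) == (None, RD_NONPOSITIVE)
        assert critical_expansion_fvc(0.5, 1.0, -0.3) == (None, RD_NONPOSITIVE)

    def test_clamped_above_unity(self):
        e, flag = critical_expansion_mlv(0.9, -0.5, 0.4)
        assert (e, flag) == (1.0, CLAMPED_ABOVE)

    def test_fvc_variant_worked_values(self):
        e, flag = critical_expansion_fvc(0.5, 1.0, 1.0)
        assert flag == VALID_OK
        assert e == pytest.approx(0.5**1.5, abs=1e-12)
        # wall at TLC fills the whole airway: closes at TLC expansion
        e, flag = critical_expansion_fvc(1.0, 1.0, 0.8)
        assert (e, flag) == (1.0, VALID_OK)
        # too distensible relative to its thin wall: never closes
        assert critical_expansion_fvc(0.5, 1.0, 0.4) == (None, NO_CLOSURE)

    @given(
        rd=st.floats(0.05, 3.0),
        wall=st.floats(0.05, 1.0),
        rd2=st.floats(0.05, 3.0),
        wall2=st.floats(0.05, 1.0),
    )
    def test_fvc_variant_monotone_in_rd_and_wall(self, rd, wall, rd2, wall2):
        def val(w, r):
            e, _ = critical_expansion_fvc(w, 1.0, r)
            return -1.0 if e is None else e

        assert val(wall, max(rd, rd2)) >= val(wall, min(rd, rd2))
        assert val(max(wall, wall2), rd) >= val(min(wall, wall2), rd)

    @given(
        rd=st.floats(0.05, 3.0),
        wall=st.floats(0.1, 0.9),
        e_b=st.floats(0.1, 0.95),
    )
    def test_closure_identity(self, rd, wall, e_b):
        """a_i* < 0 iff the critical expansion exceeds baseline expansion."""
        a_star_i = 1.0 - rd * (1.0 - e_b ** (2 / 3)) - wall
        e_crit, flag = critical_expansion_mlv(e_b, a_star_i, rd)
        if flag == VALID_OK:
            assert (a_star_i < 0) == (e_crit > e_b + 1e-12) or np.isclose(
                e_crit, e_b, atol=1e-9
            )
        elif flag == CLAMPED_ABOVE:
            assert a_star_i < 0
        elif flag == NO_CLOSURE:
            assert a_star_i > 0


class TestSubjectMinimum:
    def test_minimum_and_mean_minus_2sd(self):
        mn, m2 = subject_min_lumen([0.3, -0.1, 0.2])
        assert mn == pytest.approx(-0.1)
        assert m2 == pytest.approx(0.13333333 - 2 * 0.20816660, abs=1e-6)

    def test_degenerate_all_equal(self):
        mn, m2 = subject_min_lumen([0.2, 0.2, 0.2])
        assert mn == pytest.approx(0.2)
        assert m2 == pytest.approx(mn)  # zero spread: no SD correction

    def test_requires_two_airways(self):
        with pytest.raises(ValueError):
            subject_min_lumen([0.1])


def test_full_derivation_bundles_flags():
    m = compute_airway_mechanics(
        a_o_p=16.4, a_o_t=20.0, a_w_p=10.0, a_w_t=11.0,
        e_pb_b=1.5, e_pb_p=2.2, e_pb_t=4.0,
    )
    assert m.rd == pytest.approx(
        relative_distensibility(16.4, 20.0, 2.2, 4.0)
    )
    assert m.a_star_i == pytest.approx(m.a_star_o - 0.5)
    assert m.closure_flag_baseline == (m.a_star_i < 0)
    assert m.validity_flag in (VALID_OK, RD_NONPOSITIVE, CLAMPED_ABOVE, NO_CLOSURE)
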