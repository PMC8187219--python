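"""Vergence engine: keratometry, propagation, forward model, ELP solve,
emmetropizing toric IOL."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toricratio import (
    DEFAULT_CONSTANTS,
    DegeneratePropagationError,
    ElpSolveError,
    EyeRecord,
    MeridionalPowers,
    OpticalConstants,
    emmetropizing_power,
    full_correction_tiol,
    keratometric_power,
    predicted_postop_se,
    propagate_vergence,
    re_reference_sphere,
    solve_elp,
    spherical_equivalent,
)

from _oracles import ray_transfer_vergence


class TestKeratometricPower:
    @pytest.mark.parametrize(
        "radius_mm, expected",
        [
            (332.0, 1.0),  # radius numerically equals 1000*(n_k - 1)
            (7.7, 43.116883116883116),
            (7.5, 44.26666666666667),
        ],
    )
    def test_examples(self, radius_mm, expected):
        assert keratometric_power(radius_mm) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -7.7])
    def test_rejects_nonpositive_radius(self, bad):
        with pytest.raises(ValueError):
            keratometric_power(bad)


class TestSphericalEquivalent:
    @pytest.mark.parametrize(
        "sphere, cyl, expected",
        [(0.0, 0.0, 0.0), (-1.00, 0.50, -0.75), (2.25, -1.50, 1.50)],
    )
    def test_examples(self, sphere, cyl, expected):
        assert spherical_equivalent(sphere, cyl) == pytest.approx(expected)


class TestPropagateVergence:
    def test_plane_wave_stays_plane(self):
        assert propagate_vergence(0.0, 0.123, 1.336) == 0.0

    def test_zero_distance_is_identity(self):
        assert propagate_vergence(44.0, 0.0, 1.336) == 44.0

    def test_worked_example(self):
        # hand evaluation of 44.13 / (1 - (0.004733/1.336) * 44.13)
        assert propagate_vergence(44.13, 0.004733, 1.336) == pytest.approx(
            52.307664817925485, abs=1e-9
        )

    def test_focus_inside_gap_raises(self):
        v = 50.0  # focus at 1.336/50 m; propagate exactly onto it
        with pytest.raises(DegeneratePropagationError):
            propagate_vergence(v, 1.336 / v, 1.336)

    @given(
        v=st.floats(-20, 45),
        d=st.floats(0.0, 0.02),
        n=st.floats(1.0, 1.6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_negative_distance_inverts(self, v, d, n):
        forward = propagate_vergence(v, d, n)
        assert propagate_vergence(forward, -d, n) == pytest.approx(v, abs=1e-9)

    def test_matches_ray_transfer_matrix_oracle(self, rng):
        """Random chains of gaps and thin lenses agree with an
        independently coded 2x2 ABCD-matrix oracle to 1e-9 D."""
        for _ in range(100):
            v = rng.uniform(-5.0, 5.0)
            elements = []
            for _ in range(rng.integers(1, 6)):
                if rng.random() < 0.5:
                    elements.append(("gap", rng.uniform(0.001, 0.02), rng.uniform(1.0, 1.6)))
                else:
                    elements.append(("lens", rng.uniform(-5.0, 30.0)))
            chained = v
            try:
                for element in elements:
                    if element[0] == "gap":
                        chained = propagate_vergence(chained, element[1], element[2])
                    else:
                        chained = chained + element[1]
                expected = ray_transfer_vergence(v, elements)
            except (DegeneratePropagationError, ZeroDivisionError):
                continue
            assert chained == pytest.approx(expected, abs=1e-9)


class TestForwardModel:
    def test_emmetropizing_power_zeroes_the_refraction(self):
        k_eq, al, elp = 43.5, 23.8, 4.6
        p = emmetropizing_power(k_eq, al, elp)
        assert predicted_postop_se(k_eq, al, p, elp) == pytest.approx(0.0, abs=1e-10)

    def test_stronger_iol_gives_myopic_shift(self):
        k_eq, al, elp = 43.5, 23.8, 4.6
        p = emmetropizing_power(k_eq, al, elp)
        assert predicted_postop_se(k_eq, al, p + 0.5, elp) < 0.0

    def test_worked_example(self):
        # frozen from a hand-chained step-by-step vergence oracle
        assert predicted_postop_se(43.12, 23.5, 21.0, 4.5) == pytest.approx(
            -0.6707577149649616, abs=1e-9
        )

    def test_elp_outside_eye_rejected(self):
        with pytest.raises(ValueError):
            predicted_postop_se(43.0, 23.5, 21.0, 24.0)


class TestEmmetropizingPower:
    @pytest.mark.parametrize(
        "k, expected",
        [(44.3, 18.875973362658023), (45.3, 17.465049052260987)],
    )
    def test_worked_examples(self, k, expected):
        # frozen from the hand-chained vergence oracle (AL 23.5, ELP 4.733)
        assert emmetropizing_power(k, 23.5, 4.733) == pytest.approx(expected, abs=1e-9)

    def test_collapses_to_single_surface_formula(self):
        # ELP -> 0, vertex -> 0, lane -> infinity: P -> n_media/AL - K
        c = OpticalConstants(vertex_distance=1e-12, measurement_distance=1e12)
        k, al = 44.3, 23.5
        p = emmetropizing_power(k, al, 1e-9, c)
        assert p == pytest.approx(c.n_media / (al / 1000.0) - k, abs=1e-4)


def _emmetropized_record(k_flat, k_steep, al, elp, constants=DEFAULT_CONSTANTS):
    """Record whose measured refraction is exactly consistent with `elp`."""
    scale = (constants.n_keratometer - 1.0) * 1000.0
    k_eq = 0.5 * (k_flat + k_steep)
    p_iol = emmetropizing_power(k_eq, al, elp, constants)
    se = predicted_postop_se(k_eq, al, p_iol, elp, constants)
    return EyeRecord(
        r_flat=scale / k_flat,
        r_steep=scale / k_steep,
        axial_length=al,
        acd_phakic=3.2,
        p_iol_implanted=p_iol,
        postop_sphere=se,
        postop_cylinder=0.0,
    )


class TestSolveElp:
    def test_round_trip_recovers_elp(self):
        rec = _emmetropized_record(43.0, 44.2, 23.5, 4.5)
        assert solve_elp(rec) == pytest.approx(4.5, abs=1e-6)

    def test_forward_se_strictly_monotone_in_elp(self):
        """Grid scan: the forward SE is strictly monotone over the
        physiologic ELP bracket, so the back-solved root is unique."""
        grid = np.linspace(1.0, 8.0, 141)
        se = [predicted_postop_se(43.12, 23.5, 21.0, e) for e in grid]
        diffs = np.diff(se)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_unreachable_refraction_flagged(self):
        rec = _emmetropized_record(43.0, 44.2, 23.5, 4.5)
        rec = EyeRecord(
            **{**rec.__dict__, "p_iol_implanted": 80.0}  # absurdly strong IOL
        )
        with pytest.raises(ElpSolveError):
            solve_elp(rec)

    def test_random_eyes_round_trip(self, rng):
        """Inversion of the forward model to 1e-6 mm across random eyes."""
        for _ in range(200):
            al = rng.uniform(21.0, 27.0)
            k_eq = rng.uniform(41.0, 46.0)
            astig = rng.uniform(0.3, 3.0)
            elp = rng.uniform(3.0, 6.5)
            rec = _emmetropized_record(k_eq - astig / 2, k_eq + astig / 2, al, elp)
            assert solve_elp(rec) == pytest.approx(elp, abs=1e-6)


class TestFullCorrection:
    def test_symmetric_cornea_flagged(self):
        res = full_correction_tiol(7.7, 7.7, 23.5, 4.7)
        assert not res.valid
        assert res.reason == "zero_astigmatism"
        assert math.isnan(res.translation_ratio)

    def test_worked_example(self):
        # K_flat 44.3, K_steep 45.3 at AL 23.5, ELP 4.733
        scale = 332.0
        res = full_correction_tiol(scale / 44.3, scale / 45.3, 23.5, 4.733)
        assert res.valid
        assert res.torus == pytest.approx(1.4109243103970357, abs=1e-8)
        assert res.translation_ratio == pytest.approx(res.torus / res.corneal_astigmatism)
        assert res.p_equivalent == pytest.approx(
            0.5 * (res.p_flat_meridian + res.p_steep_meridian)
        )

    def test_ratio_equals_power_sensitivity_in_small_astig_limit(self):
        """For vanishing astigmatism the ratio tends to |dP/dK| at fixed
        AL and ELP (finite-difference oracle)."""
        al, elp, k = 23.5, 4.733, 44.8
        h = 1e-5
        dpdk = (
            emmetropizing_power(k + h, al, elp) - emmetropizing_power(k - h, al, elp)
        ) / (2 * h)
        res = full_correction_tiol(332.0 / (k - 5e-4), 332.0 / (k + 5e-4), al, elp)
        assert res.translation_ratio == pytest.approx(abs(dpdk), rel=1e-5)

    def test_ratio_invariant_under_label_exchange(self):
        r1, r2 = 332.0 / 44.3, 332.0 / 45.3
        normal = full_correction_tiol(r1, r2, 23.5, 4.733)
        swapped = full_correction_tiol(r2, r1, 23.5, 4.733)
        assert swapped.torus == pytest.approx(-normal.torus, abs=1e-12)
        assert swapped.translation_ratio == pytest.approx(
            normal.translation_ratio, abs=1e-12
        )

    def test_ratio_strictly_increasing_in_elp(self):
        """The more posterior the lens, the larger the translation ratio."""
        ratios = [
            full_correction_tiol(332.0 / 44.3, 332.0 / 45.3, 23.5, e).translation_ratio
            for e in np.linspace(3.0, 6.0, 31)
        ]
        assert np.all(np.diff(ratios) > 0)

    def test_local_ratio_elp_slope_matches_cohort_regression_scale(self):
        """d(ratio)/d(ELP) by finite differences sits near 0.1 per mm at
        average biometry."""
        for k_eq in (43.0, 43.8, 44.5):
            h = 1e-4
            lo = full_correction_tiol(
                332.0 / (k_eq - 0.5), 332.0 / (k_eq + 0.5), 23.5, 4.733 - h
            ).translation_ratio
            hi = full_correction_tiol(
                332.0 / (k_eq - 0.5), 332.0 / (k_eq + 0.5), 23.5, 4.733 + h
            ).translation_ratio
            assert 0.09 <= (hi - lo) / (2 * h) <= 0.12


class TestReReferencing:
    def test_lane_invariant(self):
        # emmetrope at 6 m reads +1/12 D at a 4 m lane
        assert re_reference_sphere(1.0 / 12.0, 4.0, 6.0) == pytest.approx(0.0)

    def test_same_eye_measured_at_4m_and_6m_gives_same_elp(self):
        rec6 = _emmetropized_record(43.0, 44.2, 23.5, 4.5)
        rec4 = EyeRecord(
            **{
                **rec6.__dict__,
                "postop_sphere": rec6.postop_sphere + (1.0 / 4.0 - 1.0 / 6.0),
                "meas_distance_m": 4.0,
            }
        )
        assert solve_elp(rec4) == pytest.approx(solve_elp(rec6), abs=1e-6)


class TestRecordValidation:
    @pytest.mark.parametrize(
        "field, value, reason",
        [
            ("r_steep", 8.5, "steep_radius_exceeds_flat"),
            ("r_flat", 11.5, "corneal_radius_out_of_range"),
            ("axial_length", 42.0, "axial_length_out_of_range"),
        ],
    )
    def test_implausible_biometry_rejected(self, field, value, reason):
        rec = _emmetropized_record(43.0, 44.2, 23.5, 4.5)
        bad = EyeRecord(**{**rec.__dict__, field: value})
        assert bad.validation_error() == reason

    def test_plausible_record_passes(self):
        assert _emmetropized_record(43.0, 44.2, 23.5, 4.5).validation_error() is None


class TestMeridionalPowers:
    def test_equivalent_is_exact_mean_and_astig_nonnegative(self):
        p = MeridionalPowers.from_radii(7.8, 7.5)
        assert p.k_equivalent == (p.k_flat + p.k_steep) / 2
        assert p.astigmatism >= 0
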