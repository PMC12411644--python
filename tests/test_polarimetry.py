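import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from polcontrast.polarimetry import (
    DEFAULT_SCHEME,
    DOPImage,
    MuellerImage,
    PolarimetricMeasurementSet,
    correct_beam_splitter,
    design_matrix,
    forward_intensities,
    mueller_from_measurements,
    signed_docp,
    signed_dolp,
    stokes_from_intensities,
    total_dop_magnitude,
)


def img(value, shape=(3, 3)):
    return np.full(shape, float(value))


def six(h, v, p, m, r, l):
    return {"H": img(h), "V": img(v), "P45": img(p), "M45": img(m), "R": img(r), "L": img(l)}


class TestStokes:
    def test_pure_h(self):
        s = stokes_from_intensities(six(1, 0, 0.5, 0.5, 0.5, 0.5))
        assert np.allclose([s.s0[0, 0], s.s1[0, 0], s.s2[0, 0], s.s3[0, 0]], [1, 1, 0, 0])
        assert s.s0_consistent

    def test_unpolarized(self):
        s = stokes_from_intensities(six(*[0.5] * 6))
        assert np.allclose([s.s0[0, 0], s.s1[0, 0], s.s2[0, 0], s.s3[0, 0]], [1, 0, 0, 0])

    def test_circular(self):
        # direct evaluation of the sum/difference definitions
        s = stokes_from_intensities(six(0.5, 0.5, 0.5, 0.5, 0.9, 0.1))
        assert np.allclose([s.s0[0, 0], s.s1[0, 0], s.s2[0, 0], s.s3[0, 0]], [1, 0, 0, 0.8])

    def test_missing_state(self):
        frames = six(*[0.5] * 6)
        del frames["L"]
        with pytest.raises(ValueError, match="missing"):
            stokes_from_intensities(frames)

    def test_negative_intensity_rejected(self):
        frames = six(*[0.5] * 6)
        frames["H"] = img(-1)
        with pytest.raises(ValueError, match="negative"):
            stokes_from_intensities(frames)

    def test_shape_mismatch(self):
        frames = six(*[0.5] * 6)
        frames["H"] = img(0.5, shape=(2, 2))
        with pytest.raises(ValueError, match="shape"):
            stokes_from_intensities(frames)

    def test_s0_inconsistency_flagged(self):
        with pytest.warns(UserWarning, match="S0"):
            s = stokes_from_intensities(six(1, 0, 0.9, 0.9, 0.5, 0.5))
        assert not s.s0_consistent

    def test_realizability_flagging(self):
        s = stokes_from_intensities(six(1, 0, 1, 0, 1, 0))
        # S = (1, 1, 1, 1): unphysical, flagged but not altered
        assert s.realizability_violations().all()
        clean = stokes_from_intensities(six(1, 0, 0.5, 0.5, 0.5, 0.5))
        assert not clean.realizability_violations().any()


class TestSignedDOCP:
    def test_full_preservation(self):
        d = signed_docp(img(1), img(0), "R")
        assert d.values[0, 0] == 1.0

    def test_full_flip(self):
        d = signed_docp(img(0), img(1), "R")
        assert d.values[0, 0] == -1.0

    def test_incident_left(self):
        # hand evaluation: sign = -1, ratio = +0.5
        d = signed_docp(img(0.75), img(0.25), "L")
        assert d.values[0, 0] == pytest.approx(-0.5, abs=1e-15)

    def test_zero_denominator_goes_invalid(self):
        i_r = np.array([[1.0, 0.0], [0.5, 0.5]])
        i_l = np.array([[0.0, 0.0], [0.5, 0.5]])
        d = signed_docp(i_r, i_l, "R")
        assert not d.valid_mask[0, 1]
        assert d.valid_mask[0, 0]
        assert np.isfinite(d.values).all()

    def test_non_circular_incident_rejected(self):
        with pytest.raises(ValueError, match="helicity"):
            signed_docp(img(1), img(0), "H")

    @given(
        hnp.arrays(float, (4, 4), elements=st.floats(0, 1e6, allow_nan=False)),
        hnp.arrays(float, (4, 4), elements=st.floats(0, 1e6, allow_nan=False)),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_antisymmetric(self, i_r, i_l):
        d = signed_docp(i_r, i_l, "R")
        assert np.all(np.abs(d.values[d.valid_mask]) <= 1.0 + 1e-12)
        swapped = signed_docp(i_l, i_r, "R")
        assert np.allclose(d.values[d.valid_mask], -swapped.values[d.valid_mask])
        flipped = signed_docp(i_r, i_l, "L")
        assert np.array_equal(d.values, -flipped.values)

    def test_magnitude_matches_unsigned_ratio(self, rng):
        i_r = rng.uniform(0.05, 1.0, (64, 64))
        i_l = rng.uniform(0.05, 1.0, (64, 64))
        d = signed_docp(i_r, i_l, "L")
        unsigned = np.abs(i_r - i_l) / (i_r + i_l)  # |S3|/S0 of the pair
        assert np.allclose(np.abs(d.values), unsigned, atol=1e-14)


class TestSignedDOLP:
    def test_pure_colinear(self):
        d = signed_dolp(img(1), img(0), img(0.5), img(0.5), "H", "P45")
        assert d.values[0, 0] == -1.0
        assert not d.flagged.any()

    def test_pure_crosslinear(self):
        d = signed_dolp(img(1), img(0), img(0.5), img(0.5), "V", "P45")
        assert d.values[0, 0] == 1.0

    def test_hand_evaluated_two_terms(self):
        # -sign(S1_in)*(0.7-0.3)/1 + sign(S2_in)*(0.6-0.4)/1 = -0.4 + 0.2
        d = signed_dolp(img(0.7), img(0.3), img(0.6), img(0.4), "H", "P45")
        assert d.values[0, 0] == pytest.approx(-0.2, abs=1e-15)

    def test_mirror_exceeds_range_and_is_flagged(self):
        # ideal mirror diag(1,1,-1,-1): co-linear H/V return, flipped 45 axis
        d = signed_dolp(img(1), img(0), img(0), img(1), "H", "P45")
        assert d.values[0, 0] == pytest.approx(-2.0)
        assert d.flagged[0, 0]

    def test_impure_incident_rejected(self):
        with pytest.raises(ValueError):
            signed_dolp(img(1), img(0), img(0.5), img(0.5), "R", "P45")
        with pytest.raises(ValueError):
            signed_dolp(img(1), img(0), img(0.5), img(0.5), "H", "R")

    def test_zero_denominator_invalid(self):
        d = signed_dolp(img(0), img(0), img(0.5), img(0.5), "H", "P45")
        assert not d.valid_mask.any()


class TestMueller:
    @pytest.mark.parametrize(
        "diag",
        [
            (1.0, 1.0, 1.0, 1.0),
            (1.0, 0.0, 0.0, 0.0),
            (1.0, 1.0, -1.0, -1.0),
            (1.0, 0.6, 0.6, -0.35),
        ],
    )
    def test_round_trip_diagonal(self, diag):
        m = np.diag(diag)
        intensities = forward_intensities(m)
        assert np.all(intensities >= -1e-12)
        frames = {k: img(intensities[i], (4, 4)) for i, k in enumerate(DEFAULT_SCHEME)}
        rec = mueller_from_measurements(PolarimetricMeasurementSet(frames=frames))
        assert np.abs(rec.m[0, 0] - m).max() < 1e-10

    def test_round_trip_random_physicalish(self, rng):
        # any matrix the forward model accepts must invert exactly
        m = np.eye(4) + 0.1 * rng.normal(size=(4, 4))
        intensities = forward_intensities(m)
        frames = {k: img(abs(intensities[i])) for i, k in enumerate(DEFAULT_SCHEME)}
        rec = mueller_from_measurements(PolarimetricMeasurementSet(frames=frames))
        expected = np.linalg.solve(design_matrix(), np.abs(intensities))
        assert np.allclose(rec.m[0, 0].ravel(), expected, atol=1e-12)

    def test_singular_scheme_rejected(self):
        scheme = tuple((g, a) for g in ("H", "V", "P45", "M45") for a in ("H", "V", "P45", "R"))
        m = np.eye(4)
        intensities = forward_intensities(np.eye(4), DEFAULT_SCHEME)
        frames = {k: img(intensities[i]) for i, k in enumerate(DEFAULT_SCHEME)}
        mset = PolarimetricMeasurementSet(frames=frames)
        with pytest.raises(ValueError, match="singular"):
            mueller_from_measurements(mset, scheme=scheme)

    def test_normalized_m11_is_one(self):
        intensities = forward_intensities(np.diag([2.0, 1.0, 1.0, -0.5]))
        frames = {k: img(intensities[i]) for i, k in enumerate(DEFAULT_SCHEME)}
        rec = mueller_from_measurements(PolarimetricMeasurementSet(frames=frames), normalize=True)
        assert np.allclose(rec.element(1, 1)[rec.valid_mask], 1.0)
        assert np.all(np.abs(rec.element(4, 4)[rec.valid_mask]) <= 1.0 + 1e-12)

    def test_noise_rmse_monotone(self, rng):
        m = np.diag([1.0, 0.6, 0.6, -0.35])
        intensities = forward_intensities(m)
        rmses = []
        for sigma in (1e-2, 1e-3, 1e-4):
            frames = {
                k: np.abs(img(intensities[i], (32, 32)) + rng.normal(0, sigma, (32, 32)))
                for i, k in enumerate(DEFAULT_SCHEME)
            }
            rec = mueller_from_measurements(PolarimetricMeasurementSet(frames=frames))
            rmses.append(float(np.sqrt(np.mean((rec.m - m) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestBeamSplitter:
    def _image(self, m):
        return MuellerImage(m=np.broadcast_to(m, (3, 3, 4, 4)).copy())

    def test_identity_is_bit_identical(self):
        raw = self._image(np.diag([1.0, 0.5, 0.5, -0.2]))
        out = correct_beam_splitter(raw, np.eye(4), np.eye(4))
        assert np.array_equal(out.m, raw.m)

    def test_construct_then_invert(self, rng):
        m_true = np.diag([1.0, 0.7, 0.7, -0.3])
        m_ill = np.eye(4) + 0.05 * rng.normal(size=(4, 4))
        m_det = np.eye(4) + 0.05 * rng.normal(size=(4, 4))
        raw = self._image(m_det @ m_true @ m_ill)
        out = correct_beam_splitter(raw, m_ill, m_det)
        assert np.abs(out.m - m_true).max() < 1e-9

    def test_singular_correction_rejected(self):
        raw = self._image(np.eye(4))
        singular = np.zeros((4, 4))
        with pytest.raises(ValueError, match="condition"):
            correct_beam_splitter(raw, singular, np.eye(4))


class TestTotalDOP:
    def _dop(self, value, metric):
        v = img(value)
        return DOPImage(values=v, metric=metric, valid_mask=np.ones_like(v, bool))

    def test_average_of_magnitudes(self):
        out = total_dop_magnitude(self._dop(0.6, "linear"), self._dop(-0.4, "circular"))
        assert np.allclose(out.values, 0.5)
        assert out.metric == "total_magnitude"

    def test_zero(self):
        out = total_dop_magnitude(self._dop(0.0, "linear"), self._dop(0.0, "circular"))
        assert np.allclose(out.values, 0.0)

    def test_endpoint(self):
        out = total_dop_magnitude(self._dop(-1.0, "linear"), self._dop(1.0, "circular"))
        assert np.allclose(out.values, 1.0)

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            total_dop_magnitude(self._dop(0.5, "circular"), self._dop(0.5, "circular"))

    def test_valid_mask_intersection(self):
        a = self._dop(0.5, "linear")
        b = self._dop(0.5, "circular")
        a.valid_mask[0, 0] = False
        b.valid_mask[1, 1] = False
        out = total_dop_magnitude(a, b)
        assert not out.valid_mask[0, 0] and not out.valid_mask[1, 1]
        assert out.valid_mask.sum() == a.valid_mask.size - 2


def test_mueller_and_dop_pathways_agree_on_mirror():
    """An ideal mirror must read as full helicity flip via both routes."""
    mirror = np.diag([1.0, 1.0, -1.0, -1.0])
    intensities = forward_intensities(mirror)
    frames = {k: img(intensities[i]) for i, k in enumerate(DEFAULT_SCHEME)}
    rec = mueller_from_measurements(PolarimetricMeasurementSet(frames=frames), normalize=True)
    assert np.allclose(rec.element(4, 4), -1.0)

    # the circular pair measured directly on the mirror
    s_in = np.array([1.0, 0.0, 0.0, 1.0])  # incident R
    s_out = mirror @ s_in
    i_r = 0.5 * (s_out[0] + s_out[3])
    i_l = 0.5 * (s_out[0] - s_out[3])
    d = signed_docp(img(i_r), img(i_l), "R")
    assert np.allclose(d.values, -1.0)
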