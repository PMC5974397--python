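"""Point-dipole exciton Hamiltonian, rotational strengths and CD couplets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoscope.errors import ExcitonError
from oligoscope.excitons import (
    build_exciton_system,
    classify_couplet,
    predict_cd,
    solve_exciton,
    synthesize_cd_spectrum,
)
from oligoscope.structures import ChromophoreSet
from oligoscope.synthetic import SyntheticOligomerSpec, make_ring_oligomer

from conftest import ring_chromophores


def _pair(p1, p2, d1, d2, lam=500.0, strength=1.0):
    d1 = np.asarray(d1, float); d1 = d1 / np.linalg.norm(d1)
    d2 = np.asarray(d2, float); d2 = d2 / np.linalg.norm(d2)
    return ChromophoreSet(
        positions=np.array([p1, p2], dtype=float),
        directions=np.array([d1, d2]),
        site_wavelengths=np.full(2, lam),
        dipole_strengths=np.full(2, strength),
    )


def _random_chromophores(rng, n):
    """Random geometry with the pairwise-distance guard satisfied."""
    while True:
        pos = rng.uniform(0, 5, (n, 3))
        diff = pos[:, None] - pos[None, :]
        d = np.linalg.norm(diff, axis=-1) + np.eye(n)
        if d.min() > 0.4:
            break
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return ChromophoreSet(pos, dirs, np.full(n, 524.0), np.full(n, 0.03))


class TestCoupling:
    def test_side_by_side_parallel_kappa_plus_one(self):
        ch = _pair([0, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1])
        sys_ = build_exciton_system(ch)
        assert sys_.coupling_matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_collinear_head_to_tail_kappa_minus_two(self):
        ch = _pair([0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0])
        sys_ = build_exciton_system(ch)
        assert sys_.coupling_matrix[0, 1] == pytest.approx(-2.0, abs=1e-12)

    def test_diagonal_is_reduced_site_energy(self):
        ch = _pair([0, 0, 0], [1, 0, 0], [0, 0, 1], [0, 0, 1], lam=524.0)
        sys_ = build_exciton_system(ch)
        assert sys_.coupling_matrix[0, 0] == pytest.approx(1 / 524.0)

    def test_c5_ring_coupling_is_circulant(self):
        ch = ring_chromophores(5, 2.15, delta_deg=-30, tilt_deg=20)
        V = build_exciton_system(ch).coupling_matrix
        for k in range(1, 5):
            vals = [V[i, (i + k) % 5] for i in range(5)]
            assert np.ptp(vals) < 1e-12

    def test_coincident_chromophores_rejected(self):
        ch = _pair([0, 0, 0], [0, 0, 1e-12], [0, 0, 1], [0, 1, 0])
        with pytest.raises(ExcitonError):
            build_exciton_system(ch)

    def test_close_pair_records_warning(self):
        ch = _pair([0, 0, 0], [0.2, 0, 0], [0, 0, 1], [0, 0, 1])
        sys_ = build_exciton_system(ch)
        assert sys_.warnings


class TestSolve:
    def test_parallel_dipoles_have_zero_rotational_strength(self):
        pos = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0.5]])
        dirs = np.tile([0.0, 0.0, 1.0], (3, 1))
        ch = ChromophoreSet(pos, dirs, np.full(3, 500.0), np.full(3, 1.0))
        sys_ = solve_exciton(build_exciton_system(ch))
        np.testing.assert_allclose(sys_.rotational_strengths, 0.0, atol=1e-15)

    def test_dimer_antisymmetry(self):
        ch = _pair([0, 0, 0], [1.2, 0, 0], [0, 1, 1], [1, 0, 1])
        sys_ = solve_exciton(build_exciton_system(ch))
        r = sys_.rotational_strengths
        assert r[0] == pytest.approx(-r[1], abs=1e-15)

    @given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sum_rule(self, seed, n):
        rng = np.random.default_rng(seed)
        sys_ = solve_exciton(build_exciton_system(_random_chromophores(rng, n)))
        assert abs(sys_.rotational_strengths.sum()) <= 1e-12

    def test_mirror_reflection_negates_strengths(self):
        rng = np.random.default_rng(42)
        ch = _random_chromophores(rng, 5)
        a = solve_exciton(build_exciton_system(ch))
        b = solve_exciton(build_exciton_system(ch.mirrored([1.0, 0.0, 0.0])))
        np.testing.assert_allclose(
            np.sort(a.rotational_strengths),
            np.sort(-b.rotational_strengths),
            atol=1e-12,
        )

    def test_orthonormal_coefficients(self):
        rng = np.random.default_rng(0)
        sys_ = solve_exciton(build_exciton_system(_random_chromophores(rng, 6)))
        c = sys_.state_coefficients
        np.testing.assert_allclose(c.T @ c, np.eye(6), atol=1e-9)


class TestSpectrum:
    def test_intrinsic_only_single_peak_at_lambda_max(self):
        # chromophores far apart: couplings negligible
        ch = _pair([0, 0, 0], [500.0, 0, 0], [0, 1, 1], [1, 0, 1],
                   lam=524.0, strength=0.03)
        sys_, spec, cls = predict_cd(ch, intrinsic_amplitude=1.0)
        assert spec.apparent_peak == pytest.approx(524.0, abs=0.5)
        assert cls.label == "single_peak_at_max"
        assert cls.red_lobe_sign == "+"

    def test_pure_couplet_integrates_to_zero(self):
        ch = ring_chromophores(5, 2.15, delta_deg=-30, tilt_deg=20)
        sys_, spec, _ = predict_cd(ch, grid=(300.0, 900.0, 0.25))
        integral = np.trapezoid(spec.delta_eps, spec.wavelengths)
        scale = np.trapezoid(np.abs(spec.delta_eps), spec.wavelengths)
        assert abs(integral) <= 1e-6 * max(scale, 1e-30)

    def test_grid_excluding_all_bands_rejected(self):
        ch = ring_chromophores(3, 1.6, delta_deg=-90, tilt_deg=20)
        sys_ = solve_exciton(build_exciton_system(ch))
        with pytest.raises(ExcitonError):
            synthesize_cd_spectrum(sys_, grid=(300.0, 350.0, 0.5))

    def test_all_zero_spectrum_is_null(self):
        # parallel dipoles: no rotational strength, no intrinsic band
        pos = np.array([[0, 0, 0], [1.5, 0, 0]])
        dirs = np.tile([0.0, 0.0, 1.0], (2, 1))
        ch = ChromophoreSet(pos, dirs, np.full(2, 500.0), np.full(2, 0.03))
        sys_, spec, cls = predict_cd(ch)
        assert cls.label == "null"
        assert (cls.blue_lobe_sign, cls.red_lobe_sign) == ("0", "0")


class TestCoupletPhenomenology:
    @pytest.mark.parametrize("n_fold,ring_radius", [(3, 1.6), (5, 2.15), (6, 2.3)])
    @pytest.mark.parametrize("tilt", [5.0, 15.0, 25.0, 35.0, 45.0])
    def test_azimuth_mode_flip_inverts_couplet(self, n_fold, ring_radius, tilt):
        """The packing-mode claim: head-to-tail and tail-to-tail retinal
        arrangements on the same ring give opposite couplet signs."""
        labels = {}
        for mode in ("head_to_tail", "tail_to_tail"):
            spec = SyntheticOligomerSpec(
                n=n_fold, ring_radius=ring_radius, dipole_polar=tilt,
                dipole_azimuth_mode=mode, seed=1,
            )
            _, chrom, _ = make_ring_oligomer(spec)
            _, _, cls = predict_cd(chrom)
            labels[mode] = cls.label
        assert labels["head_to_tail"] == "normal_couplet"
        assert labels["tail_to_tail"] == "inverted_couplet"

    def test_couplet_amplitude_decays_with_ring_radius(self):
        """The observable couplet vanishes as 1/d^3 coupling collapses the
        splitting; opposite-signed bands then cancel."""
        amps = []
        for rr in (2.0, 4.0, 8.0, 16.0):
            ch = ring_chromophores(5, rr, delta_deg=-30, tilt_deg=20)
            sys_ = solve_exciton(build_exciton_system(ch))
            cd = synthesize_cd_spectrum(sys_)
            amps.append(float(np.abs(cd.delta_eps).max()))
        assert all(a > b for a, b in zip(amps, amps[1:]))
        assert amps[-1] < 1e-1 * amps[0]

    def test_weak_inverted_couplet_redshifts_apparent_peak(self):
        """A dominant positive intrinsic band plus a weak inverted couplet
        gives one all-positive peak red of lambda_max that shifts further
        red as the couplet grows."""
        peaks = []
        for strength in (0.016, 0.020, 0.025):
            spec = SyntheticOligomerSpec(
                n=5, ring_radius=2.15, dipole_azimuth_mode="tail_to_tail",
                dipole_strength=strength, seed=1,
            )
            _, chrom, _ = make_ring_oligomer(spec)
            sys_ = solve_exciton(build_exciton_system(chrom))
            cd = synthesize_cd_spectrum(
                sys_, intrinsic_amplitude=2e-5, grid=(380.0, 700.0, 0.1)
            )
            assert cd.apparent_peak > cd.lambda_max_abs
            peaks.append(cd.apparent_peak)
        assert peaks == sorted(set(peaks))  # strictly increasing redshift
        # the weakest case: blue-side dip stays above zero (no crossing)
        assert peaks[0] > 524.0

    def test_mirror_swaps_normal_and_inverted(self):
        spec = SyntheticOligomerSpec(n=3, ring_radius=1.6, seed=2,
                                     dipole_azimuth_mode="head_to_tail")
        _, chrom, _ = make_ring_oligomer(spec)
        _, _, straight = predict_cd(chrom)
        _, _, mirrored = predict_cd(chrom.mirrored([0.0, 1.0, 0.0]))
        assert straight.label == "normal_couplet"
        assert mirrored.label == "inverted_couplet"
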