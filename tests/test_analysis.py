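import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionpair.analysis import (
    Configuration,
    MixingState,
    PairingSummary,
    RDFResult,
    classify_pairs,
    compute_rdf,
    coordination_number,
    delta_mu_ind,
    exchange_acceptance,
    find_cip_sip_minimum,
    find_first_peak,
    first_minimum_after_peak,
    induced_dipole_from_drude,
    mixed_energy,
    polarizability_from_volume,
    read_xyz,
    shell_membership,
    upol_field,
    upol_point_charge,
    write_xyz,
)


def make_rdf(g, bin_width=0.05, rho_B=0.01):
    edges = np.arange(0, (len(g) + 1) * bin_width, bin_width)[: len(g) + 1]
    return RDFResult(bin_edges=edges, g=np.asarray(g, float),
                     counts=np.zeros(len(g)), rho_B=rho_B)


def gaussian_rdf(centers, heights, widths, r_max=10.0, bin_width=0.05):
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    x = 0.5 * (edges[:-1] + edges[1:])
    g = np.ones_like(x)
    for c, h, w in zip(centers, heights, widths):
        g += h * np.exp(-((x - c) ** 2) / w)
    return RDFResult(bin_edges=edges, g=g, counts=np.zeros_like(x),
                     rho_B=0.01)


class TestComputeRDF:
    def test_uncorrelated_particles_give_unity(self, rng):
        L = 30.0
        frames = [
            Configuration(rng.random((400, 3)) * L,
                          np.array(["A"] * 400, dtype=object), L)
            for _ in range(20)
        ]
        rdf = compute_rdf(frames, "A", "A", bin_width=0.5)
        beyond = rdf.bin_centers > 1.0
        # 3 sigma of Poisson counting noise per bin
        sigma = 1.0 / np.sqrt(np.maximum(rdf.counts[beyond], 1.0))
        assert np.all(np.abs(rdf.g[beyond] - 1.0) <= 3.2 * sigma + 0.02)

    def test_fixed_pair_lands_in_one_bin(self):
        conf = Configuration(np.array([[0.0, 0, 0], [5.0, 0, 0]]),
                             np.array(["A", "B"], dtype=object), 20.0)
        rdf = compute_rdf(conf, "A", "B", bin_width=0.1)
        k = np.flatnonzero(rdf.counts)
        assert len(k) == 1
        assert rdf.bin_edges[k[0]] <= 5.0 < rdf.bin_edges[k[0] + 1]

    def test_r_max_beyond_half_box_rejected(self):
        conf = Configuration(np.zeros((1, 3)),
                             np.array(["A"], dtype=object), 10.0)
        with pytest.raises(ValueError):
            compute_rdf(conf, "A", "A", r_max=6.0)


class TestPeakFinding:
    def test_single_gaussian_peak_position(self):
        rdf = gaussian_rdf([2.1], [2.0], [0.02])
        peak = find_first_peak(rdf)
        assert peak == pytest.approx(2.1, abs=0.025)

    def test_flat_curve_has_no_peak(self):
        rdf = make_rdf(np.ones(100))
        assert find_first_peak(rdf) is None

    def test_two_peaks_returns_first(self):
        rdf = gaussian_rdf([2.1, 4.0], [2.0, 3.0], [0.02, 0.05])
        assert find_first_peak(rdf) == pytest.approx(2.1, abs=0.025)

    def test_requires_enough_populated_bins(self):
        rdf = make_rdf([0, 0, 1, 0])
        with pytest.raises(ValueError):
            find_first_peak(rdf)


class TestCipSipMinimum:
    def test_bimodal_minimum_position(self):
        rdf = gaussian_rdf([2.5, 4.5], [3.0, 2.0], [0.1, 0.1])
        assert find_cip_sip_minimum(rdf) == pytest.approx(3.5, abs=0.06)

    def test_single_peak_returns_none(self):
        rdf = gaussian_rdf([2.5], [3.0], [0.1])
        assert find_cip_sip_minimum(rdf) is None

    def test_robust_to_multiplicative_noise(self):
        clean = gaussian_rdf([2.5, 4.5], [3.0, 2.0], [0.1, 0.1])
        rng = np.random.Generator(np.random.PCG64(3))
        noisy = RDFResult(
            bin_edges=clean.bin_edges,
            g=clean.g * (1 + 0.05 * rng.normal(size=len(clean.g))),
            counts=clean.counts, rho_B=clean.rho_B)
        r0 = find_cip_sip_minimum(clean)
        r1 = find_cip_sip_minimum(noisy)
        assert abs(r1 - r0) <= 0.05  # within one bin

    def test_fallback_minimum_after_single_peak(self):
        rdf = gaussian_rdf([2.5], [3.0], [0.1])
        r = first_minimum_after_peak(rdf)
        assert r is not None and r > 2.5


class TestCoordinationNumber:
    def test_zero_g_gives_zero(self):
        assert coordination_number(make_rdf(np.zeros(100)), 3.0) == 0.0

    def test_ideal_gas_closed_form(self):
        # g = 1, rho_B = 0.01, r_cut = 3: N = (4/3) pi 27 * 0.01
        rdf = make_rdf(np.ones(200), bin_width=0.05, rho_B=0.01)
        n = coordination_number(rdf, 3.0)
        assert n == pytest.approx(4.0 / 3.0 * math.pi * 27 * 0.01, rel=2e-3)

    def test_monotone_in_cutoff(self):
        rdf = gaussian_rdf([2.5, 4.5], [3.0, 2.0], [0.1, 0.1])
        cuts = np.linspace(0.5, 5.0, 20)
        ns = [coordination_number(rdf, c) for c in cuts]
        assert np.all(np.diff(ns) >= 0)

    def test_cut_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            coordination_number(make_rdf(np.ones(10)), 100.0)


class TestClassifyPairs:
    def _planted(self):
        # 2 cations; anion0 at 3.0 from cation0 (CIP), anion1 at 5.5 from
        # cation1 (SIP), anion2 far from everything
        pos = np.array([
            [10.0, 10, 10], [30.0, 30, 30],
            [13.0, 10, 10], [30.0, 35.5, 30], [50.0, 50, 50],
        ])
        spc = np.array(["M", "M", "X", "X", "X"], dtype=object)
        return Configuration(pos, spc, 60.0)

    def test_planted_counts(self):
        labels, n_cip, n_sip = classify_pairs(self._planted(), 4.0, 6.5)
        assert (n_cip, n_sip) == (1, 1)
        total = labels.size
        n_unpaired = int((labels == "unpaired").sum())
        assert n_cip + n_sip + n_unpaired == total

    def test_everything_beyond_window(self):
        conf = Configuration(
            np.array([[0.0, 0, 0], [25.0, 25, 25]]),
            np.array(["M", "X"], dtype=object), 60.0)
        _, n_cip, n_sip = classify_pairs(conf, 4.0, 6.5)
        assert (n_cip, n_sip) == (0, 0)

    def test_anion_shared_by_two_cations_counts_twice(self):
        conf = Configuration(
            np.array([[10.0, 10, 10], [16.0, 10, 10], [13.0, 10, 10]]),
            np.array(["M", "M", "X"], dtype=object), 60.0)
        _, n_cip, _ = classify_pairs(conf, 4.0, 6.5)
        assert n_cip == 2

    def test_window_inversion_rejected(self):
        with pytest.raises(ValueError):
            classify_pairs(self._planted(), 6.5, 4.0)


class TestShellMembership:
    def test_cutoff_boundary(self):
        for dist, expected in [(3.1, True), (3.3, False)]:
            conf = Configuration(
                np.array([[10.0, 10, 10], [10.0 + dist, 10, 10]]),
                np.array(["M", "W"], dtype=object), 40.0)
            mask = shell_membership(conf, "M", "W")
            assert bool(mask[0]) is expected

    def test_no_centers_gives_empty_mask(self):
        conf = Configuration(np.array([[1.0, 1, 1]]),
                             np.array(["W"], dtype=object), 40.0)
        mask = shell_membership(conf, "M", "W")
        assert mask.shape == (1,) and not mask.any()

    def test_membership_counted_once_per_water(self):
        # water within 3.2 A of two cations appears once in the mask
        conf = Configuration(
            np.array([[10.0, 10, 10], [14.0, 10, 10], [12.0, 10, 10]]),
            np.array(["M", "M", "W"], dtype=object), 40.0)
        assert shell_membership(conf, "M", "W").sum() == 1


class TestDeltaMuInd:
    def _system(self, shell_mag, bulk_mag):
        pos = [[10.0, 10, 10]]
        spc = ["M"]
        mus = [[0.0, 0, 0]]
        for k in range(6):  # first shell at 2.5 A
            ang = 2 * math.pi * k / 6
            pos.append([10 + 2.5 * math.cos(ang), 10 + 2.5 * math.sin(ang),
                        10.0])
            spc.append("W")
            mus.append([shell_mag, 0, 0])
        for k in range(12):  # bulk at 12 A
            ang = 2 * math.pi * k / 12
            pos.append([10 + 12 * math.cos(ang), 10 + 12 * math.sin(ang),
                        10.0])
            spc.append("W")
            mus.append([bulk_mag, 0, 0])
        return Configuration(np.array(pos), np.array(spc, dtype=object),
                             40.0, induced_dipoles=np.array(mus))

    def test_planted_difference(self):
        conf = self._system(1.65, 0.65)
        assert delta_mu_ind(conf) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_dipoles_give_zero(self):
        conf = self._system(0.65, 0.65)
        assert delta_mu_ind(conf) == pytest.approx(0.0, abs=1e-12)

    def test_missing_dipoles_refused(self):
        conf = Configuration(np.array([[1.0, 1, 1], [4.0, 1, 1]]),
                             np.array(["M", "W"], dtype=object), 40.0)
        with pytest.raises(ValueError):
            delta_mu_ind(conf)


class TestPolarization:
    def test_drude_dipole_conversion(self):
        mu = induced_dipole_from_drude(np.array([0.1, 0.0, 0.0]), -1.0)
        assert np.linalg.norm(mu) == pytest.approx(0.48032, abs=2e-4)
        # linearity
        mu2 = induced_dipole_from_drude(np.array([0.2, 0.0, 0.0]), -1.0)
        assert np.linalg.norm(mu2) == pytest.approx(2 * np.linalg.norm(mu),
                                                    rel=1e-12)
        assert np.allclose(induced_dipole_from_drude(np.zeros(3), -1.0), 0.0)

    def test_upol_field_laws(self):
        alpha = polarizability_from_volume(5.0)
        assert upol_field(alpha, 0.0) == 0.0
        u1 = upol_field(alpha, 0.2)
        u2 = upol_field(alpha, 0.4)
        assert u1 < 0 and u2 == pytest.approx(4 * u1, rel=1e-12)
        with pytest.raises(ValueError):
            upol_field(-1.0, 0.1)

    def test_upol_point_charge_laws(self):
        assert upol_point_charge(5.0, 0.0, 3.0) == 0.0
        u = upol_point_charge(5.0, 2.0, 3.0)
        assert u < 0
        # halving r multiplies |U| by 16; doubling q multiplies by 4
        assert upol_point_charge(5.0, 2.0, 1.5) == pytest.approx(16 * u,
                                                                 rel=1e-12)
        assert upol_point_charge(5.0, 1.0, 3.0) == pytest.approx(u / 4,
                                                                 rel=1e-12)
        with pytest.raises(ValueError):
            upol_point_charge(5.0, 2.0, 0.0)

    def test_field_route_is_half_of_point_charge_form(self):
        # U = -(alpha/2) E^2 with E = q/r^2 equals half the verbatim
        # point-charge expression; the half-consistent flag restores equality
        alpha_prime, q, r = 5.0, 2.0, 3.0
        alpha = polarizability_from_volume(alpha_prime)
        u_field = upol_field(alpha, q / r**2)
        u_point = upol_point_charge(alpha_prime, q, r)
        assert u_field == pytest.approx(0.5 * u_point, rel=1e-12)
        assert upol_point_charge(alpha_prime, q, r, half_consistent=True) \
            == pytest.approx(u_field, rel=1e-12)


class TestMixingAndExchange:
    @settings(deadline=None, derandomize=True)
    @given(lam=st.floats(0, 1), ua=st.floats(-50, 50), ub=st.floats(-50, 50))
    def test_mixed_energy_affine(self, lam, ua, ub):
        u = mixed_energy(MixingState(lam, ua, ub))
        assert u == pytest.approx((1 - lam) * ua + lam * ub, rel=1e-12,
                                  abs=1e-12)

    def test_mixed_energy_end_states(self):
        assert mixed_energy(MixingState(0.0, 10.0, 20.0)) == 10.0
        assert mixed_energy(MixingState(1.0, 10.0, 20.0)) == 20.0
        assert mixed_energy(MixingState(0.5, 10.0, 20.0)) == 15.0
        with pytest.raises(ValueError):
            MixingState(1.5, 0.0, 0.0)

    def test_exchange_acceptance(self):
        assert exchange_acceptance(0.0) == 1.0
        assert exchange_acceptance(math.log(2.0)) == pytest.approx(0.5,
                                                                   rel=1e-12)
        assert exchange_acceptance(800.0) == 0.0  # underflows to 0+
        assert exchange_acceptance(-5.0) == 1.0
        with pytest.raises(ValueError):
            exchange_acceptance(float("nan"))


class TestPairingSummary:
    def test_peak_must_precede_minimum(self):
        with pytest.raises(ValueError):
            PairingSummary(n_contact=1.0, r_first_peak=4.0,
                           r_cip_sip_min=3.0, n_cip=1, n_sip=1)


class TestXYZRoundTrip:
    def test_bit_stable_round_trip(self, tmp_path, rng):
        frames = []
        for k in range(3):
            n = 5 + k
            frames.append(Configuration(
                rng.random((n, 3)) * 17.5,
                np.array(["M", "X", "W", "W", "W", "W", "W"][:n],
                         dtype=object),
                17.5,
                induced_dipoles=rng.normal(size=(n, 3)),
            ))
        path = tmp_path / "frames.xyz"
        write_xyz(frames, path)
        back = read_xyz(path)
        assert len(back) == 3
        for a, b in zip(frames, back):
            np.testing.assert_array_equal(a.positions, b.positions)
            np.testing.assert_array_equal(a.induced_dipoles,
                                          b.induced_dipoles)
            assert list(a.species) == list(b.species)
            assert a.box_length == b.box_length
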