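import numpy as np
import pytest

from ionpair.analysis import (
    classify_pairs,
    compute_rdf,
    coordination_number,
    delta_mu_ind,
    minimum_image_distances,
)
from ionpair.fit import predict_curve
from ionpair.generate import (
    DipoleFieldSpec,
    PairedSystemSpec,
    SULFATE_SO_DISTANCE,
    gen_dipole_field,
    gen_osmotic_curve,
    gen_paired_config,
    gen_random_config,
)
from ionpair.model import Species, build_model, molality_to_state


@pytest.fixture(scope="module")
def ionic_model():
    return build_model(
        [Species("M", 2.0, 2.6), Species("X", -2.0, 4.6),
         Species("W", 0.0, 2.8)],
        78.36, 298.15,
    )


class TestGenRandomConfig:
    def test_zero_density_gives_empty_configuration(self, restricted_22):
        state = molality_to_state(restricted_22, 0.0, {"M": 1, "X": 1})
        conf = gen_random_config(restricted_22, state, 30.0, seed=1)
        assert conf.n_particles == 0

    def test_hard_cores_respected(self, restricted_22):
        state = molality_to_state(restricted_22, 1.0, {"M": 1, "X": 1})
        conf = gen_random_config(restricted_22, state, 40.0, seed=1)
        d = minimum_image_distances(conf.positions, conf.positions, 40.0)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4.6 - 1e-12

    def test_seed_determinism(self, restricted_22):
        state = molality_to_state(restricted_22, 0.5, {"M": 1, "X": 1})
        a = gen_random_config(restricted_22, state, 40.0, seed=7)
        b = gen_random_config(restricted_22, state, 40.0, seed=7)
        c = gen_random_config(restricted_22, state, 40.0, seed=8)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)


class TestGenPairedConfig:
    @pytest.mark.parametrize("n_cip", [0, 1, 3, 8])
    @pytest.mark.parametrize("n_sip", [0, 1, 3, 8])
    def test_planted_truth_round_trip(self, n_cip, n_sip):
        spec = PairedSystemSpec(
            n_cations=16, n_anions=16, n_waters=30, box_length=90.0,
            n_cip=n_cip, n_sip=n_sip, r_contact=3.5, r_sip_gap=2.9, seed=5)
        conf, truth = gen_paired_config(spec)
        _, got_cip, got_sip = classify_pairs(conf, r_cip=4.5, r_sip=6.4)
        assert (got_cip, got_sip) == (n_cip, n_sip)
        assert len(truth) == n_cip + n_sip

    def test_no_cip_means_no_close_contacts(self):
        spec = PairedSystemSpec(
            n_cations=8, n_anions=8, n_waters=0, box_length=70.0,
            n_cip=0, n_sip=0, seed=2)
        conf, _ = gen_paired_config(spec)
        ic, ia = conf.select("M"), conf.select("X")
        d = minimum_image_distances(conf.positions[ic], conf.positions[ia],
                                    conf.box_length)
        assert d.min() >= 2.2 * spec.r_sip_gap

    def test_overfull_spec_rejected(self):
        with pytest.raises(ValueError):
            PairedSystemSpec(n_cations=2, n_anions=2, n_waters=5,
                             box_length=40.0, n_cip=2, n_sip=1)

    def test_determinism(self):
        spec = PairedSystemSpec(n_cations=5, n_anions=5, n_waters=10,
                                box_length=60.0, n_cip=2, n_sip=1, seed=3)
        a, ta = gen_paired_config(spec)
        b, tb = gen_paired_config(spec)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert ta == tb

    def test_tetrahedral_anions_geometry(self):
        spec = PairedSystemSpec(n_cations=2, n_anions=3, n_waters=0,
                                box_length=60.0, n_cip=0, n_sip=0, seed=4,
                                tetrahedral_anions=True)
        conf, _ = gen_paired_config(spec)
        s_sites = conf.select("X")
        o_sites = conf.select("X_O")
        assert len(o_sites) == 4 * len(s_sites)
        d = minimum_image_distances(conf.positions[s_sites],
                                    conf.positions[o_sites],
                                    conf.box_length)
        nearest = np.sort(d, axis=1)[:, :4]
        np.testing.assert_allclose(nearest, SULFATE_SO_DISTANCE, atol=1e-9)

    def test_n_contact_recovers_two_planted_contacts_per_cation(self):
        # 4 cations, each with exactly two anions at contact distance
        rng = np.random.Generator(np.random.PCG64(6))
        from ionpair.analysis import Configuration

        L = 80.0
        centers = rng.random((4, 3)) * L
        pos, spc = [], []
        for c in centers:
            pos.append(c)
            spc.append("M")
        for c in centers:
            for _ in range(2):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos.append((c + 3.5 * v) % L)
                spc.append("X")
        conf = Configuration(np.array(pos), np.array(spc, dtype=object), L)
        rdf = compute_rdf(conf, "M", "X", bin_width=0.1, r_max=20.0)
        n = coordination_number(rdf, 5.0)
        assert n == pytest.approx(2.0, abs=0.01)


class TestGenDipoleField:
    def test_no_ions_gives_zero_dipoles(self, ionic_model):
        from ionpair.analysis import Configuration

        conf = Configuration(np.array([[1.0, 1, 1], [5.0, 5, 5]]),
                             np.array(["W", "W"], dtype=object), 30.0)
        out = gen_dipole_field(conf, DipoleFieldSpec(alpha_prime=1.0),
                               ionic_model)
        np.testing.assert_allclose(out.induced_dipoles, 0.0)

    def test_inverse_square_field_of_single_cation(self, ionic_model):
        from ionpair.analysis import Configuration

        L = 200.0
        mus = []
        for r in (5.0, 10.0):
            conf = Configuration(
                np.array([[0.0, 0, 0], [r, 0, 0]]),
                np.array(["M", "W"], dtype=object), L)
            out = gen_dipole_field(conf, DipoleFieldSpec(alpha_prime=1.0),
                                   ionic_model)
            mus.append(np.linalg.norm(out.induced_dipoles[1]))
        assert mus[0] == pytest.approx(4 * mus[1], rel=1e-9)

    def test_linear_in_ion_charge(self, ionic_model):
        from ionpair.analysis import Configuration

        mono = build_model(
            [Species("M", 1.0, 2.6), Species("X", -1.0, 4.6),
             Species("W", 0.0, 2.8)], 78.36, 298.15)
        conf = Configuration(
            np.array([[0.0, 0, 0], [6.0, 0, 0]]),
            np.array(["M", "W"], dtype=object), 100.0)
        spec = DipoleFieldSpec(alpha_prime=1.0)
        mu_di = np.linalg.norm(
            gen_dipole_field(conf, spec, ionic_model).induced_dipoles[1])
        mu_mono = np.linalg.norm(
            gen_dipole_field(conf, spec, mono).induced_dipoles[1])
        assert mu_di == pytest.approx(2 * mu_mono, rel=1e-12)

    def test_superposition_of_two_ions(self, ionic_model):
        from ionpair.analysis import Configuration

        L = 100.0
        w = np.array([[10.0, 10, 10]])
        ion1 = np.array([[3.0, 10, 10]])
        ion2 = np.array([[10.0, 18, 10]])
        spec = DipoleFieldSpec(alpha_prime=1.0)

        def field_of(ion_pos, labels):
            conf = Configuration(np.vstack([ion_pos, w]),
                                 np.array(labels + ["W"], dtype=object), L)
            return gen_dipole_field(conf, spec, ionic_model).induced_dipoles[-1]

        both = field_of(np.vstack([ion1, ion2]), ["M", "M"])
        single = field_of(ion1, ["M"]) + field_of(ion2, ["M"])
        np.testing.assert_allclose(both, single, rtol=1e-12)

    def test_divalent_small_cation_polarizes_shell_more_than_monovalent_large(
            self, ionic_model):
        """The ordering behind the size/valence dependence of shell
        polarization: a small divalent cation produces a larger first-shell
        excess dipole than a large monovalent one."""
        from ionpair.analysis import Configuration

        def shell_system(model, r_shell):
            pos = [[20.0, 20, 20]]
            spc = ["M"]
            for k in range(6):
                ang = 2 * np.pi * k / 6
                pos.append([20 + r_shell * np.cos(ang),
                            20 + r_shell * np.sin(ang), 20.0])
                spc.append("W")
            for k in range(12):
                ang = 2 * np.pi * k / 12
                pos.append([20 + 15 * np.cos(ang), 20 + 15 * np.sin(ang),
                            20.0])
                spc.append("W")
            conf = Configuration(np.array(pos), np.array(spc, dtype=object),
                                 60.0)
            return gen_dipole_field(conf, DipoleFieldSpec(alpha_prime=1.0),
                                    model)

        mono = build_model(
            [Species("M", 1.0, 3.6), Species("X", -1.0, 4.6),
             Species("W", 0.0, 2.8)], 78.36, 298.15)
        # shell radius ~ (d_cation + d_water)/2
        d_div = delta_mu_ind(shell_system(ionic_model, 2.7))
        d_mono = delta_mu_ind(shell_system(mono, 3.2))
        assert d_div > d_mono > 0

    def test_shell_dipole_shrinks_with_cation_size(self, ionic_model):
        from ionpair.analysis import Configuration

        def mu_at(r):
            conf = Configuration(np.array([[0.0, 0, 0], [r, 0, 0]]),
                                 np.array(["M", "W"], dtype=object), 100.0)
            out = gen_dipole_field(conf, DipoleFieldSpec(alpha_prime=1.0),
                                   ionic_model)
            return np.linalg.norm(out.induced_dipoles[1])

        assert mu_at(2.7) > mu_at(3.2) > mu_at(3.7)


class TestGenOsmoticCurve:
    def test_zero_noise_equals_prediction(self, sulfate_template, fast_grid):
        ms = [0.5, 1.0]
        a = gen_osmotic_curve(sulfate_template, 4.0, ms, noise_sigma=0.0,
                              grid=fast_grid)
        b = predict_curve(sulfate_template, 4.0, ms, grid=fast_grid)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_noise_determinism_contract(self, sulfate_template, fast_grid):
        ms = [0.5, 1.0]
        a = gen_osmotic_curve(sulfate_template, 4.0, ms, noise_sigma=0.01,
                              seed=1, grid=fast_grid)
        b = gen_osmotic_curve(sulfate_template, 4.0, ms, noise_sigma=0.01,
                              seed=1, grid=fast_grid)
        c = gen_osmotic_curve(sulfate_template, 4.0, ms, noise_sigma=0.01,
                              seed=2, grid=fast_grid)
        np.testing.assert_array_equal(a.phi, b.phi)
        assert not np.array_equal(a.phi, c.phi)
        assert np.all(a.sigma_phi == 0.01)
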