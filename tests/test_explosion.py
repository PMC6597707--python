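import numpy as np
import pytest

from ethmig import explosion as ex
from ethmig.kinematics import dalitz_from_event, CoincidenceEvent
from ethmig.units import COULOMB_EV_ANG, get_species


def bodies_at_rest(specs):
    return [
        ex.ChargedBody(mass=m, charge=q, position=pos, velocity=np.zeros(3),
                       species=sp)
        for m, q, pos, sp in specs
    ]


class TestPropagation:
    def test_two_body_analytic_ker(self):
        b = bodies_at_rest(
            [(17, 1, [0, 0, 0], "OH+"), (29, 1, [2.880, 0, 0], "C2H5+")]
        )
        out, info = ex.propagate_to_asymptote(b)
        assert info["kinetic_eV"] == pytest.approx(5.000, rel=5e-3)

    def test_zero_charges_drift_linearly(self):
        b = [
            ex.ChargedBody(17, 0, [0, 0, 0], [0.1, 0, 0], "OH+"),
            ex.ChargedBody(29, 0, [3, 0, 0], [0, -0.2, 0], "C2H5+"),
        ]
        out = ex.coulomb_propagate(b, t_end=10.0, dt=0.5)
        np.testing.assert_allclose(out[0].position, [1.0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(out[1].position, [3, -2.0, 0], atol=1e-9)
        np.testing.assert_allclose(out[0].velocity, [0.1, 0, 0], atol=1e-12)

    def test_equilateral_triangle_symmetric_speeds(self):
        r = 2.0
        angles = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        b = bodies_at_rest(
            [
                (18, 1, [r * np.cos(a), r * np.sin(a), 0.0], "H2O+")
                for a in angles
            ]
        )
        out, _ = ex.propagate_to_asymptote(b)
        speeds = [np.linalg.norm(o.velocity) for o in out]
        assert max(speeds) - min(speeds) < 1e-6 * max(speeds)

    def test_momentum_conserved_to_machine_precision(self):
        b = bodies_at_rest(
            [
                (1, 1, [1.8, -0.5, 0.9], "H+"),
                (18, 1, [0.1, -0.3, 0.0], "H2O+"),
                (27, 1, [1.7, 1.4, 0.0], "C2H3+"),
            ]
        )
        out, _ = ex.propagate_to_asymptote(b)
        psum = np.sum([o.momentum_au for o in out], axis=0)
        assert np.linalg.norm(psum) < 1e-6

    def test_coincident_bodies_rejected(self):
        b = bodies_at_rest(
            [(17, 1, [0, 0, 0], "OH+"), (29, 1, [0.01, 0, 0], "C2H5+")]
        )
        with pytest.raises(ex.DegenerateConfigurationError):
            ex.propagate_to_asymptote(b)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(42)
        rot = ex.random_rotation(rng)
        pos = np.array([[0.0, 0, 0], [2.2, 0, 0], [1.1, 1.9, 0.3]])
        species = [("H+", 1), ("H2O+", 18), ("C2H3+", 27)]
        plain = bodies_at_rest(
            [(m, 1, pos[k], s) for k, (s, m) in enumerate(species)]
        )
        rotated = bodies_at_rest(
            [(m, 1, rot @ pos[k], s) for k, (s, m) in enumerate(species)]
        )
        out_a, _ = ex.propagate_to_asymptote(plain)
        out_b, _ = ex.propagate_to_asymptote(rotated)
        for a, b in zip(out_a, out_b):
            np.testing.assert_allclose(
                rot @ a.momentum_au, b.momentum_au, atol=1e-9
            )


class TestConcerted:
    def test_two_body_antiparallel_momenta(self):
        ev = ex.simulate_concerted("NHM", seed=3)
        p1, p2 = ev.momenta_au
        np.testing.assert_allclose(p1, -p2, rtol=1e-9)

    def test_ker_independent_of_orientation(self):
        kers = [ex.simulate_concerted("TRIPLE", seed=s).ker_eV
                for s in range(20)]
        assert (max(kers) - min(kers)) / max(kers) < 1e-3

    def test_explicit_charge_sites_match_analytic(self):
        sites = {"OH+": np.zeros(3), "C2H5+": np.array([1.83, 0, 0])}
        ev = ex.simulate_concerted("NHM", seed=0, charge_sites=sites)
        assert ev.ker_eV == pytest.approx(14.3996 / 1.83, rel=1e-2)

    def test_unknown_channel_error_lists_channels(self):
        with pytest.raises(ValueError, match="NHM"):
            ex.simulate_concerted("XYZ", seed=0)


class TestSequential:
    def test_daughter_masses_sum_to_intermediate(self):
        for proc in ex.PROCESSES.values():
            assert sum(
                get_species(d).mass for d in proc.daughters
            ) == get_species(proc.intermediate).mass

    def test_degenerate_equals_concerted(self):
        from ethmig.units import FRAGMENT_ATOMS, ethanol_geometry, \
            fragment_sites

        geo = ethanol_geometry()
        seed = 5
        step1 = fragment_sites(geo, FRAGMENT_ATOMS["seq_i"])
        sub = fragment_sites(geo, {"H+": [6], "H2O+": [0, 3, 4]})
        com = step1["H3O+"]
        rot = ex.random_rotation(np.random.default_rng(seed))
        offsets = {k: rot @ (v - com) for k, v in sub.items()}
        ev_seq = ex.simulate_sequential(
            "seq_i", 0.0, seed=seed, daughter_sites=offsets
        )
        ev_con = ex.simulate_concerted(
            "custom",
            seed=seed,
            charge_sites={
                "C2H3+": step1["C2H3+"],
                "H+": sub["H+"],
                "H2O+": sub["H2O+"],
            },
        )
        assert ev_seq.ker_eV == pytest.approx(ev_con.ker_eV, rel=1e-2)
        mags_seq = sorted(np.linalg.norm(ev_seq.momenta_au, axis=1))
        mags_con = sorted(np.linalg.norm(ev_con.momenta_au, axis=1))
        np.testing.assert_allclose(mags_seq, mags_con, rtol=1e-2)

    def test_proton_first_energy_sharing_limit(self):
        """At large ionization delay the proton keeps its two-body share:
        E_H/KER → (45/46)·KER₁/(KER₁+KER₂)."""
        from ethmig.kinematics import kinetic_energy
        from ethmig.units import FRAGMENT_ATOMS, ethanol_geometry, \
            fragment_sites

        geo = ethanol_geometry()
        sites = fragment_sites(geo, FRAGMENT_ATOMS["seq_iii"])
        r1 = np.linalg.norm(sites["H+"] - sites["C2H5O+"])
        ker1 = COULOMB_EV_ANG / r1
        ker2 = COULOMB_EV_ANG / ex.PROCESSES["seq_iii"].daughter_separation
        predicted = (45.0 / 46.0) * ker1 / (ker1 + ker2)
        ev = ex.simulate_sequential("seq_iii", 5000.0, seed=2)
        e_h = kinetic_energy(
            ev.momenta_au[ev.species.index("H+")], get_species("H+").mass
        )
        assert e_h / ev.ker_eV == pytest.approx(predicted, rel=1e-2)

    def test_negative_t_ionize_rejected(self):
        with pytest.raises(ValueError):
            ex.simulate_sequential("seq_i", -1.0, seed=0)


class TestEnsemble:
    def test_same_seed_bitwise_identical(self):
        a = ex.simulate_process_ensemble("seq_ii", 5, seed=9)
        b = ex.simulate_process_ensemble("seq_ii", 5, seed=9)
        for ea, eb in zip(a, b):
            assert ea.t_ionize_fs == eb.t_ionize_fs
            np.testing.assert_array_equal(ea.momenta_au, eb.momenta_au)

    def test_proton_first_lies_higher_on_dalitz(self):
        """H+-first events share more energy to the proton than H2O+-first
        events (upper vs lower Dalitz region)."""

        def mean_yd(process):
            evs = ex.simulate_process_ensemble(process, 60, seed=7)
            pts = [
                dalitz_from_event(
                    CoincidenceEvent(
                        delay_fs=0.0,
                        fragments=list(zip(e.species, e.momenta_au)),
                    )
                )
                for e in evs
            ]
            return np.mean([p.y_d for p in pts])

        assert mean_yd("seq_iii") > mean_yd("seq_ii")

    def test_late_ionization_lowers_ker(self):
        early = ex.simulate_process_ensemble("seq_i", 30, seed=1, t_mean=10)
        late = ex.simulate_process_ensemble("seq_i", 30, seed=1, t_mean=800)
        concerted_ker = np.mean([e.ker_eV for e in early])
        assert np.mean([e.ker_eV for e in late]) < concerted_ker
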