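"""Conserved-order-parameter Ising simulator: energetics, conservation, reactions."""

import numpy as np
import pytest
from scipy import stats

from phasecorr import ising_signaling as isg


def _small_params(**kw):
    defaults = dict(L=32, n_receptors=8, n_kinases=16, n_phosphatases=16,
                    equil_sweeps=0, sweeps=0, seed=5)
    defaults.update(kw)
    return isg.SimParams(**defaults)


class TestInitialization:
    def test_default_composition_exact(self):
        p = isg.SimParams(L=256, equil_sweeps=0, sweeps=0)
        st = isg.init_state(p)
        counts = st.species_counts()
        assert counts["receptor"] == 50
        assert counts["kinase"] == 100
        assert counts["phosphatase"] == 100
        assert counts["background"] == 256**2 - 250

    def test_species_spin_convention(self):
        st = isg.init_state(_small_params())
        st.check_invariants()  # receptors/kinases +1, phosphatases -1

    def test_same_seed_identical_state(self):
        a = isg.init_state(_small_params())
        b = isg.init_state(_small_params())
        assert np.array_equal(a.spin, b.spin)
        assert np.array_equal(a.species, b.species)

    def test_infeasible_composition_rejected(self):
        with pytest.raises(ValueError):
            isg.init_state(_small_params(n_receptors=2000))
        with pytest.raises(ValueError):
            isg.init_state(_small_params(ordered_fraction=1.5))

    def test_beta_set_from_temperature_ratio(self):
        st = isg.init_state(_small_params())
        assert st.beta == pytest.approx(1.0 / (1.05 * isg.TC_EXACT))


class TestHamiltonian:
    def test_ground_state_energy(self):
        p = _small_params(n_receptors=0, n_kinases=0, n_phosphatases=0, ordered_fraction=1.0, L=16)
        st = isg.init_state(p)
        assert isg.hamiltonian(st) == -2 * 16**2  # 2 L^2 bonds, all satisfied

    def test_checkerboard_energy(self):
        p = _small_params(n_receptors=0, n_kinases=0, n_phosphatases=0, ordered_fraction=1.0, L=16)
        st = isg.init_state(p)
        sp = st.spin.copy()
        sp[::2, 1::2] *= -1
        sp[1::2, ::2] *= -1
        st.spin = sp
        assert isg.hamiltonian(st) == +2 * 16**2

    def test_receptor_field_contributes_minus_phi(self):
        p = _small_params(n_receptors=1, n_kinases=0, n_phosphatases=0, ordered_fraction=1.0, L=16)
        st = isg.init_state(p)
        h_no_field = isg.hamiltonian(st)
        phi = 7.0
        st.set_field(isg.FieldSpec("receptor_field", radius_px=4.0, magnitude=phi, center=(8, 8)))
        # move the receptor to the field center (spins all +1 so bonds unchanged)
        st.species[:] = 0
        st.species[8, 8] = 1
        assert isg.hamiltonian(st) == h_no_field - phi

    def test_domain_field_couples_to_all_spins(self):
        p = _small_params(n_receptors=0, n_kinases=0, n_phosphatases=0, ordered_fraction=1.0, L=16)
        st = isg.init_state(p)
        h0 = isg.hamiltonian(st)
        st.set_field(isg.FieldSpec("domain_field", radius_px=3.0, magnitude=1.0, center=(8, 8)))
        n_disc = (st._phi_d > 0).sum()
        assert isg.hamiltonian(st) == h0 - n_disc  # all spins +1 inside the disc


class TestDynamics:
    def test_conservation_under_updates(self):
        st = isg.init_state(_small_params(seed=9), isg.RECEPTOR_FIELD)
        m0 = st.magnetization()
        isg.mc_update(st, 32 * 32 * 200, mode="nonlocal", react=False)
        isg.mc_update(st, 32 * 32 * 200, mode="local", react=True)
        st.check_invariants()
        assert st.magnetization() == m0

    def test_same_seed_identical_trajectory(self):
        outs = []
        for _ in range(2):
            p = _small_params(equil_sweeps=20, sweeps=30, seed=17)
            traj = isg.run_simulation(p, isg.RECEPTOR_FIELD, "equilibrated")
            outs.append((traj.phospho_fraction.copy(), traj.final_state.spin.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_zero_temperature_limit_never_raises_energy(self):
        st = isg.init_state(_small_params(seed=3))
        st.beta = 1e9  # effectively T -> 0: only dH <= 0 moves accepted
        e = isg.hamiltonian(st)
        for _ in range(20):
            isg.mc_update(st, 32 * 32 * 5, mode="local", react=False)
            e_new = isg.hamiltonian(st)
            assert e_new <= e + 1e-9
            e = e_new

    def test_local_and_nonlocal_sample_same_boltzmann_distribution(self):
        # reaction-free Kawasaki dynamics: both proposal schemes must sample
        # the same equilibrium energy distribution at equal beta.  Conserved
        # dynamics decorrelate slowly, so compare mean energies of independent
        # replicate runs rather than serial (autocorrelated) samples.
        energies = {}
        for mode in ("local", "nonlocal"):
            means = []
            for rep in range(10):
                p = _small_params(seed=100 + rep)
                st = isg.init_state(p)
                isg.mc_update(st, 32 * 32 * 400, mode="nonlocal", react=False)
                isg.mc_update(st, 32 * 32 * 50, mode=mode, react=False)
                samples = []
                for _ in range(15):
                    isg.mc_update(st, 32 * 32 * 10, mode=mode, react=False)
                    samples.append(isg.hamiltonian(st))
                means.append(np.mean(samples))
            energies[mode] = np.asarray(means)
        stat, pval = stats.ks_2samp(energies["local"], energies["nonlocal"])
        assert pval > 0.01

    def test_receptor_field_confines_receptors(self):
        p = isg.SimParams(L=128, equil_sweeps=300, sweeps=200, seed=2)
        traj = isg.run_simulation(p, isg.RECEPTOR_FIELD, "equilibrated")
        st = traj.final_state
        yy, xx = np.mgrid[0:128, 0:128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= 16**2
        inside = ((st.species == 1) & disc).sum()
        assert inside >= 0.9 * p.n_receptors

    def test_phospho_flags_travel_with_receptors(self):
        st = isg.init_state(_small_params(seed=4))
        st.phospho[st.species == 1] = 1
        isg.mc_update(st, 32 * 32 * 100, mode="nonlocal", react=False)
        st.check_invariants()
        assert st.phospho.sum() == 8  # flags conserved without reactions


class TestReactions:
    @staticmethod
    def _state_with_neighborhood(neighbor_species):
        p = _small_params(n_receptors=1, n_kinases=1, n_phosphatases=1,
                          ordered_fraction=0.5, L=16)
        st = isg.init_state(p)
        st.species[:] = 0
        st.spin[:] = 1
        st.species[8, 8] = 1  # receptor under test
        st.species[8, 9] = isg.SPECIES_CODES[neighbor_species]
        if neighbor_species == "phosphatase":
            st.spin[8, 9] = -1
        # park the bookkeeping species somewhere far away
        st.species[0, 0] = 2 if neighbor_species != "kinase" else 3
        st.spin[0, 0] = 1 if st.species[0, 0] == 2 else -1
        st.species[0, 2] = ({1, 2, 3} - {st.species[8, 9], st.species[0, 0]}).pop()
        st.spin[0, 2] = 1 if st.species[0, 2] != 3 else -1
        return st

    def test_phosphatase_contact_deterministically_dephosphorylates(self):
        st = self._state_with_neighborhood("phosphatase")
        st.phospho[8, 8] = 1
        isg.reaction_step(st, (8, 8))
        assert st.phospho[8, 8] == 0

    def test_kinase_contact_rate_matches_binomial(self):
        st = self._state_with_neighborhood("kinase")
        events = 0
        n = 10_000
        for _ in range(n):
            st.phospho[8, 8] = 0
            isg.reaction_step(st, (8, 8))
            events += int(st.phospho[8, 8])
        # ~Binomial(10^4, 0.001): mean 10, accept within ~4 sigma
        assert 1 <= events <= 24

    def test_phosphatase_dominates_simultaneous_adjacency(self):
        st = self._state_with_neighborhood("kinase")
        st.species[8, 7] = 3  # phosphatase on the other side
        st.spin[8, 7] = -1
        st.phospho[8, 8] = 1
        for _ in range(200):
            isg.reaction_step(st, (8, 8))
            assert st.phospho[8, 8] == 0  # dephos applied last, p = 1

    def test_without_kinases_or_rbk_phospho_never_increases(self):
        p = _small_params(n_kinases=0, rbk_enabled=False, seed=12)
        st = isg.init_state(p, isg.RECEPTOR_FIELD)
        st.phospho[st.species == 1] = 1
        counts = [int(st.phospho.sum())]
        for _ in range(50):
            isg.mc_update(st, 32 * 32, mode="local", react=True)
            counts.append(int(st.phospho.sum()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_rbk_spreads_phosphorylation(self):
        # a phosphorylated receptor next to another receptor can pass the mark
        p = _small_params(n_receptors=2, n_kinases=1, n_phosphatases=1, L=16)
        st = isg.init_state(p)
        st.species[:] = 0
        st.spin[:] = 1
        st.species[8, 8] = st.species[8, 9] = 1
        st.phospho[8, 8] = 1
        st.species[0, 0] = 2
        st.species[0, 2] = 3
        st.spin[0, 2] = -1
        events = 0
        n = 10_000
        for _ in range(n):
            st.phospho[8, 9] = 0
            isg.reaction_step(st, (8, 9))
            events += int(st.phospho[8, 9])
        assert 1 <= events <= 24


class TestSnapshotCorrelation:
    def test_random_species_flat_autocorrelation(self):
        # unclustered snapshots: kinase vs ordered background ~ random at long r
        p = _small_params(L=64, n_receptors=0, n_kinases=200, n_phosphatases=200,
                          sweeps=40, equil_sweeps=100, snapshot_every=4, seed=6)
        traj = isg.run_simulation(p, isg.FieldSpec("none"), "off")
        res = isg.snapshot_crosscorr(traj, "kinase", "phosphatase", r_max_nm=40.0)
        tail = res.r > 20.0
        assert abs(np.nanmean(res.c[tail]) - 1.0) < 0.1

    def test_blur_attenuates_amplitude(self):
        p = isg.SimParams(L=128, equil_sweeps=500, sweeps=600, snapshot_every=12, seed=7)
        traj = isg.run_simulation(p, isg.RECEPTOR_FIELD, "equilibrated")
        raw = isg.snapshot_crosscorr(traj, "receptor", "kinase", r_max_nm=40.0)
        blur = isg.snapshot_crosscorr(traj, "receptor", "kinase", blur_sigma_nm=30.0,
                                      r_max_nm=40.0)
        short = raw.r < 10.0
        assert np.nanmean(raw.c[short]) > np.nanmean(blur.c[short]) > 1.0

    def test_requires_snapshots(self):
        p = _small_params(sweeps=5, equil_sweeps=0)
        traj = isg.run_simulation(p, isg.FieldSpec("none"), "off")
        with pytest.raises(ValueError, match="snapshot"):
            isg.snapshot_crosscorr(traj, "receptor", "kinase")


class TestCompositionSweep:
    def test_half_fraction_matches_run_simulation_defaults(self):
        p = _small_params(equil_sweeps=30, sweeps=40, seed=19)
        sweep = isg.composition_sweep(p, [0.5], field_schedule="equilibrated")
        direct = isg.run_simulation(p, isg.RECEPTOR_FIELD, "equilibrated")
        assert np.array_equal(
            sweep[0.5]["trajectory"].phospho_fraction, direct.phospho_fraction
        )

    def test_infeasible_fraction_skipped_with_warning(self):
        p = _small_params(equil_sweeps=5, sweeps=5)
        with pytest.warns(UserWarning, match="infeasible"):
            out = isg.composition_sweep(p, [-0.2, 0.5], field_schedule="equilibrated")
        assert list(out) == [0.5]
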