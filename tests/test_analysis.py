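"""Estimators and fits: exact regression identities, parameter-recovery
round trips, estimator-noise separation, and the grafted-layer pipeline
contracts (fluctuation peak, attraction collapse, "not a brush")."""

import numpy as np
import pytest

from graftnp import (ForceField, SimSettings, build_grafted_np, run_nvt,
                     sample_free_chains)
from graftnp import theory as th
from graftnp.analysis import (fit_crossover, interaction_sweep,
                              persistence_length, rg_scaling_exponent,
                              sigma_rh_curve, summarize_ensemble)
from graftnp.engine import ChainEnsemble
from graftnp.workbench import make_fixture


def _ensemble_with_rg(rg: float) -> ChainEnsemble:
    """Two-bead ensemble whose radius of gyration is exactly rg."""
    pos = np.zeros((1, 1, 2, 3))
    pos[0, 0, 1, 2] = 2 * rg
    return ChainEnsemble(pos, 2)


class TestScalingExponent:
    def test_exact_power_law_recovered(self):
        ens = {L: _ensemble_with_rg(0.4 * L**0.7) for L in (5, 10, 18, 40)}
        fit = rg_scaling_exponent(ens, n_boot=10, seed=0)
        assert fit["nu"] == pytest.approx(0.700, abs=1e-9)
        assert fit.rho == pytest.approx(1.0, abs=1e-9)

    def test_rigid_rod_limit(self):
        def rod(L):
            pos = np.zeros((1, 1, L, 3))
            pos[0, 0, :, 0] = 0.63 * np.arange(L)
            return ChainEnsemble(pos, L)

        fit = rg_scaling_exponent({L: rod(L) for L in (8, 16, 32, 64)},
                                  n_boot=5, seed=0)
        assert fit["nu"] == pytest.approx(1.0, abs=0.02)

    def test_needs_three_lengths(self):
        with pytest.raises(ValueError):
            rg_scaling_exponent({5: _ensemble_with_rg(1.0),
                                 10: _ensemble_with_rg(1.5)})

    def test_md_chains_swollen_exponent(self, free_chain_ensembles_small):
        """Short semiflexible excluded-volume chains: nu between the theta
        and rod limits, with high log-log correlation."""
        fit = rg_scaling_exponent(free_chain_ensembles_small, n_boot=50,
                                  seed=1)
        assert 0.55 < fit["nu"] < 0.85
        assert fit.rho > 0.99


class TestPersistenceLength:
    def test_freely_rotating_oracle(self, rng):
        """Synthetic chains with a fixed bond angle: C(s) = cos(gamma)^s
        exactly, so the 1/e arc length is -b/ln cos(gamma)."""
        b, cg, L, n = 0.63, 0.7, 30, 400
        pos = np.zeros((1, n, L, 3))
        for c in range(n):
            d = np.array([0.0, 0.0, 1.0])
            for i in range(1, L):
                # rotate d by angle gamma about a random perpendicular axis
                axis = np.cross(d, rng.normal(size=3))
                axis /= np.linalg.norm(axis)
                g = np.arccos(cg)
                d = d * np.cos(g) + np.cross(axis, d) * np.sin(g)
                d /= np.linalg.norm(d)
                pos[0, c, i] = pos[0, c, i - 1] + b * d
        fit = persistence_length(ChainEnsemble(pos, L), n_boot=50, seed=0)
        # discrete 1/e crossing of cg^s, linearly interpolated
        k = int(np.ceil(-1 / np.log(cg)))
        frac = (cg ** (k - 1) - 1 / np.e) / (cg ** (k - 1) - cg**k)
        expect = (k - 1 + frac) * b
        assert fit["l_p"] == pytest.approx(
            expect, abs=3 * fit.std_errors["l_p"] + 0.02 * expect)

    def test_stiffness_monotonicity(self):
        """l_p grows with k_lin; k_lin = 0 gives of order one bond length."""
        lps = {}
        for klin in (0.0, 3.0):
            ffk = ForceField(k_lin=klin)
            ens = sample_free_chains(
                [20], ffk, SimSettings(n_steps=80_000, n_samples=40,
                                       seed=11), n_chains=10)[20]
            lps[klin] = persistence_length(ens, n_boot=30, seed=2)["l_p"]
        assert lps[0.0] < lps[3.0]
        assert 0.3 < lps[0.0] < 1.2  # of order the 0.63 nm bond length

    def test_too_stiff_reports_no_crossing(self):
        pos = np.zeros((1, 3, 10, 3))
        pos[..., 2] = 0.63 * np.arange(10)  # straight rods never decay
        with pytest.raises(ValueError, match="crossing"):
            persistence_length(ChainEnsemble(pos, 10), n_boot=0)


class TestCrossoverFit:
    def test_phi_one_round_trip(self):
        N = np.array([1, 2, 5, 10, 20, 50, 100])
        y = th.delta_rh_grafted_chains(N, 0.08, 2.0, 1.0)
        fit = fit_crossover(np.column_stack([N, y]), 0.08)
        assert fit["phi"] == pytest.approx(1.0, abs=0.02)
        assert fit["delta_rh_sat"] == pytest.approx(2.0, rel=0.02)
        assert fit.rho > 0.999

    def test_noisy_recovery_within_two_se(self, rng):
        N = np.array([1, 2, 5, 10, 20, 50, 100, 200, 400])
        y = th.delta_rh_grafted_chains(N, 0.06, 1.8, 0.7)
        y = y * (1 + 0.05 * rng.standard_normal(y.shape))
        fit = fit_crossover(np.column_stack([N, y]), 0.06)
        assert abs(fit["phi"] - 0.7) < max(2 * fit.std_errors["phi"], 0.05)
        assert abs(fit["delta_rh_sat"] - 1.8) < max(
            2 * fit.std_errors["delta_rh_sat"], 0.05 * 1.8)

    def test_linear_regime_unbounded_saturation(self):
        N = np.array([1, 2, 3, 4, 5], dtype=float)
        y = 0.05 * N  # purely linear: saturation not identifiable
        fit = fit_crossover(np.column_stack([N, y]), 0.05)
        assert (not np.isfinite(fit.std_errors["delta_rh_sat"])
                or fit.std_errors["delta_rh_sat"]
                > 10 * fit["delta_rh_sat"]
                or fit["delta_rh_sat"] > 100 * y.max())


class TestEnsembleSummary:
    def test_frozen_snapshots_have_zero_conformational_variance(self):
        fx = make_fixture("grafted_np",
                          {"R": 3.0, "N_c": 5, "L": 5,
                           "forcefield": {"r_s_core": 2.675}}, seed=1)
        frames = [fx.obj] * 40
        summ = summarize_ensemble(frames, n_walks=4_000, seed=0)
        noise = np.sqrt((summ.table.R_h_se**2).mean())
        assert summ.sigma_rh < noise

    def test_bare_core_trivial(self, ff):
        from graftnp.engine import run_nvt as _run
        cfg = build_grafted_np(5.0, 0, 10, ff)
        traj = _run(cfg, ff, SimSettings(n_steps=1_000, n_samples=40))
        summ = summarize_ensemble(traj, n_walks=5_000, seed=1)
        assert summ.mean_rh == pytest.approx(5.0, rel=0.01)
        assert summ.sigma_rh < 0.02
        assert abs(summ.delta_rh) < 0.05

    def test_requires_thirty_snapshots(self):
        fx = make_fixture("sphere", {"R": 1.0})
        with pytest.raises(ValueError, match="30"):
            summarize_ensemble([fx.obj] * 10)

    def test_histograms_normalized(self, ff_small_system_summary):
        summ = ff_small_system_summary
        dens, edges = summ.histograms["R_h"]
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)
        assert summ.sigma_rh >= 0


@pytest.fixture(scope="module")
def ff_small_system_summary():
    ffc = ForceField(r_s_core=2.675)
    cfg = build_grafted_np(3.0, 8, 6, ffc, seed=4)
    traj = run_nvt(cfg, ffc, SimSettings(n_steps=60_000, n_samples=40,
                                         seed=4))
    return summarize_ensemble(traj, n_walks=6_000, seed=4,
                              metadata={"R": 3.0})


class TestPipelines:
    def test_sigma_rh_curve_peaks_in_interior(self):
        """Fluctuations rise with coverage, peak, then fall toward the
        brush limit; N = 0 has zero conformational variance."""
        df = sigma_rh_curve(2.0, 5, [0, 2, 8, 30],
                            ff=ForceField(r_s_core=2.0 - 0.325),
                            settings=SimSettings(n_steps=60_000,
                                                 n_samples=40, seed=6),
                            n_walks=8_000, seed=6)
        assert df.sigma_rh.iloc[0] == 0.0
        peak_n = df.attrs["peak_N"]
        assert peak_n not in (0, 30)
        assert df.sigma_rh.iloc[-1] < df.attrs["peak_sigma"]

    def test_attraction_collapses_layer(self):
        """Core--bead attraction reduces mean R_h at low grafting density."""
        df = interaction_sweep([0.0, 2.0], 3.0, 5, 8,
                               settings=SimSettings(n_steps=60_000,
                                                    n_samples=40, seed=8),
                               n_walks=8_000, seed=8)
        assert df.mean_rh.iloc[1] < df.mean_rh.iloc[0]

    def test_delta_rh_linear_in_L_but_chains_unstretched(
            self, free_chain_ensembles_small):
        """The central observation: delta R_h grows near-linearly with chain
        length at fixed coverage (rho >= 0.9) while the per-chain R_g in the
        grafted layer stays within 10% of the free-chain value - the layer
        is not a brush."""
        Ls = [5, 10, 18]
        ffc = ForceField(r_s_core=4.675)
        deltas = []
        grafted_rg = {}
        for L in Ls:
            cfg = build_grafted_np(5.0, 15, L, ffc, seed=L)
            traj = run_nvt(cfg, ffc, SimSettings(n_steps=80_000,
                                                 n_samples=40, seed=L))
            summ = summarize_ensemble(traj, n_walks=6_000, seed=L)
            deltas.append(summ.delta_rh)
            x = np.array([f.per_chain_positions() for f in traj.frames])
            com = x.mean(axis=2, keepdims=True)
            grafted_rg[L] = float(np.sqrt(
                ((x - com) ** 2).sum(axis=-1).mean()))
        rho = np.corrcoef(Ls, deltas)[0, 1]
        assert rho >= 0.9
        assert np.all(np.diff(deltas) > 0)
        for L in Ls:
            free = free_chain_ensembles_small[L].rg_per_snapshot()
            free_rms = float(np.sqrt((free**2).mean()))
            assert grafted_rg[L] == pytest.approx(free_rms, rel=0.10)
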