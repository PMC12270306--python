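import numpy as np
import pytest

from spopulse.ssa import (IDX_TAP, SSAModel, SSAParams, SSA_SPECIES,
                          build_matrix_ssa, burn_in, gillespie_simulate,
                          initial_state, run_ensemble)


def _model_from_rows(rows):
    """Assemble a small SSAModel from (rate, rtype, sp1, sp2, changes)."""
    n_sp = len(SSA_SPECIES)
    rates, rtypes, sp1, sp2, stoich = [], [], [], [], []
    for rate, rtype, s1, s2, changes in rows:
        rates.append(rate)
        rtypes.append(rtype)
        sp1.append(s1)
        sp2.append(s2)
        row = np.zeros(n_sp, dtype=np.int64)
        for idx, d in changes:
            row[idx] += d
        stoich.append(row)
    return SSAModel(np.array(rates), np.array(rtypes, np.int64),
                    np.array(sp1, np.int64), np.array(sp2, np.int64),
                    np.array(stoich, np.int64), omega=1.0, refresh_dt=0.05,
                    locked=False)


X = SSA_SPECIES.index("TapA")     # reuse a slot as the generic species
G_OFF = SSA_SPECIES.index("PI_off")
G_ON = SSA_SPECIES.index("PI_on")


def birth_death_model(k=80.0, gamma=2.0):
    return _model_from_rows([
        (k, 0, -1, -1, [(X, +1)]),
        (gamma, 1, X, -1, [(X, -1)]),
    ])


def telegraph_model(kon=1.0, koff=3.0, ktx=60.0, gamma=2.0):
    return _model_from_rows([
        (kon, 1, G_OFF, -1, [(G_OFF, -1), (G_ON, +1)]),
        (koff, 1, G_ON, -1, [(G_ON, -1), (G_OFF, +1)]),
        (ktx, 1, G_ON, -1, [(X, +1)]),
        (gamma, 1, X, -1, [(X, -1)]),
    ])


class TestKernel:
    def test_zero_propensities_freeze_state(self):
        model = _model_from_rows([(0.0, 0, -1, -1, [(X, +1)])])
        y0 = initial_state()
        y0[X] = 7
        ts, rec, fin = gillespie_simulate(model, 0.0, 5.0, seed=1, y0=y0)
        assert np.all(rec == 7)
        assert fin[X] == 7

    def test_identical_seeds_identical_output(self):
        model = birth_death_model()
        _, r1, f1 = gillespie_simulate(model, 0.0, 10.0, seed=42)
        _, r2, f2 = gillespie_simulate(model, 0.0, 10.0, seed=42)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(f1, f2)

    def test_different_seeds_differ(self):
        model = birth_death_model()
        _, r1, _ = gillespie_simulate(model, 0.0, 10.0, seed=1)
        _, r2, _ = gillespie_simulate(model, 0.0, 10.0, seed=2)
        assert not np.array_equal(r1, r2)

    def test_birth_death_stationary_poisson(self):
        # constitutive birth-death: stationary law Poisson(k/gamma),
        # so mean = variance = k/gamma (Fano factor 1)
        k, gamma = 80.0, 2.0
        model = birth_death_model(k, gamma)
        samples = []
        for s in range(40):
            # sample every 2.5/gamma after a 5/gamma burn-in
            _, rec, _ = gillespie_simulate(model, 0.0, 320.0, seed=1000 + s,
                                           record_dt=1.25)
            samples.extend(rec[4:])
        samples = np.asarray(samples, float)
        n_eff = samples.size
        mean, var = samples.mean(), samples.var()
        se_mean = np.sqrt(var / n_eff)
        assert abs(mean - k / gamma) < 3 * se_mean + 0.05
        fano = var / mean
        se_fano = np.sqrt(2.0 / n_eff)      # Poisson approximation
        assert abs(fano - 1.0) < 4 * se_fano + 0.05

    def test_telegraph_stationary_mean(self):
        # ON<->OFF gene: stationary mRNA mean ktx*kon/((kon+koff)*gamma)
        kon, koff, ktx, gamma = 1.0, 3.0, 60.0, 2.0
        model = telegraph_model(kon, koff, ktx, gamma)
        y0 = initial_state()
        samples = []
        for s in range(60):
            _, rec, _ = gillespie_simulate(model, 0.0, 260.0, seed=500 + s,
                                           y0=y0, record_dt=2.0)
            samples.extend(rec[3:])
        samples = np.asarray(samples, float)
        expected = ktx * kon / ((kon + koff) * gamma)
        se = samples.std() / np.sqrt(samples.size / 2.0)  # mild correlation
        assert abs(samples.mean() - expected) < 3 * se + 0.1


class TestMatrixNetworkSSA:
    def test_burn_in_zero_input_classified_off(self):
        model = build_matrix_ssa(timing=0.4)
        y = burn_in(model, 0.0, seed=3)
        assert y[IDX_TAP] < 200

    def test_burn_in_saturating_input_classified_on(self):
        model = build_matrix_ssa(timing=0.4)
        y = burn_in(model, 3.0, seed=4)
        assert y[IDX_TAP] >= 200

    def test_promoter_state_conservation(self):
        model = build_matrix_ssa(timing=0.4)
        y = initial_state()
        for seed in range(5):
            _, _, y = gillespie_simulate(model, 0.5, 3.0, seed=seed, y0=y)
            assert model.check_promoter_conservation(y)
            assert np.all(y >= 0)

    def test_locked_variant_conserves_promoters(self):
        model = build_matrix_ssa(timing=0.4, locked=True)
        y = initial_state()
        _, _, y = gillespie_simulate(model, 0.5, 10.0, seed=9, y0=y)
        assert model.check_promoter_conservation(y)

    def test_single_cell_ensemble_reduces_to_simulation(self):
        model = build_matrix_ssa(timing=0.4)
        ens = run_ensemble(model, 0.2, n_cells=1, seed_base=7, duration=5.0)
        y0 = burn_in(model, 0.0, seed=7)
        _, rec, _ = gillespie_simulate(model, 0.2, 5.0, seed=7 + 1_000_000,
                                       y0=y0)
        np.testing.assert_array_equal(ens.tapA[0], rec)

    def test_ensemble_counts_partition(self):
        model = build_matrix_ssa(timing=0.4)
        ens = run_ensemble(model, 0.3, n_cells=4, seed_base=11, duration=4.0)
        assert np.all(ens.n_on() + ens.n_off() == 4)

    def test_omega_scaling_reduces_relative_noise(self):
        # doubling the system size shrinks relative fluctuations of the
        # TapA count around its deterministic value
        outs = {}
        for scale in (1.0, 4.0):
            model = build_matrix_ssa(timing=0.4, omega_scale=scale)
            y = burn_in(model, 3.0, seed=21)
            _, rec, _ = gillespie_simulate(model, 3.0, 30.0, seed=22, y0=y)
            outs[scale] = rec / model.omega
        assert outs[4.0].std() / outs[4.0].mean() < \
            outs[1.0].std() / outs[1.0].mean()


class TestBinomialPartitioning:
    def test_daughter_mean_is_half(self):
        # E[daughter] = X/2 under Binomial(X, 1/2) partitioning
        rng = np.random.default_rng(0)
        x = 400
        draws = rng.binomial(x, 0.5, size=10_000)
        se = np.sqrt(x / 4.0 / 10_000)
        assert abs(draws.mean() - x / 2) < 3 * se

    def test_stochastic_cycle_ensemble_runs(self):
        from spopulse.ssa import stochastic_cycle_ensemble
        ens = stochastic_cycle_ensemble(n_cells=2, seed_base=5, g_mean=0.4,
                                        duration=6.0, n_pulse_grid=5)
        assert ens.tapA.shape[0] == 2
        assert np.all(ens.tapA >= 0)


def test_ensemble_summary_csv(tmp_path):
    model = build_matrix_ssa(timing=0.4)
    ens = run_ensemble(model, 0.3, n_cells=3, seed_base=2, duration=2.0)
    path = tmp_path / "summary.csv"
    ens.summary_to_csv(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert np.all(data[:, 1] + data[:, 2] == 3)
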