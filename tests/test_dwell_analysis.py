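"""Constant-force pipeline: screening, state assignment, dwell kinetics."""

import numpy as np
import pandas as pd
import pytest

from riboforce import dwell_analysis as da
from riboforce import synthetic_data as sd
from riboforce.trace_model import ConditionLabel, Trace


def _square_trace(pattern, level=60.0, step=15.0, fs=30.0, noise=0.0, rng=None,
                  samples_per=30):
    """Trace whose extension follows a given folded(0)/unfolded(1) pattern."""
    states = np.repeat(np.asarray(pattern, dtype=int), samples_per)
    z = level + step * states
    if noise:
        z = z + (rng or np.random.default_rng(0)).normal(0, noise, states.size)
    t = np.arange(states.size) / fs
    return Trace("b0", ConditionLabel(), t, z, np.full(states.size, 7.0), fs), states


class TestExcludeNoisy:
    def test_clean_simulated_trace_passes(self, control_cf_trace):
        tr, _, _ = control_cf_trace
        assert da.exclude_noisy(tr, 15.0).passed

    def test_planted_artifact_excursion_fails(self, control_cf_trace):
        tr, _, _ = control_cf_trace
        bad = tr.slice(slice(0, len(tr)))
        bad.extension = tr.extension.copy()
        bad.extension[5000:5012] += 40.0
        verdict = da.exclude_noisy(bad, 15.0)
        assert not verdict.passed
        assert "window-range-exceeds-2x-structure" in verdict.reasons

    def test_flat_trace_fails_for_no_transitions(self, rng):
        t = np.arange(3000) / 30.0
        tr = Trace("b", ConditionLabel(), t, 60 + rng.normal(0, 3, 3000),
                   np.full(3000, 7.0), 30.0)
        assert "no-transitions" in da.exclude_noisy(tr, 15.0).reasons

    def test_never_folding_trace_fails(self, rng):
        # four brief visits to the folded level in an 11-min trace (0.3%)
        states = np.ones(20000, dtype=int)
        for start in (3000, 8000, 13000, 18000):
            states[start : start + 15] = 0
        z = 60 + 15 * states + rng.normal(0, 1, 20000)
        tr = Trace("b", ConditionLabel(), np.arange(20000) / 30.0, z,
                   np.full(20000, 7.0), 30.0)
        assert "never-folds" in da.exclude_noisy(tr, 15.0).reasons

    def test_window_longer_than_trace_errors(self):
        tr, _ = _square_trace([0, 1], samples_per=5)
        with pytest.raises(ValueError):
            da.exclude_noisy(tr, 15.0, window_s=10.0)


class TestAssignStates:
    def test_noiseless_square_wave_recovered_exactly(self):
        tr, truth = _square_trace([0, 1, 0, 1, 1, 0], samples_per=45)
        path = da.assign_states(tr)
        np.testing.assert_array_equal(path.states, truth)

    def test_snr_five_gives_99_percent_agreement(self, control_model):
        proto = sd.ProtocolParams(kind="constant_force", hold_force=7.0,
                                  hold_duration=1800.0, noise_sd=3.0)  # SNR = 15/3
        tr, _, truth = sd.simulate_constant_force_trace(control_model, proto, 0.0, rng=77)
        path = da.assign_states(tr)
        agreement = np.mean((path.states == 1) == truth)
        assert agreement >= 0.99

    def test_unimodal_histogram_raises(self, rng):
        t = np.arange(2000) / 30.0
        tr = Trace("b", ConditionLabel(), t, 60 + rng.normal(0, 2, 2000),
                   np.full(2000, 7.0), 30.0)
        with pytest.raises(da.StateAssignmentError):
            da.assign_states(tr)

    def test_runs_shorter_than_two_samples_are_merged(self):
        tr, _ = _square_trace([0, 1, 0], samples_per=30)
        tr.extension[45] += 15.0  # single-sample blip inside a folded run
        path = da.assign_states(tr)
        lengths = [r[1] for r in da._runs(path.states)]
        assert min(lengths) >= 2


class TestExtractDwells:
    def test_fffuuff_pattern_arithmetic(self):
        path = da.StatePath(np.array([0, 0, 0, 1, 1, 0, 0]), 60.0, 75.0, 1.0, 30.0)
        dwells = da.extract_dwells(path)
        assert [d.duration for d in dwells] == pytest.approx([3 / 30, 2 / 30, 2 / 30])
        assert [d.censored for d in dwells] == [True, False, True]
        assert [d.state.value for d in dwells] == ["folded", "unfolded", "folded"]

    def test_durations_conserve_trace_length(self, control_cf_trace):
        tr, _, _ = control_cf_trace
        path = da.assign_states(tr)
        dwells = da.extract_dwells(path)
        assert sum(d.duration for d in dwells) == pytest.approx(tr.duration, abs=1e-9)

    def test_dwell_count_is_transition_count_plus_one(self, control_cf_trace):
        tr, _, _ = control_cf_trace
        path = da.assign_states(tr)
        dwells = da.extract_dwells(path)
        transitions = int(np.sum(np.diff(path.states) != 0))
        assert len(dwells) == transitions + 1


class TestExpMixture:
    def test_single_component_mle_is_sample_mean(self, rng):
        d = rng.exponential(2.5, 200)
        sel = da.fit_exp_mixture(d, rng=0)
        assert sel.fits[1].lifetimes[0] == pytest.approx(np.mean(d), abs=1e-9)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            da.fit_exp_mixture(np.ones(5))

    def test_planted_two_component_mixture_recovered(self):
        hits = 0
        for s in range(10):
            g = np.random.default_rng(300 + s)
            d = np.where(g.random(500) < 0.5, g.exponential(1.0, 500),
                         g.exponential(10.0, 500))
            sel = da.fit_exp_mixture(d, rng=s)
            if sel.best.n_components == 2:
                t1, t2 = sel.best.lifetimes
                if abs(t1 - 1.0) < 0.4 and abs(t2 - 10.0) < 2.5:
                    hits += 1
        assert hits >= 9

    def test_bic_not_fooled_by_single_exponential(self):
        wrong = 0
        for s in range(10):
            d = np.random.default_rng(400 + s).exponential(3.0, 500)
            wrong += da.fit_exp_mixture(d, rng=s).best.n_components != 1
        assert wrong <= 1

    def test_weights_sum_to_one_and_lifetimes_sorted(self, rng):
        d = np.concatenate([rng.exponential(1.0, 300), rng.exponential(8.0, 300)])
        sel = da.fit_exp_mixture(d, rng=1)
        for fit in sel.fits.values():
            assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
            assert list(fit.lifetimes) == sorted(fit.lifetimes)


def _dwells_frame(spec):
    """spec: {(bead, ligand, conc): (folded_durs, unfolded_durs)}"""
    rows = []
    for (b, lig, c), (fd, ud) in spec.items():
        for d in fd:
            rows.append({"bead_id": b, "ligand": lig, "concentration": c,
                         "state": "folded", "duration": d, "censored": False})
        for d in ud:
            rows.append({"bead_id": b, "ligand": lig, "concentration": c,
                         "state": "unfolded", "duration": d, "censored": False})
    return pd.DataFrame(rows)


class TestAggregateRates:
    def test_control_self_normalizes_to_zero(self, rng):
        fd, ud = rng.exponential(4.0, 80), rng.exponential(3.0, 80)
        df = _dwells_frame({("b0", "control", 0.0): (fd, ud)})
        out = da.aggregate_rates(df)
        row = out.iloc[0]
        assert row.norm_log_unfold_rate == 0.0
        assert row.norm_log_refold_rate == 0.0

    def test_halved_unfolding_rate_shifts_log_rate_by_ln2(self):
        hits = 0
        for s in range(8):
            g = np.random.default_rng(500 + s)
            spec = {}
            for b in range(6):
                spec[(f"b{b}", "control", 0.0)] = (g.exponential(4.0, 150),
                                                   g.exponential(3.0, 150))
                spec[(f"b{b}", "compound4", 5e-4)] = (g.exponential(8.0, 150),
                                                      g.exponential(3.0, 150))
            out = da.aggregate_rates(_dwells_frame(spec))
            m = out[out.ligand == "compound4"].norm_log_unfold_rate
            se = m.std(ddof=1) / np.sqrt(len(m)) + 1e-12
            # per-bead sampling error of log-mean lifetime: ~1/sqrt(150)
            if abs(m.mean() + np.log(2)) < 3 * max(se, 2 / np.sqrt(150)):
                hits += 1
        assert hits >= 7

    def test_bead_without_control_dropped(self, rng):
        spec = {("b0", "control", 0.0): (rng.exponential(4, 50), rng.exponential(3, 50)),
                ("b1", "compound4", 1e-4): (rng.exponential(4, 50), rng.exponential(3, 50))}
        with pytest.warns(UserWarning, match="without control"):
            out = da.aggregate_rates(_dwells_frame(spec))
        assert set(out.bead_id) == {"b0"}

    def test_mixture_route_reports_long_component_weight(self, rng):
        fd = np.where(rng.random(400) < 0.6, rng.exponential(2.0, 400),
                      rng.exponential(40.0, 400))
        spec = {("b0", "control", 0.0): (rng.exponential(2.0, 200), rng.exponential(3, 200)),
                ("b0", "preq1", 5e-7): (fd, rng.exponential(3, 200))}
        out = da.aggregate_rates(_dwells_frame(spec), rng=0)
        row = out[out.ligand == "preq1"].iloc[0]
        assert 0.25 <= row.long_component_weight <= 0.55
        assert np.isfinite(row.log_unfold_rate_long)
        # short component tracks the control lifetime
        assert abs(row.norm_log_unfold_rate) < 0.3


class TestOccupancy:
    def test_planted_occupancy_curve_recovered(self):
        g = np.random.default_rng(9)
        KD = 50e-9
        fits = {}
        for c in (0.0, 1e-8, 5e-8, 2e-7, 1e-6):
            p = c / (c + KD)
            n = 600
            d = np.where(g.random(n) < p, g.exponential(50.0, n), g.exponential(2.0, n))
            fits[c] = da.fit_exp_mixture(d, rng=3)
        table, sat = da.occupancy_vs_concentration(fits)
        w = dict(zip(table.concentration, table.long_component_weight))
        assert w[0.0] == 0.0
        for c in (1e-8, 5e-8, 2e-7):
            p = c / (c + KD)
            assert abs(w[c] - p) < 4 * np.sqrt(p * (1 - p) / 600) + 0.02
        assert sat is not None
        assert sat.params["K_D"] == pytest.approx(KD, rel=0.5)

    def test_all_single_exponential_yields_note(self, rng):
        fits = {c: da.fit_exp_mixture(rng.exponential(3.0, 200), rng=1)
                for c in (0.0, 1e-8, 1e-7, 1e-6)}
        with pytest.warns(UserWarning, match="single-exponential"):
            table, sat = da.occupancy_vs_concentration(fits)
        assert (table.long_component_weight == 0).all()
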