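"""Ramp pipeline: segmentation, detection, selection, normalization."""

import numpy as np
import pandas as pd
import pytest

from riboforce import ramp_analysis as ra
from riboforce import synthetic_data as sd
from riboforce.trace_model import ConditionLabel, Ligand, Trace


def _step_trace(step_force=8.0, step_size=15.0, n_cycles=1, noise=0.0, rng=None):
    """Noise-controlled ramp trace with one planted unfolding step per cycle."""
    model = sd.KineticModel(k_unfold0=0.0, k_fold0=0.0)
    proto = sd.ProtocolParams(n_cycles=n_cycles, noise_sd=noise)
    tr, _ = sd.simulate_ramp_trace(model, proto, 0.0, rng=rng if rng is not None else 0)
    half = len(tr) // (2 * n_cycles)
    for c in range(n_cycles):
        up = slice(2 * c * half, (2 * c + 1) * half)
        mask = np.zeros(len(tr), dtype=bool)
        mask[up] = tr.force[up] >= step_force
        tr.extension[mask] += step_size
    return tr


class TestSegmentation:
    def test_fifty_cycle_protocol_yields_fifty_cycles(self, control_ramp_trace):
        tr, _ = control_ramp_trace
        cycles = ra.segment_cycles(tr)
        assert len(cycles) == 50

    def test_boundaries_within_one_sample_of_protocol(self, control_ramp_trace):
        tr, _ = control_ramp_trace
        cycles = ra.segment_cycles(tr)
        n_half = len(tr) // 100  # 50 cycles, two phases each
        for i, c in enumerate(cycles):
            assert abs(c.up_slice.start - 2 * i * n_half) <= 1
            assert abs(c.up_slice.stop - 1 - (2 * i + 1) * n_half) <= 1

    def test_truncated_final_half_cycle_is_flagged(self, control_model):
        proto = sd.ProtocolParams(n_cycles=5)
        tr, _ = sd.simulate_ramp_trace(control_model, proto, 0.0, rng=5)
        cut = tr.slice(slice(0, len(tr) - len(tr) // 10 - len(tr) // 20))
        with pytest.warns(UserWarning, match="incomplete"):
            cycles = ra.segment_cycles(cut)
        assert len(cycles) == 4

    def test_flat_force_gives_empty_list_with_warning(self):
        tr = Trace("b", ConditionLabel(), np.arange(100) / 30.0,
                   np.zeros(100), np.full(100, 5.0), 30.0)
        with pytest.warns(UserWarning):
            assert ra.segment_cycles(tr) == []


class TestDetection:
    @pytest.mark.parametrize("method", ["cluster", "changepoint"])
    def test_noiseless_step_detected_exactly(self, method):
        tr = _step_trace(step_force=8.0, step_size=15.0)
        events = ra.detect_events(tr, method=method)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction.value == "unfold"
        assert ev.force == pytest.approx(8.0, abs=2.0 / 30.0)  # sample resolution
        assert ev.size == pytest.approx(15.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["cluster", "changepoint"])
    def test_pure_noise_phase_yields_no_events(self, method):
        model = sd.KineticModel(k_unfold0=0.0, k_fold0=0.0)
        proto = sd.ProtocolParams(n_cycles=1, noise_sd=3.0)
        tr, _ = sd.simulate_ramp_trace(model, proto, 0.0, rng=1)
        assert ra.detect_events(tr, method=method) == []

    def test_sub_threshold_jump_ignored(self):
        tr = _step_trace(step_size=3.0)  # below the 5 nm minimum
        assert ra.detect_events(tr) == []

    def test_cluster_matches_changepoint_oracle_on_noisy_cycles(self, control_ramp_trace):
        """The two independent detectors must agree on force and size."""
        tr, _ = control_ramp_trace
        cycles = ra.segment_cycles(tr)
        by_key = lambda evs: {(e.cycle_index, e.direction.value): e for e in evs}
        cl = by_key(ra.detect_events(tr, cycles, method="cluster"))
        cp = by_key(ra.detect_events(tr, cycles, method="changepoint"))
        common = set(cl) & set(cp)
        assert len(common) >= 50
        agree = sum(
            abs(cl[k].force - cp[k].force) <= 0.5 and abs(cl[k].size - cp[k].size) <= 2.0
            for k in common
        )
        assert agree / len(common) >= 0.9

    def test_multi_event_mode_reports_flickers(self):
        tr = _step_trace(step_force=6.0, step_size=15.0)
        # plant a second, larger step higher up the same ramp
        up = slice(0, len(tr) // 2)
        mask = np.zeros(len(tr), dtype=bool)
        mask[up] = tr.force[up] >= 15.0
        tr.extension[mask] += 8.0
        single = ra.detect_events(tr)
        multi = ra.detect_events(tr, multi_event=True)
        assert len(single) == 1
        assert len(multi) == 2


class TestQC:
    def test_nominal_noise_passes_and_inflated_noise_fails(self, control_model):
        proto = sd.ProtocolParams(n_cycles=10)
        tr, _ = sd.simulate_ramp_trace(control_model, proto, 0.0, rng=2)
        assert ra.qc_brownian(tr).passed
        loud = sd.ProtocolParams(n_cycles=10, noise_sd=15.0)
        tr2, _ = sd.simulate_ramp_trace(control_model, loud, 0.0, rng=2)
        assert not ra.qc_brownian(tr2).passed

    def test_trace_shorter_than_window_errors(self):
        tr = Trace("b", ConditionLabel(), np.arange(10) / 30.0,
                   np.zeros(10), np.ones(10), 30.0)
        with pytest.raises(ValueError):
            ra.qc_brownian(tr)


class TestStatsAndSelection:
    def _toy_cycles(self):
        rows = []
        for b, (n, n_unf, f, s) in {
            "good": (30, 27, 9.0, 16.0),
            "few_cycles": (10, 10, 9.0, 16.0),
            "weak": (30, 30, 3.0, 16.0),
            "tiny_step": (30, 30, 9.0, 6.0),
            "boundary80": (30, 24, 9.0, 16.0),  # exactly 80% unfold
        }.items():
            for i in range(n):
                has = i < n_unf
                rows.append(
                    {"bead_id": b, "ligand": "control", "concentration": 0.0,
                     "cycle_index": i,
                     "unfold_force": f + 0.01 * i if has else np.nan,
                     "unfold_size": s if has else np.nan,
                     "refold_force": 0.7 * f if has else np.nan,
                     "refold_size": s if has else np.nan}
                )
                rows.append(
                    {"bead_id": b, "ligand": "compound4", "concentration": 1e-4,
                     "cycle_index": i,
                     "unfold_force": f + 0.5 if has else np.nan,
                     "unfold_size": s if has else np.nan,
                     "refold_force": 0.7 * f + 0.5 if has else np.nan,
                     "refold_size": s if has else np.nan}
                )
        return pd.DataFrame(rows)

    def test_stats_match_brute_force_recomputation(self):
        df = self._toy_cycles()
        stats = ra.structure_stats(df)
        g = df[(df.bead_id == "good") & (df.ligand == "control")]
        row = stats[(stats.bead_id == "good") & (stats.ligand == "control")].iloc[0]
        assert row.n_cycles_analyzable == len(g)
        assert row.n_cycles_with_unfold == g.unfold_force.notna().sum()
        assert row.unfold_fraction == pytest.approx(27 / 30)
        assert row.median_unfold_force == pytest.approx(g.unfold_force.median())

    def test_selection_classifies_planted_labels_exactly(self):
        stats = ra.structure_stats(self._toy_cycles())
        verdicts = ra.select_structures(stats).set_index("bead_id")
        assert bool(verdicts.loc["good", "selected"])
        assert not verdicts.loc["few_cycles", "enough_cycles"]
        assert not verdicts.loc["weak", "force_in_window"]
        assert not verdicts.loc["tiny_step", "size_in_window"]
        # strict >80%: a bead at exactly 80% is rejected
        assert not verdicts.loc["boundary80", "unfold_fraction_ok"]

    def test_missing_control_condition_errors(self):
        df = self._toy_cycles()
        df = df[df.ligand != "control"]
        with pytest.raises(ValueError):
            ra.select_structures(ra.structure_stats(df))


class TestNormalization:
    def test_control_normalized_median_is_one(self):
        df = TestStatsAndSelection()._toy_cycles()
        stats = ra.structure_stats(df)
        norm = ra.normalize_forces(df, stats)
        for bead, g in norm[norm.ligand == "control"].groupby("bead_id"):
            assert g["norm_unfold_force"].median() == pytest.approx(1.0)
            assert g["norm_refold_force"].median() == pytest.approx(1.0)

    def test_round_trip_denormalization_is_identity(self):
        df = TestStatsAndSelection()._toy_cycles()
        stats = ra.structure_stats(df)
        norm = ra.normalize_forces(df, stats)
        ctrl = stats[stats.ligand == "control"].set_index("bead_id")
        back = norm["norm_unfold_force"] * norm["bead_id"].map(ctrl["median_unfold_force"])
        mask = norm["unfold_force"].notna()
        np.testing.assert_allclose(back[mask], norm.loc[mask, "unfold_force"], rtol=1e-12)

    def test_bead_without_control_dropped_with_warning(self):
        df = TestStatsAndSelection()._toy_cycles()
        orphan = df[df.bead_id == "good"].assign(bead_id="orphan")
        orphan = orphan[orphan.ligand != "control"]
        stats = ra.structure_stats(pd.concat([df, orphan]))
        with pytest.warns(UserWarning, match="control"):
            norm = ra.normalize_forces(pd.concat([df, orphan]), stats)
        assert "orphan" not in set(norm.bead_id)


class TestHighForceFraction:
    def _norm_cycles(self, rng, n_ctrl=500, p_pk=0.0, n_treat=500):
        rows = []
        ctrl = rng.normal(1.0, 0.1, n_ctrl)
        for i, f in enumerate(ctrl):
            rows.append({"bead_id": f"b{i % 10}", "ligand": "control",
                         "concentration": 0.0, "norm_unfold_force": f})
        for i in range(n_treat):
            if rng.random() < p_pk:
                f = np.nan if rng.random() < 0.5 else rng.normal(2.0, 0.1)
            else:
                f = rng.normal(1.0, 0.1)
            rows.append({"bead_id": f"b{i % 10}", "ligand": "preq1",
                         "concentration": 5e-7, "norm_unfold_force": f})
        return pd.DataFrame(rows)

    def test_control_fraction_is_five_percent_by_construction(self, rng):
        df = self._norm_cycles(rng)
        table, thr = ra.high_force_fraction(df)
        ctrl = table[table.ligand == "control"].iloc[0]
        assert ctrl.fraction_high_force == pytest.approx(0.05, abs=0.01)

    def test_planted_pseudoknot_fraction_recovered(self, rng):
        """p of cycles go high-force/no-unfold; the rest keep the base 5%."""
        p = 0.4
        df = self._norm_cycles(rng, p_pk=p, n_treat=1000)
        table, thr = ra.high_force_fraction(df)
        treat = table[table.ligand == "preq1"].iloc[0]
        expected = p + 0.05 * (1 - p)
        # binomial error over 1000 cycles
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(treat.fraction_high_force - expected) < 4 * se

    def test_invariant_under_monotone_force_rescaling(self, rng):
        df = self._norm_cycles(rng, p_pk=0.3)
        t1, _ = ra.high_force_fraction(df)
        df2 = df.assign(norm_unfold_force=np.exp(df.norm_unfold_force * 2.0))
        t2, _ = ra.high_force_fraction(df2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_needs_twenty_control_events(self, rng):
        df = self._norm_cycles(rng, n_ctrl=10, n_treat=10)
        with pytest.raises(ValueError):
            ra.high_force_fraction(df)


class TestPeakMedian:
    def test_unimodal_equals_median_closely(self, rng):
        v = rng.normal(1.0, 0.1, 2000)
        assert ra.peak_median(v) == pytest.approx(np.median(v), abs=0.02)

    def test_tracks_dominant_mode_not_pooled_median(self, rng):
        v = np.concatenate([rng.normal(1.0, 0.05, 1500), rng.normal(2.0, 0.05, 500)])
        assert ra.peak_median(v) == pytest.approx(1.0, abs=0.05)
        assert np.median(v) > ra.peak_median(v)
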