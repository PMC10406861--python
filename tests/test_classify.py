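import dataclasses

import numpy as np
import pandas as pd
import pytest

from nucswap.classify import (ClassificationRules, QCThresholds,
                              TraceClassifier, build_histograms,
                              classify_molecule, compute_census,
                              detect_bleach_steps, qc_filter,
                              verify_red_excitation)
from nucswap.correction import CorrectedTrace, LeakageFactors, correct_trace
from nucswap.simulate import TraceSimulationParams, synthesize_trace


def _manual_corrected(i3, i5, i55, dt=0.2, noise_sd=0.0):
    """Build a CorrectedTrace directly from corrected green-phase series."""
    n = len(i3)
    f5 = np.where(i3 + i5 + i55 > 0, i5 / np.maximum(i3 + i5 + i55, 1e-12), np.nan)
    f55 = np.where(i3 + i5 + i55 > 0, i55 / np.maximum(i3 + i5 + i55, 1e-12), np.nan)
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) * dt,
            "phase": "green",
            "i_cy3": i3, "i_cy5": i5, "i_cy55": i55,
            "fret_cy5": f5, "fret_cy55": f55,
            "undefined_flag": ~np.isfinite(f5),
        }
    )
    bg = {"cy3": 0.0, "cy5": 0.0, "cy55": 0.0,
          "noise_sd": {"cy3": noise_sd, "cy5": noise_sd, "cy55": noise_sd},
          "n_frames": 25}
    return CorrectedTrace(frames=df, background=bg, leakage=LeakageFactors())


class TestBleachDetection:
    def test_step_located_within_one_frame_at_snr_ten(self, rng):
        n, step, level, sd = 300, 120, 200.0, 20.0  # SNR 10
        y = np.where(np.arange(n) < step, level, 0.0) + rng.normal(0, sd, n)
        tr = _manual_corrected(np.zeros(n), y, np.zeros(n), noise_sd=sd)
        steps = detect_bleach_steps(tr)
        assert abs(steps["cy5"].frame - step) <= 1
        assert not steps["cy5"].multi_step

    def test_flat_trace_has_no_step(self, rng):
        n = 200
        y = rng.normal(100.0, 10.0, n)
        tr = _manual_corrected(np.zeros(n), y, np.zeros(n), noise_sd=10.0)
        assert detect_bleach_steps(tr)["cy5"].frame is None

    def test_two_step_aggregate_flagged_multi_step(self, rng):
        n = 300
        y = np.where(np.arange(n) < 100, 400.0,
                     np.where(np.arange(n) < 200, 200.0, 0.0))
        y = y + rng.normal(0, 10.0, n)
        tr = _manual_corrected(np.zeros(n), y, np.zeros(n), noise_sd=10.0)
        st = detect_bleach_steps(tr)["cy5"]
        assert st.multi_step

    def test_short_trace_rejected(self):
        tr = _manual_corrected(np.zeros(10), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            detect_bleach_steps(tr)


class TestQC:
    def _trace_with_bleach(self, bleach_s, rng, sd=15.0):
        n = 300
        level = 150.0
        y = np.where(np.arange(n) * 0.2 < bleach_s, level, 0.0)
        y = y + rng.normal(0, sd, n)
        i3 = np.full(n, 100.0) + rng.normal(0, sd, n)
        return _manual_corrected(i3, y, np.zeros(n) + rng.normal(0, sd, n),
                                 noise_sd=sd)

    def test_short_lifetime_fails(self, rng):
        tr = self._trace_with_bleach(8.0, rng)
        res = qc_filter(tr)
        assert not res.passed and "lifetime" in res.reasons

    def test_low_snr_fails(self, rng):
        n = 300
        sd = 50.0  # brightest channel at 150 -> SNR 3
        y = np.where(np.arange(n) < 150, 150.0, 0.0) + rng.normal(0, sd, n)
        i3 = np.full(n, 100.0) + rng.normal(0, sd, n)
        tr = _manual_corrected(i3, y, rng.normal(0, sd, n), noise_sd=sd)
        res = qc_filter(tr)
        assert not res.passed and "snr" in res.reasons

    def test_clean_trace_passes(self, rng):
        tr = self._trace_with_bleach(30.0, rng)
        res = qc_filter(tr)
        assert res.passed and res.reasons == []
        assert res.lifetime_s > 10 and res.snr > 4

    def test_nonzero_post_bleach_residual_fails(self, rng):
        n = 300
        sd = 10.0
        y = np.where(np.arange(n) < 150, 300.0, 80.0) + rng.normal(0, sd, n)
        i3 = np.full(n, 100.0) + rng.normal(0, sd, n)
        tr = _manual_corrected(i3, y, rng.normal(0, sd, n), noise_sd=sd)
        res = qc_filter(tr)
        assert not res.passed and "residual" in res.reasons

    def test_stricter_thresholds_never_pass_more(self, default_params):
        rng = np.random.default_rng(8)
        traces = [
            correct_trace(synthesize_trace(cls, default_params, rng))
            for cls in ("intact", "distal_exchanged") for _ in range(15)
        ]
        lax = QCThresholds(min_lifetime=5.0, min_snr=2.0)
        strict = QCThresholds(min_lifetime=20.0, min_snr=8.0)
        n_lax = sum(qc_filter(t, lax).passed for t in traces)
        n_strict = sum(qc_filter(t, strict).passed for t in traces)
        assert n_strict <= n_lax


class TestRedExcitation:
    def test_acceptor_statuses(self, ideal_params):
        distal = correct_trace(synthesize_trace("distal_exchanged", ideal_params, 1))
        assert verify_red_excitation(distal).status == "both_present"
        intact = correct_trace(synthesize_trace("intact", ideal_params, 1))
        assert verify_red_excitation(intact).status == "cy5_present"

    def test_fully_bleached_acceptors(self):
        params = TraceSimulationParams(
            noise_sd=0.0,
            bleach_lifetime={"cy3": np.inf, "cy5": 0.4, "cy55": 0.2},
        )
        tr = synthesize_trace("distal_exchanged", params, 2)
        # force deterministic early acceptor bleaching via tiny lifetimes;
        # retry seeds until both acceptors die inside the green phase
        for seed in range(10):
            tr = synthesize_trace("distal_exchanged", params, seed)
            bf = tr.meta["true_bleach_frames"]
            if bf["cy5"] < 250 and bf["cy55"] < 250:
                break
        corr = correct_trace(tr)
        assert verify_red_excitation(corr).status == "bleached"

    def test_missing_red_phase_is_unknown(self, ideal_params):
        params = dataclasses.replace(ideal_params, n_frames_red=0)
        corr = correct_trace(synthesize_trace("intact", params, 1))
        assert verify_red_excitation(corr).status == "unknown"


class TestClassification:
    @pytest.mark.parametrize(
        "cls", ["intact", "proximal_exchanged", "distal_exchanged"]
    )
    def test_signature_classes_recovered_noiselessly(self, cls, ideal_params):
        corr = correct_trace(synthesize_trace(cls, ideal_params, 3))
        assert classify_molecule(corr) == cls

    def test_noisy_signatures_recovered(self, default_params):
        params = dataclasses.replace(
            default_params,
            bleach_lifetime={"cy3": np.inf, "cy5": np.inf, "cy55": 1e30},
        )
        rng = np.random.default_rng(17)
        for cls in ("intact", "proximal_exchanged", "distal_exchanged"):
            labels = [
                classify_molecule(correct_trace(synthesize_trace(cls, params, rng)))
                for _ in range(10)
            ]
            assert labels.count(cls) == 10

    def test_unmatched_signature_is_ambiguous(self):
        n = 300
        # mid-level FRET_cy5 with zero FRET_cy5.5 matches no rule window
        i3, i5, i55 = np.full(n, 400.0), np.full(n, 100.0), np.zeros(n)
        tr = _manual_corrected(i3, i5, i55)
        assert classify_molecule(tr) == "ambiguous"

    def test_classifier_estimator(self, ideal_params):
        traces = [
            correct_trace(synthesize_trace(c, ideal_params, i))
            for i, c in enumerate(
                ["intact", "distal_exchanged", "proximal_exchanged"]
            )
        ]
        clf = TraceClassifier().fit()
        labels = clf.predict(traces)
        assert list(labels) == ["intact", "distal_exchanged", "proximal_exchanged"]
        table = clf.analyze(traces)
        assert table["qc_pass"].all()
        assert list(table["class"]) == list(labels)

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            ClassificationRules(theta_55=0.0)
        with pytest.raises(ValueError):
            ClassificationRules(m_frames=0)


class TestHistograms:
    def test_noiseless_intact_mass_in_expected_bins(self, ideal_params):
        traces = [correct_trace(synthesize_trace("intact", ideal_params, i))
                  for i in range(20)]
        h = build_histograms(traces)
        df = h.to_frame()
        peak5 = df.loc[df["count_fret_cy5"].idxmax()]
        assert peak5["bin_left"] <= 0.6 <= peak5["bin_right"]
        assert df["count_fret_cy5"].sum() == peak5["count_fret_cy5"]
        assert h.counts_fret_cy55[0] == h.counts_fret_cy55.sum()

    def test_mixture_is_bimodal_with_cy55_mass(self, ideal_params):
        traces = [correct_trace(synthesize_trace("intact", ideal_params, i))
                  for i in range(10)]
        traces += [
            correct_trace(synthesize_trace("distal_exchanged", ideal_params, i))
            for i in range(10)
        ]
        h = build_histograms(traces)
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
        occupied5 = centers[h.counts_fret_cy5 > 0]
        assert any(abs(occupied5 - 0.6) < 0.011) and any(abs(occupied5 - 0.35) < 0.011)
        assert h.counts_fret_cy55[(centers > 0.25) & (centers < 0.35)].sum() > 0

    def test_count_conservation(self, ideal_params):
        traces = [correct_trace(synthesize_trace("intact", ideal_params, i))
                  for i in range(5)]
        n_defined = sum((~t.frames["undefined_flag"]).sum() for t in traces)
        h = build_histograms(traces)
        assert h.counts_fret_cy5.sum() == n_defined

    def test_empty_input(self):
        h = build_histograms([])
        assert h.counts_fret_cy5.sum() == 0


class TestCensus:
    @staticmethod
    def _table(n_per_class, t_h=1.0, rep=0):
        rows = []
        for cls, n in n_per_class.items():
            rows += [{"timepoint_h": t_h, "replicate": rep, "class": cls,
                      "qc_pass": True}] * n
        return pd.DataFrame(rows)

    def test_basic_fraction(self):
        tc = compute_census(self._table({"intact": 80, "distal_exchanged": 20}))
        assert tc.summary["fraction"].iloc[0] == pytest.approx(0.2)
        assert tc.summary["n_qualifying"].iloc[0] == 100

    def test_zero_distal_everywhere(self):
        tc = compute_census(self._table({"intact": 50}))
        assert (tc.summary["fraction"] == 0).all()

    def test_denominator_conventions(self):
        table = self._table(
            {"intact": 60, "proximal_exchanged": 20, "distal_exchanged": 20}
        )
        all_conv = compute_census(table, denominator="all")
        no_prox = compute_census(table, denominator="intact_distal")
        assert all_conv.summary["fraction"].iloc[0] == pytest.approx(0.2)
        assert no_prox.summary["fraction"].iloc[0] == pytest.approx(0.25)
        with pytest.raises(ValueError):
            compute_census(table, denominator="bogus")

    def test_ambiguous_and_qc_failures_excluded(self):
        table = self._table({"intact": 50, "distal_exchanged": 10, "ambiguous": 40})
        fail = self._table({"distal_exchanged": 30})
        fail["qc_pass"] = False
        tc = compute_census(pd.concat([table, fail], ignore_index=True))
        assert tc.summary["n_qualifying"].iloc[0] == 60
        assert tc.summary["fraction"].iloc[0] == pytest.approx(10 / 60)

    def test_order_and_replicate_relabeling_invariance(self, rng):
        parts = []
        for rep, nd in [(0, 10), (1, 14), (2, 6)]:
            parts.append(self._table({"intact": 40, "distal_exchanged": nd},
                                     t_h=2.0, rep=rep))
        table = pd.concat(parts, ignore_index=True)
        base = compute_census(table)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.copy()
        relabeled["replicate"] = relabeled["replicate"].map({0: 7, 1: 5, 2: 9})
        for variant in (shuffled, relabeled):
            tc = compute_census(variant)
            assert tc.summary["fraction"].iloc[0] == pytest.approx(
                base.summary["fraction"].iloc[0]
            )
            assert tc.summary["sd"].iloc[0] == pytest.approx(
                base.summary["sd"].iloc[0]
            )

    def test_replicate_sd_undefined_for_single_replicate(self):
        tc = compute_census(self._table({"intact": 10, "distal_exchanged": 2}))
        assert np.isnan(tc.summary["sd"].iloc[0])
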