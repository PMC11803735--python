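"""Leak QC, amplitudes, rundown correction, percent block, and LC50 fitting."""

import numpy as np
import pandas as pd
import pytest

from strobescreen.pharmacology import (
    EphysTrace,
    aggregate_block,
    epoch_amplitude,
    fit_lc50,
    leak_qc,
    percent_block,
    rundown_fraction,
    well_mortality,
)
from strobescreen.synthetic_data import gen_ephys_trace, gen_mortality


def _flat_trace(levels, epoch_s=5.0, fs=10.0, oocyte="o1"):
    """Piecewise-flat current trace; ``levels`` maps epoch label -> nA."""
    labels = list(levels)
    n = int(epoch_s * fs)
    current = np.concatenate([np.full(n, v) for v in levels.values()])
    time = np.arange(current.size) / fs
    epochs = {lab: (i * epoch_s, (i + 1) * epoch_s) for i, lab in enumerate(labels)}
    return EphysTrace(time, current, fs, epochs, oocyte_id=oocyte)


class TestLeakQC:
    def test_modest_leak_passes(self):
        assert leak_qc(_flat_trace({"baseline": -50.0}))

    def test_excessive_leak_fails(self):
        assert not leak_qc(_flat_trace({"baseline": -1500.0}))

    def test_boundary_exactly_minus_1000_passes(self):
        assert leak_qc(_flat_trace({"baseline": -1000.0}))

    def test_missing_baseline_epoch_rejected(self):
        tr = _flat_trace({"gaba_only_pre": -100.0})
        with pytest.raises(KeyError, match="baseline"):
            leak_qc(tr)


class TestEpochAmplitude:
    def test_flat_epoch_zero_baseline(self):
        tr = _flat_trace({"baseline": 0.0, "gaba_only_pre": -100.0})
        assert epoch_amplitude(tr, "gaba_only_pre") == pytest.approx(100.0)

    def test_baseline_subtraction(self):
        tr = _flat_trace({"baseline": -10.0, "gaba_only_pre": -110.0})
        assert epoch_amplitude(tr, "gaba_only_pre") == pytest.approx(100.0)

    def test_short_epoch_rejected(self):
        tr = _flat_trace({"baseline": 0.0, "gaba_only_pre": -50.0}, epoch_s=0.5)
        with pytest.raises(ValueError, match="shorter"):
            epoch_amplitude(tr, "gaba_only_pre")

    def test_noisy_planted_amplitude_recovered(self):
        for seed in range(5):
            tr = gen_ephys_trace(i_gaba_na=400.0, rundown_frac=0.0, block_frac=0.0,
                                 noise_sd=2.0, seed=seed)
            got = epoch_amplitude(tr, "gaba_only_pre")
            assert got == pytest.approx(400.0, abs=3 * 2.0)


class TestRundown:
    def test_no_rundown(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -100.0,
             "gaba_only_post": -100.0}
        )
        assert rundown_fraction([tr]) == 0.0

    def test_hand_value(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -95.0,
             "gaba_only_post": -90.0}
        )
        assert rundown_fraction([tr]) == pytest.approx(0.10)

    def test_floored_at_zero_when_post_exceeds_pre(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -90.0, "coapplication": -95.0,
             "gaba_only_post": -100.0}
        )
        assert rundown_fraction([tr]) == 0.0

    def test_zero_early_amplitude_rejected(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": 0.0, "gaba_only_post": -10.0}
        )
        with pytest.raises(ValueError, match="zero pre"):
            rundown_fraction([tr])


class TestPercentBlock:
    def test_null_compound_zero_block(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -100.0}
        )
        assert percent_block(tr, 0.0) == 0.0

    def test_full_block_hundred(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": 0.0}
        )
        assert percent_block(tr, 0.0) == 100.0

    def test_hand_value_with_rundown(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -40.0}
        )
        assert percent_block(tr, 0.10) == pytest.approx(100 * (1 - 0.4 / 0.9))

    def test_antitone_in_coapplication_amplitude(self):
        blocks = []
        for coapp in (-90.0, -60.0, -30.0, -5.0):
            tr = _flat_trace(
                {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": coapp}
            )
            blocks.append(percent_block(tr, 0.05))
        assert blocks == sorted(blocks)

    def test_crediting_more_rundown_lowers_the_block_estimate(self):
        # current lost to desensitization must not be attributed to the compound
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -50.0}
        )
        vals = [percent_block(tr, r) for r in (0.0, 0.1, 0.2)]
        assert vals == sorted(vals, reverse=True)

    def test_failing_leak_qc_rejected(self):
        tr = _flat_trace(
            {"baseline": -2000.0, "gaba_only_pre": -2100.0, "coapplication": -2050.0}
        )
        with pytest.raises(ValueError, match="leak"):
            percent_block(tr, 0.0)

    def test_subtractive_mode_available(self):
        tr = _flat_trace(
            {"baseline": 0.0, "gaba_only_pre": -100.0, "coapplication": -40.0}
        )
        assert percent_block(tr, 0.10, mode="subtract") == pytest.approx(50.0)


class TestAggregateBlock:
    def test_zero_spread(self):
        (res,) = aggregate_block({"c1": [50.0, 50.0, 50.0]})
        assert res.mean == 50.0 and res.sem == 0.0

    def test_closed_form_sem(self):
        with pytest.warns(UserWarning, match="design range"):
            (res,) = aggregate_block({"c1": [40.0, 60.0]})
        assert res.mean == 50.0 and res.sem == pytest.approx(10.0)

    def test_single_oocyte_sem_missing(self):
        with pytest.warns(UserWarning):
            (res,) = aggregate_block({"c1": [42.0]})
        assert res.sem is None and res.n == 1


class TestWellMortality:
    def test_all_dead(self):
        assert well_mortality([True, True, True])

    def test_one_survivor_vetoes(self):
        assert not well_mortality([True, True, False])

    def test_empty_well_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            well_mortality([])

    def test_high_dose_wells_nearly_all_dead(self):
        tab = gen_mortality([200.0], lc50=8.6, slope=4, n_reps=50, seed=0)
        assert tab["well_dead"].mean() > 0.95


class TestFitLC50:
    def test_log_symmetric_design_forces_midpoint(self):
        rows = []
        for dose, n_dead in [(1.0, 0), (10.0, 6), (100.0, 12)]:
            for i in range(12):
                rows.append({"dose_ug_per_well": dose, "well_id": f"{dose}_{i}",
                             "well_dead": i < n_dead})
        fit = fit_lc50(pd.DataFrame(rows))
        assert fit.lc50 == pytest.approx(10.0, rel=1e-3)

    def test_all_alive_flags_non_convergence(self):
        tab = gen_mortality([2, 4, 8], lc50=np.inf, slope=4, seed=0)
        fit = fit_lc50(tab)
        assert not fit.converged and np.isnan(fit.lc50)

    def test_scale_equivariance(self):
        tab = gen_mortality([2, 2.83, 4, 5.66, 8, 11.3, 16], 8.6, 4, seed=1)
        f1 = fit_lc50(tab)
        tab2 = tab.copy()
        tab2["dose_ug_per_well"] *= 3.7
        f2 = fit_lc50(tab2)
        assert f2.lc50 == pytest.approx(3.7 * f1.lc50, rel=1e-6)

    def test_ci_brackets_estimate(self):
        tab = gen_mortality([2, 2.83, 4, 5.66, 8, 11.3, 16], 8.6, 4, seed=2)
        fit = fit_lc50(tab)
        assert fit.ci_low < fit.lc50 < fit.ci_high

    def test_loglik_at_fit_beats_truth(self):
        """MLE sanity: fitted parameters never score below the generating ones."""
        from scipy.special import expit

        tab = gen_mortality([2, 2.83, 4, 5.66, 8, 11.3, 16], 8.6, 4, seed=3)
        fit = fit_lc50(tab)
        p = expit(4.0 * (np.log(tab["dose_ug_per_well"]) - np.log(8.6)))
        p_well = np.clip(p ** tab["n_larvae"], 1e-12, 1 - 1e-12)
        y = tab["well_dead"].astype(float)
        ll_truth = float((y * np.log(p_well) + (1 - y) * np.log(1 - p_well)).sum())
        assert fit.loglik >= ll_truth - 1e-6

    def test_matches_logistic_regression_when_one_larva_per_well(self):
        """Independent oracle: with one larva per well the model is plain
        logistic regression on log dose (cross-checked against sklearn)."""
        from sklearn.linear_model import LogisticRegression

        tab = gen_mortality([2, 2.83, 4, 5.66, 8, 11.3, 16], 8.6, 4,
                            n_reps=40, larvae_per_well=(1, 1), seed=4)
        fit = fit_lc50(tab)
        X = np.log(tab["dose_ug_per_well"].to_numpy()).reshape(-1, 1)
        y = tab["well_dead"].astype(int).to_numpy()
        lr = LogisticRegression(penalty=None, tol=1e-10, max_iter=10000).fit(X, y)
        lc50_lr = float(np.exp(-lr.intercept_[0] / lr.coef_[0][0]))
        assert fit.lc50 == pytest.approx(lc50_lr, rel=1e-3)

    def test_single_dose_rejected(self):
        tab = gen_mortality([8.0], lc50=8.6, slope=4, seed=0)
        with pytest.raises(ValueError, match="distinct doses"):
            fit_lc50(tab)
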