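"""Parameter estimation: recovery, uncertainty, AIC and the two-stage run."""

import dataclasses

import numpy as np
import pytest

from petkin import (
    KineticParameters,
    ModelSpec,
    TissueTAC,
    UnreliableK4Error,
    WeightScheme,
    compute_aic,
    default_schedule,
    fit_tac,
    frame_average,
    percent_se,
    run_dual_stage,
    select_model,
    simulate_tissue_curve,
)
from petkin.fitting import FitResult

from conftest import WHOLE_BRAIN_ROWS


def _clean_tac(params, inputs, schedule, roi="roi"):
    t = np.arange(0.0, schedule.total_span_s / 60.0 + 1e-9, 1.0 / 120.0)
    curve = simulate_tissue_curve(params, inputs, t)
    tac = frame_average(curve, schedule)
    return TissueTAC(roi, schedule, tac.activity)


def _noisy(tac, sigma, rng):
    return TissueTAC(tac.roi_label, tac.schedule,
                     tac.activity + sigma * rng.standard_normal(tac.activity.size))


@pytest.fixture(scope="module")
def gm_tac(true_inputs, gm_rrms_params, schedule):
    return _clean_tac(gm_rrms_params, true_inputs, schedule, "whole_brain_GM")


# ---------------------------------------------------------------------------
# fit_tac
# ---------------------------------------------------------------------------

class TestFitTac:
    @pytest.mark.parametrize("row", list(WHOLE_BRAIN_ROWS), ids=lambda r: "_".join(r))
    def test_noiseless_recovery_of_published_rows(self, row, true_inputs, schedule):
        """Free five-parameter fits of noiseless self-simulated TACs recover
        every generating whole-brain parameter within 1%."""
        true = KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[row])
        tac = _clean_tac(true, true_inputs, schedule)
        fit = fit_tac(tac, true_inputs, ModelSpec("2T4k", include_vb=True))
        for name in ("K1", "k2", "k3", "k4", "VB"):
            est = getattr(fit.estimates, name)
            assert est == pytest.approx(getattr(true, name), rel=0.01), name

    def test_pure_blood_signal_yields_zero_delivery(self, true_inputs, schedule):
        wb = TissueTAC("blood", schedule,
                       0.05 * frame_average(true_inputs.whole_blood, schedule).activity)
        fit = fit_tac(wb, true_inputs, ModelSpec("2T4k", include_vb=True))
        assert fit.estimates.K1 <= 1e-4
        assert fit.estimates.VB == pytest.approx(0.05, rel=1e-3)

    def test_fixing_k4_at_truth_matches_free_fit(self, gm_tac, true_inputs,
                                                 gm_rrms_params):
        free = fit_tac(gm_tac, true_inputs, ModelSpec("2T4k", include_vb=True))
        fixed = fit_tac(gm_tac, true_inputs,
                        ModelSpec("2T4k", include_vb=True,
                                  fixed_params={"k4": gm_rrms_params.k4}))
        for name in ("K1", "k2", "k3", "VB"):
            assert getattr(fixed.estimates, name) == pytest.approx(
                getattr(free.estimates, name), rel=1e-3), name

    def test_reported_fit_is_best_of_starts(self, gm_tac, true_inputs):
        """More multistart points can only improve (or tie) the objective."""
        few = fit_tac(gm_tac, true_inputs, ModelSpec("2T4k"), n_starts=3, seed=0)
        many = fit_tac(gm_tac, true_inputs, ModelSpec("2T4k"), n_starts=10, seed=0)
        assert many.rss <= few.rss + 1e-12

    def test_weight_rescaling_leaves_aic_ordering_invariant(self, gm_tac,
                                                            true_inputs):
        rng = np.random.default_rng(4)
        noisy = _noisy(gm_tac, 0.05, rng)
        w = WeightScheme("frame").weights(noisy.schedule)
        tac1 = TissueTAC(noisy.roi_label, noisy.schedule, noisy.activity, w)
        tac2 = TissueTAC(noisy.roi_label, noisy.schedule, noisy.activity, 7.3 * w)
        for spec in (ModelSpec("1T2k"), ModelSpec("2T4k")):
            f1 = fit_tac(tac1, true_inputs, spec)
            f2 = fit_tac(tac2, true_inputs, spec)
            assert f1.aic == pytest.approx(f2.aic, rel=1e-9)


# ---------------------------------------------------------------------------
# AIC
# ---------------------------------------------------------------------------

class TestAic:
    def _fit_stub(self, rss, n, p):
        sched = default_schedule()
        tac = TissueTAC("x", sched, np.zeros(sched.n_frames))
        return FitResult(
            estimates=KineticParameters("1T2k", K1=0.1, k2=0.5),
            model_label="1T2k", free_names=("K1", "k2"), se={}, percent_se={},
            rss=rss, n_frames=n, n_free=p, aic=np.nan, fitted_tac=tac,
            converged=True,
            macro=None)

    def test_extra_parameter_at_equal_rss_costs_two(self):
        a = compute_aic(self._fit_stub(1.0, 22, 4))
        b = compute_aic(self._fit_stub(1.0, 22, 5))
        assert b - a == pytest.approx(2.0)

    def test_halving_rss_drops_aic_by_n_ln2(self):
        a = compute_aic(self._fit_stub(2.0, 22, 4))
        b = compute_aic(self._fit_stub(1.0, 22, 4))
        assert a - b == pytest.approx(22 * np.log(2.0))

    def test_zero_rss_returns_minus_inf_with_warning(self):
        with pytest.warns(UserWarning, match="zero residual"):
            assert compute_aic(self._fit_stub(0.0, 22, 4)) == -np.inf

    def test_prefers_two_tissue_on_noisy_two_tissue_data(self, gm_tac,
                                                         true_inputs, schedule):
        """AIC picks the reversible two-tissue family over the single-tissue
        model in the large majority of noisy replicates."""
        rng = np.random.default_rng(123)
        df = 2.0 ** (-schedule.mid_min / 20.385)
        sd = 0.05 * np.sqrt(np.maximum(gm_tac.activity, 0.01)
                            / (schedule.duration_min * df))
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            noisy = TissueTAC(gm_tac.roi_label, schedule,
                              gm_tac.activity + sd * rng.standard_normal(22))
            f1 = fit_tac(noisy, true_inputs, ModelSpec("1T2k", include_vb=True))
            f2 = fit_tac(noisy, true_inputs, ModelSpec("2T4k", include_vb=True))
            wins += select_model([f1, f2]).model_label == "2T4k_VB"
        assert wins >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# %SE
# ---------------------------------------------------------------------------

class TestPercentSE:
    def test_fixed_parameter_has_no_entry(self, gm_tac, true_inputs):
        fit = fit_tac(gm_tac, true_inputs,
                      ModelSpec("2T4k", include_vb=True, fixed_params={"k4": 0.02}))
        assert "k4" not in percent_se(fit)
        assert set(percent_se(fit)) == {"K1", "k2", "k3", "VB"}

    def test_noiseless_fit_has_vanishing_percent_se(self, gm_tac, true_inputs):
        fit = fit_tac(gm_tac, true_inputs, ModelSpec("2T4k", include_vb=True))
        assert all(v <= 0.1 for v in percent_se(fit).values())

    def test_percent_se_decreases_with_noise(self, gm_tac, true_inputs):
        rng = np.random.default_rng(2)
        ks = []
        for sigma in (0.2, 0.02, 0.002):
            noisy = _noisy(gm_tac, sigma, rng)
            fit = fit_tac(noisy, true_inputs, ModelSpec("2T4k", include_vb=True))
            ks.append(fit.percent_se["K1"])
        assert ks[0] > ks[1] > ks[2]

    def test_matches_bootstrap_oracle_order_of_magnitude(self, gm_tac,
                                                         true_inputs):
        """Gauss-Newton %SE for K1 agrees with a parametric-bootstrap
        estimate within a factor of two on one noisy TAC."""
        rng = np.random.default_rng(9)
        sigma = 0.08
        noisy = _noisy(gm_tac, sigma, rng)
        spec = ModelSpec("2T4k", include_vb=True)
        weights = WeightScheme("uniform")
        fit = fit_tac(noisy, true_inputs, spec, weights=weights)
        boot = []
        for _ in range(30):
            resampled = TissueTAC(noisy.roi_label, noisy.schedule,
                                  fit.fitted_tac.activity
                                  + sigma * rng.standard_normal(22))
            b = fit_tac(resampled, true_inputs, spec, weights=weights, n_starts=4)
            boot.append(b.estimates.K1)
        boot_pse = 100.0 * np.std(boot, ddof=1) / fit.estimates.K1
        ratio = fit.percent_se["K1"] / boot_pse
        assert 0.5 <= ratio <= 2.0


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

class TestSelectModel:
    def _stub(self, aic, p):
        f = TestAic()._fit_stub(1.0, 22, p)
        return dataclasses.replace(f, aic=aic)

    def test_single_candidate_wins(self):
        only = self._stub(3.0, 4)
        assert select_model([only]) is only

    def test_tie_goes_to_fewer_parameters(self):
        a = self._stub(5.0, 5)
        b = self._stub(5.0, 4)
        assert select_model([a, b]) is b

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_noiseless_two_tissue_data_selects_two_tissue(self, gm_tac,
                                                          true_inputs):
        f1 = fit_tac(gm_tac, true_inputs, ModelSpec("1T2k", include_vb=True))
        f2 = fit_tac(gm_tac, true_inputs, ModelSpec("2T4k", include_vb=True))
        assert select_model([f1, f2]).model_label == "2T4k_VB"


# ---------------------------------------------------------------------------
# Two-stage fixed-k4 run
# ---------------------------------------------------------------------------

class TestDualStage:
    def test_homogeneous_subject_self_consistency(self, true_inputs,
                                                  gm_rrms_params, schedule):
        """When every ROI shares the whole-brain parameters, stage-2
        estimates equal stage-1 estimates."""
        wm = KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[("RRMS", "WM")])
        tacs = {
            "whole_brain_GM": _clean_tac(gm_rrms_params, true_inputs, schedule),
            "whole_brain_WM": _clean_tac(wm, true_inputs, schedule),
            "cortex": _clean_tac(gm_rrms_params, true_inputs, schedule),
        }
        classes = {"whole_brain_GM": "GM", "whole_brain_WM": "WM", "cortex": "GM"}
        res = run_dual_stage(tacs, classes, true_inputs)
        for name in ("K1", "k2", "k3", "VB"):
            assert getattr(res.stage2["cortex"].estimates, name) == pytest.approx(
                getattr(res.stage1["GM"].estimates, name), rel=5e-3), name

    def test_heterogeneous_k3_recovered_with_class_common_k4(self, true_inputs,
                                                             schedule):
        gm = KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[("RRMS", "GM")])
        wm = KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[("RRMS", "WM")])
        roi_gm = dataclasses.replace(gm, k3=0.050)     # shares GM k4
        roi_wm = dataclasses.replace(wm, k3=0.030)     # shares WM k4
        tacs = {
            "whole_brain_GM": _clean_tac(gm, true_inputs, schedule),
            "whole_brain_WM": _clean_tac(wm, true_inputs, schedule),
            "thalamus": _clean_tac(roi_gm, true_inputs, schedule),
            "lesion": _clean_tac(roi_wm, true_inputs, schedule),
        }
        classes = {"whole_brain_GM": "GM", "whole_brain_WM": "WM",
                   "thalamus": "GM", "lesion": "T2lesion"}
        res = run_dual_stage(tacs, classes, true_inputs)
        assert res.stage2["thalamus"].estimates.k3 == pytest.approx(0.050, rel=0.01)
        assert res.stage2["lesion"].estimates.k3 == pytest.approx(0.030, rel=0.01)
        # lesions inherit the white-matter k4
        assert res.stage2["lesion"].estimates.k4 == res.k4_by_class["WM"]

    def test_stage1_k4_matches_generating_value(self, true_inputs,
                                                gm_rrms_params, schedule):
        wm = KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[("RRMS", "WM")])
        tacs = {
            "whole_brain_GM": _clean_tac(gm_rrms_params, true_inputs, schedule),
            "whole_brain_WM": _clean_tac(wm, true_inputs, schedule),
        }
        classes = {"whole_brain_GM": "GM", "whole_brain_WM": "WM"}
        res = run_dual_stage(tacs, classes, true_inputs)
        assert res.k4_by_class["GM"] == pytest.approx(0.020, rel=0.01)
        assert res.k4_by_class["WM"] == pytest.approx(0.032, rel=0.01)

    def test_unreliable_whole_brain_k4_aborts(self, true_inputs, schedule):
        """A whole-brain TAC with no specific-binding signal leaves k4
        unidentifiable and must abort the two-stage run."""
        flat = KineticParameters("2T4k", K1=0.087, k2=0.535, k3=0.0, k4=0.02,
                                 VB=0.075)
        rng = np.random.default_rng(0)
        tac = _noisy(_clean_tac(flat, true_inputs, schedule), 0.15, rng)
        tacs = {"whole_brain_GM": tac, "whole_brain_WM": tac}
        classes = {"whole_brain_GM": "GM", "whole_brain_WM": "WM"}
        with pytest.raises(UnreliableK4Error):
            run_dual_stage(tacs, classes, true_inputs)

    def test_missing_whole_brain_tac_raises(self, true_inputs, gm_rrms_params,
                                            schedule):
        tacs = {"whole_brain_GM": _clean_tac(gm_rrms_params, true_inputs, schedule)}
        with pytest.raises(ValueError, match="whole_brain_WM"):
            run_dual_stage(tacs, {"whole_brain_GM": "GM"}, true_inputs)
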