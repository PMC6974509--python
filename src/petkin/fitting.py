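"""Weighted nonlinear least-squares estimation of compartment-model
parameters, uncertainty quantification, AIC model selection, and the
two-stage fixed-k4 fitting procedure.

Fits minimise the weighted residual sum of squares between a
frame-averaged model prediction and a measured TAC with a bounded
trust-region least-squares solver, restarted from a low-discrepancy set of
initial points because the small specific-binding compartment of
fast-clearing tracers creates local minima. Parameter standard errors come
from the Gauss-Newton approximation at the optimum,
``cov = RSS_w/(n-p) * (J^T W J)^{-1}``, reported as percentages of the
estimates (%SE) — the quantity the reliability filter acts on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core import (
    C11_HALF_LIFE_MIN,
    FINE_DT_MIN,
    FrameSchedule,
    KineticParameters,
    MacroParameters,
    TissueTAC,
    _fine_grid,
    _simulate_on_grid,
    average_grid_over_frames,
    macro_parameters,
)
from .input_function import InputFunctionSet

__all__ = [
    "DEFAULT_BOUNDS",
    "SE_CUTOFFS",
    "ModelSpec",
    "WeightScheme",
    "FitResult",
    "DualStageResult",
    "UnreliableK4Error",
    "fit_tac",
    "compute_aic",
    "percent_se",
    "select_model",
    "run_dual_stage",
]

#: Default parameter bounds — generous envelopes around published
#: whole-brain estimates for fast-clearing neuroinflammation tracers.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "K1": (0.0, 1.0),
    "k2": (1e-3, 5.0),
    "k3": (0.0, 1.0),
    "k4": (1e-4, 1.0),
    "VB": (0.0, 0.3),
}

#: %SE reliability cutoffs: 25% for the robust parameters, 50% for the
#: noise-prone specific-compartment rates.
SE_CUTOFFS: dict[str, float] = {"K1": 25.0, "k2": 25.0, "VB": 25.0,
                                "k3": 50.0, "k4": 50.0}

_MODEL_RATE_PARAMS = {
    "1T2k": ("K1", "k2"),
    "2T3k": ("K1", "k2", "k3"),
    "2T4k": ("K1", "k2", "k3", "k4"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, which parameters are fixed, and the bounds."""

    model_id: str
    include_vb: bool = True
    fixed_params: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_RATE_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
        for name, val in self.fixed_params.items():
            if name not in self.param_names:
                raise ValueError(f"fixed parameter {name!r} not in model {self.label}")
            lo, hi = self.bounds[name]
            if not lo <= val <= hi:
                raise ValueError(f"fixed {name}={val} outside bounds [{lo}, {hi}]")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(_MODEL_RATE_PARAMS[self.model_id])
        if self.include_vb:
            names.append("VB")
        return tuple(names)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n not in self.fixed_params)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def label(self) -> str:
        lab = self.model_id + ("_VB" if self.include_vb else "")
        if "k4" in self.fixed_params:
            lab += "_k4"
        return lab

    def build_params(self, free_values: np.ndarray) -> KineticParameters:
        values = dict.fromkeys(("K1", "k2", "k3", "k4", "VB"), 0.0)
        values.update(self.fixed_params)
        values.update(zip(self.free_names, map(float, free_values)))
        return KineticParameters(self.model_id, **values)


@dataclass(frozen=True)
class WeightScheme:
    """Per-frame weighting of the residuals.

    ``frame`` mode weights each frame by duration * decay factor (the
    count-statistics surrogate: long, early frames carry more information);
    ``uniform`` weights all frames equally. Weights are normalised to mean
    one so AIC comparisons are invariant under rescaling.
    """

    mode: str = "frame"
    half_life_min: float = C11_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "frame"):
            raise ValueError("mode must be 'uniform' or 'frame'")

    def weights(self, schedule: FrameSchedule) -> np.ndarray:
        if self.mode == "uniform":
            w = np.ones(schedule.n_frames)
        else:
            decay = 2.0 ** (-schedule.mid_min / self.half_life_min)
            w = schedule.duration_min * decay
        return w / w.mean()


@dataclass(frozen=True)
class FitResult:
    """One model fit to one TAC."""

    estimates: KineticParameters
    model_label: str
    free_names: tuple[str, ...]
    se: dict[str, float]
    percent_se: dict[str, float]
    rss: float
    n_frames: int
    n_free: int
    aic: float
    fitted_tac: TissueTAC
    converged: bool
    macro: MacroParameters


class UnreliableK4Error(RuntimeError):
    """First-stage whole-brain k4 estimate failed the reliability cutoff."""


@dataclass(frozen=True)
class DualStageResult:
    """Output of the two-stage fixed-k4 procedure."""

    stage1: dict[str, FitResult]        # tissue class -> whole-brain fit
    k4_by_class: dict[str, float]
    stage2: dict[str, FitResult]        # ROI label -> fixed-k4 fit


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------

def _starts(spec: ModelSpec, n_starts: int, seed: int) -> np.ndarray:
    lo = np.array([spec.bounds[n][0] for n in spec.free_names])
    hi = np.array([spec.bounds[n][1] for n in spec.free_names])
    sampler = qmc.Halton(d=len(lo), scramble=True, seed=seed)
    u = sampler.random(n_starts)
    return lo + u * (hi - lo)


def fit_tac(tac: TissueTAC, inputs: InputFunctionSet, spec: ModelSpec,
            weights: WeightScheme | None = None, n_starts: int = 10,
            seed: int = 0, dt_min: float = FINE_DT_MIN) -> FitResult:
    """Fit a compartment model to a frame-averaged TAC.

    Weighted bounded least squares with ``n_starts`` multistart points
    drawn from a scrambled Halton sequence over the bounds; the best
    optimum across starts is returned. Standard errors use the
    Gauss-Newton covariance at that optimum.
    """
    weights = weights or WeightScheme()
    sched = tac.schedule
    w = tac.weights / tac.weights.mean() if tac.weights is not None else weights.weights(sched)
    sw = np.sqrt(w)
    y = tac.activity

    grid = _fine_grid(sched.total_span_s / 60.0, dt_min)

    def predict(params: KineticParameters) -> np.ndarray:
        fine = _simulate_on_grid(params, inputs, grid, dt_min)
        return average_grid_over_frames(grid, fine, sched)

    def resid(x: np.ndarray) -> np.ndarray:
        return sw * (predict(spec.build_params(x)) - y)

    lo = np.array([spec.bounds[n][0] for n in spec.free_names])
    hi = np.array([spec.bounds[n][1] for n in spec.free_names])
    best = None
    any_converged = False
    for x0 in _starts(spec, n_starts, seed):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol

    est = spec.build_params(best.x)
    rss = float(2.0 * best.cost)
    n, p = sched.n_frames, spec.n_free
    se = _gauss_newton_se(best.jac, rss, n, p, spec.free_names)
    pse = {name: (np.inf if best.x[i] == 0 else 100.0 * se[name] / abs(best.x[i]))
           for i, name in enumerate(spec.free_names)}
    aic = _aic(rss, n, p)
    fitted = TissueTAC(tac.roi_label, sched, predict(est), tac.weights)
    try:
        macro = macro_parameters(est)
    except ZeroDivisionError:
        macro = MacroParameters(VT=None, VND=np.nan, BPND=None, K1k2=np.nan)
    return FitResult(
        estimates=est, model_label=spec.label, free_names=spec.free_names,
        se=se, percent_se=pse, rss=rss, n_frames=n, n_free=p, aic=aic,
        fitted_tac=fitted, converged=any_converged, macro=macro,
    )


def _gauss_newton_se(jac: np.ndarray, rss: float, n: int, p: int,
                     names: Sequence[str]) -> dict[str, float]:
    s2 = rss / max(n - p, 1)
    jtj = jac.T @ jac
    # near-singular information: parameters aligned with tiny singular
    # values get infinite SE rather than a spuriously finite one
    try:
        u, s, vt = np.linalg.svd(jtj)
    except np.linalg.LinAlgError:
        return dict(zip(names, np.full(p, np.inf)))
    tol = s.max() * 1e-12 if s.size and s.max() > 0 else np.inf
    bad = s <= tol
    inv_s = np.where(bad, 0.0, 1.0 / np.where(bad, 1.0, s))
    diag = np.einsum("ij,j,ij->i", vt.T, inv_s, vt.T)
    se_vals = np.sqrt(np.maximum(s2 * diag, 0.0))
    # parameters with weight in a null direction are unidentifiable
    if bad.any():
        affected = np.abs(vt[bad, :]).max(axis=0) > 1e-8
        se_vals = np.where(affected, np.inf, se_vals)
    return dict(zip(names, se_vals))


def _aic(rss: float, n: int, p: int) -> float:
    if rss <= 0:
        warnings.warn("zero residual sum of squares; AIC set to -inf")
        return -np.inf
    return n * np.log(rss / n) + 2 * p


def compute_aic(fit: FitResult) -> float:
    """Akaike information criterion of a fit: n*ln(RSS_w/n) + 2p."""
    if fit.n_frames <= fit.n_free:
        raise ValueError("AIC requires more frames than free parameters")
    return _aic(fit.rss, fit.n_frames, fit.n_free)


def percent_se(fit: FitResult) -> dict[str, float]:
    """Per-free-parameter standard errors as percentages of the estimates."""
    return dict(fit.percent_se)


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """The fit with minimum AIC; ties go to the fit with fewer free
    parameters (then to input order)."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(enumerate(fits), key=lambda kv: (kv[1].aic, kv[1].n_free, kv[0]))[1]


# ---------------------------------------------------------------------------
# Two-stage fixed-k4 procedure
# ---------------------------------------------------------------------------

#: ROI tissue classes that inherit the white-matter whole-brain k4 (lesions
#: are carved out of the white-matter mask).
_WM_LIKE = {"WM", "T2lesion", "GdLesion"}


def run_dual_stage(tacs: Mapping[str, TissueTAC],
                   tissue_class: Mapping[str, str],
                   inputs: InputFunctionSet,
                   wb_gm_label: str = "whole_brain_GM",
                   wb_wm_label: str = "whole_brain_WM",
                   weights: WeightScheme | None = None,
                   n_starts: int = 10, seed: int = 0,
                   k4_se_cutoff: float = 50.0) -> DualStageResult:
    """Two-stage reversible two-tissue fit with whole-brain-fixed k4.

    Stage 1 fits 2T4k_VB with free k4 to the whole-brain grey- and
    white-matter TACs. Stage 2 refits every ROI with k4 fixed to its
    tissue class's stage-1 estimate (lesion ROIs inherit the white-matter
    value), reducing the number of free parameters where the small
    specific compartment makes k4 unstable.
    """
    for lab in (wb_gm_label, wb_wm_label):
        if lab not in tacs:
            raise ValueError(f"whole-brain TAC {lab!r} missing")

    free_spec = ModelSpec("2T4k", include_vb=True)
    stage1: dict[str, FitResult] = {}
    k4_by_class: dict[str, float] = {}
    for cls, lab in (("GM", wb_gm_label), ("WM", wb_wm_label)):
        fit = fit_tac(tacs[lab], inputs, free_spec, weights=weights,
                      n_starts=n_starts, seed=seed)
        k4_se = fit.percent_se.get("k4", np.inf)
        if not np.isfinite(k4_se) or k4_se > k4_se_cutoff:
            raise UnreliableK4Error(
                f"whole-brain {cls} k4 %SE {k4_se:.1f}% exceeds {k4_se_cutoff}%")
        stage1[cls] = fit
        k4_by_class[cls] = fit.estimates.k4

    stage2: dict[str, FitResult] = {}
    for roi, tac in tacs.items():
        cls = tissue_class.get(roi, "GM")
        k4 = k4_by_class["WM"] if cls in _WM_LIKE else k4_by_class["GM"]
        spec = ModelSpec("2T4k", include_vb=True, fixed_params={"k4": k4})
        stage2[roi] = fit_tac(tac, inputs, spec, weights=weights,
                              n_starts=n_starts, seed=seed)
    return DualStageResult(stage1=stage1, k4_by_class=k4_by_class, stage2=stage2)
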