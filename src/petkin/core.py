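"""Compartment models for dynamic PET and their analytic solutions.

This module defines the tissue-side primitives of plasma-input kinetic
analysis: the dynamic frame schedule, sampled concentration curves,
frame-averaged time-activity curves (TACs), the kinetic parameter sets of
the single-tissue (1T2k) and two-tissue (2T3k irreversible, 2T4k
reversible) compartment models, the closed-form impulse responses of those
models, the forward simulation of a tissue TAC from an arterial input
function, and the macro parameters (VT, VND, BPND, K1/k2, Ki) derived from
the rate constants.

Conventions
-----------
* Time is measured in **minutes** from tracer injection everywhere except
  frame schedules, which are stored in **seconds** (the units acquisition
  consoles print) and converted at the boundary.
* Rate constants are in min^-1, K1 in mL·cm^-3·min^-1, activity
  concentrations in kBq·mL^-1.
* All curves are assumed decay-corrected to injection time; radioactive
  decay enters only through noise models.
* Frames are half-open intervals [start, start + duration); they must not
  overlap but gaps are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.signal import lfilter

if TYPE_CHECKING:  # pragma: no cover
    from .input_function import InputFunctionSet

__all__ = [
    "C11_HALF_LIFE_MIN",
    "MODEL_IDS",
    "FrameSchedule",
    "SampledCurve",
    "TissueTAC",
    "KineticParameters",
    "MacroParameters",
    "ExpSum",
    "default_schedule",
    "impulse_response",
    "convolve_expsum",
    "simulate_tissue_curve",
    "frame_average",
    "macro_parameters",
]

#: Physical half-life of carbon-11 in minutes.
C11_HALF_LIFE_MIN = 20.385

#: Recognised compartment-model identifiers.
MODEL_IDS = ("1T2k", "2T3k", "2T4k")

#: Internal quadrature grid step for convolutions (minutes); 0.5 s resolves
#: the 15 s first frame of the default schedule.
FINE_DT_MIN = 0.5 / 60.0


# ---------------------------------------------------------------------------
# Frame schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds) of a dynamic acquisition."""

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start_s and frame_duration_s must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = start + dur
        overlap = np.nonzero(ends[:-1] > start[1:] + 1e-9)[0]
        if overlap.size:
            rows = ", ".join(f"{i}->{i + 1}" for i in overlap)
            raise ValueError(f"overlapping frames at rows {rows}")

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], start_s: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from successive frame durations."""
        dur = np.asarray(durations_s, dtype=float)
        starts = start_s + np.concatenate(([0.0], np.cumsum(dur)[:-1]))
        return cls(starts, dur)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.frame_start_s + 0.5 * self.frame_duration_s

    @property
    def start_min(self) -> np.ndarray:
        return self.frame_start_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.frame_end_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.frame_duration_s / 60.0

    @property
    def total_span_s(self) -> float:
        """Time from injection to the end of the last frame (seconds)."""
        return float(self.frame_end_s[-1])

    def truncate(self, cut_minutes: float) -> "FrameSchedule":
        """Keep only frames whose *start* lies before ``cut_minutes``."""
        keep = self.frame_start_s < cut_minutes * 60.0
        if not np.any(keep):
            raise ValueError("truncation removes all frames")
        return FrameSchedule(self.frame_start_s[keep], self.frame_duration_s[keep])


#: Frame durations (s) of the default 90-min dynamic acquisition:
#: 1x15, 3x5, 3x10, 4x60, 2x150, 2x300, 7x600 s -- 22 frames, 5400 s.
DEFAULT_FRAME_DURATIONS_S = (
    [15.0] + [5.0] * 3 + [10.0] * 3 + [60.0] * 4 + [150.0] * 2 + [300.0] * 2 + [600.0] * 7
)


def default_schedule() -> FrameSchedule:
    """The 22-frame, 90-min acquisition schedule used throughout."""
    return FrameSchedule.from_durations(DEFAULT_FRAME_DURATIONS_S)


# ---------------------------------------------------------------------------
# Curves and TACs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledCurve:
    """A concentration curve sampled at strictly increasing times (minutes).

    The curve is treated as piecewise linear between samples, zero before
    the first sample (pre-arrival) and constant after the last.
    """

    time_min: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("time and value must be 1-D and equal length")
        if t.size == 0:
            raise ValueError("curve must contain at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    def __call__(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time_min, self.value,
                         left=0.0, right=float(self.value[-1]))

    @property
    def t_max(self) -> float:
        return float(self.time_min[-1])

    def shifted(self, delay_s: float) -> "SampledCurve":
        """Shift the curve later in time by ``delay_s`` seconds."""
        return SampledCurve(self.time_min + delay_s / 60.0, self.value)

    def scaled(self, factor: float) -> "SampledCurve":
        return SampledCurve(self.time_min, self.value * factor)


@dataclass(frozen=True)
class TissueTAC:
    """Frame-averaged regional activity on a frame schedule."""

    roi_label: str
    schedule: FrameSchedule
    activity: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", a)
        if a.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must equal the number of frames")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != a.shape:
                raise ValueError("weights length must equal the number of frames")
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be nonnegative and not all zero")

    def truncate(self, cut_minutes: float) -> "TissueTAC":
        sched = self.schedule.truncate(cut_minutes)
        n = sched.n_frames
        w = self.weights[:n] if self.weights is not None else None
        return TissueTAC(self.roi_label, sched, self.activity[:n], w)


# ---------------------------------------------------------------------------
# Kinetic parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of a plasma-input compartment model.

    ``model_id`` selects the topology: ``1T2k`` (single tissue), ``2T3k``
    (irreversible two-tissue, k4 = 0) or ``2T4k`` (reversible two-tissue).
    ``VB`` is the fractional blood volume; models without a blood-volume
    term simply carry VB = 0.
    """

    model_id: str
    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.VB < 1.0:
            raise ValueError("VB must lie in [0, 1)")
        if self.K1 > 0 and self.k2 <= 0:
            raise ValueError("k2 must be positive when K1 > 0")
        if self.model_id == "1T2k" and (self.k3 != 0 or self.k4 != 0):
            raise ValueError("1T2k requires k3 = k4 = 0")
        if self.model_id == "2T3k" and self.k4 != 0:
            raise ValueError("2T3k requires k4 = 0")
        if self.model_id == "2T4k" and self.k3 > 0 and self.k4 <= 0:
            raise ValueError("2T4k requires k4 > 0 when k3 > 0")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in ("K1", "k2", "k3", "k4", "VB")}


@dataclass(frozen=True)
class MacroParameters:
    """Macro (composite) parameters of a compartment model.

    VT    total volume of distribution, (K1/k2)(1 + k3/k4); undefined for
          the irreversible model.
    VND   non-displaceable volume of distribution, K1/k2.
    BPND  non-displaceable binding potential, k3/k4 (reversible model only).
    K1k2  the K1/k2 ratio (identical to VND; kept as an explicit endpoint
          because it is reported separately for lesions).
    Ki    net influx rate K1*k3/(k2+k3), irreversible model only.
    """

    VT: float | None
    VND: float
    BPND: float | None
    K1k2: float
    Ki: float | None = None


# ---------------------------------------------------------------------------
# Impulse response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpSum:
    """A sum of exponentials  sum_i amps[i]*exp(-rates[i]*t), optionally
    plus a repeated-root ramp term  ramp_amp * t * exp(-ramp_rate*t)."""

    amps: np.ndarray
    rates: np.ndarray
    ramp_amp: float = 0.0
    ramp_rate: float = 0.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, r in zip(self.amps, self.rates):
            out = out + a * np.exp(-r * t)
        if self.ramp_amp:
            out = out + self.ramp_amp * t * np.exp(-self.ramp_rate * t)
        return out

    @property
    def value_at_zero(self) -> float:
        return float(np.sum(self.amps))


def impulse_response(params: KineticParameters) -> ExpSum:
    """Closed-form tissue impulse response to a unit plasma input.

    1T2k:  K1 * exp(-k2 t)
    2T3k:  K1*k3/(k2+k3) + K1*k2/(k2+k3) * exp(-(k2+k3) t)
           (the constant is represented as an exponential with rate 0)
    2T4k:  phi1*exp(-a1 t) + phi2*exp(-a2 t) with
           a1,2 = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2,
           phi1 = K1 (k3+k4-a1)/(a2-a1), phi2 = K1 (a2-k3-k4)/(a2-a1);
           a repeated root (a1 == a2) degenerates to
           K1*exp(-a t) + K1*(k3+k4-a)*t*exp(-a t).

    The amplitudes always sum to K1 at t = 0.
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if params.model_id == "1T2k":
        return ExpSum(np.array([K1]), np.array([k2]))
    if params.model_id == "2T3k":
        s = k2 + k3
        if s <= 0:
            raise ValueError("2T3k requires k2 + k3 > 0")
        return ExpSum(np.array([K1 * k3 / s, K1 * k2 / s]), np.array([0.0, s]))
    # 2T4k
    b = k2 + k3 + k4
    disc = b * b - 4.0 * k2 * k4
    if disc < -1e-12 * max(b * b, 1.0):
        raise ValueError("negative discriminant: invalid 2T4k rate constants")
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    if root <= 1e-10 * max(b, 1.0):
        alpha = 0.5 * b
        return ExpSum(np.array([K1]), np.array([alpha]),
                      ramp_amp=K1 * (k3 + k4 - alpha), ramp_rate=alpha)
    a1 = 0.5 * (b - root)
    a2 = 0.5 * (b + root)
    phi1 = K1 * (k3 + k4 - a1) / (a2 - a1)
    phi2 = K1 * (a2 - k3 - k4) / (a2 - a1)
    return ExpSum(np.array([phi1, phi2]), np.array([a1, a2]))


# ---------------------------------------------------------------------------
# Convolution on a uniform grid
# ---------------------------------------------------------------------------

def _exp_step_integrals(theta: float, dt: float) -> tuple[float, float, float]:
    """I0 = int_0^dt e^{-theta u} du, I1 = int u e^{-theta u} du,
    I2 = int u^2 e^{-theta u} du, with series fallbacks for small theta*dt."""
    x = theta * dt
    if x < 1e-5:
        i0 = dt * (1.0 - x / 2.0 + x * x / 6.0)
        i1 = dt * dt * (0.5 - x / 3.0 + x * x / 8.0)
        i2 = dt ** 3 * (1.0 / 3.0 - x / 4.0 + x * x / 10.0)
        return i0, i1, i2
    e = np.exp(-x)
    i0 = (1.0 - e) / theta
    i1 = (1.0 - e * (1.0 + x)) / (theta * theta)
    i2 = (2.0 - e * (2.0 + 2.0 * x + x * x)) / (theta ** 3)
    return i0, i1, i2


def _conv_single_exp(theta: float, cp: np.ndarray, dt: float) -> np.ndarray:
    """y(t_i) = int_0^{t_i} e^{-theta (t_i - s)} cp(s) ds for cp piecewise
    linear on a uniform grid, via the exact one-step recursion
    y_i = E*y_{i-1} + b_i (implemented as an IIR filter)."""
    e = float(np.exp(-theta * dt))
    i0, i1, _ = _exp_step_integrals(theta, dt)
    c0 = cp[:-1]
    c1 = cp[1:]
    b = c1 * i0 + (c0 - c1) * (i1 / dt)
    y = np.empty_like(cp)
    y[0] = 0.0
    y[1:] = lfilter([1.0], [1.0, -e], b)
    return y


def _conv_ramp_exp(theta: float, cp: np.ndarray, dt: float,
                   y: np.ndarray) -> np.ndarray:
    """z(t_i) = int (t_i - s) e^{-theta (t_i - s)} cp(s) ds, given y from
    :func:`_conv_single_exp` for the same theta (repeated-root term)."""
    e = float(np.exp(-theta * dt))
    _, i1, i2 = _exp_step_integrals(theta, dt)
    c0 = cp[:-1]
    c1 = cp[1:]
    b = c1 * i1 + (c0 - c1) * (i2 / dt)
    d = b + e * dt * y[:-1]
    z = np.empty_like(cp)
    z[0] = 0.0
    z[1:] = lfilter([1.0], [1.0, -e], d)
    return z


def convolve_expsum(irf: ExpSum, cp: np.ndarray, dt_min: float) -> np.ndarray:
    """Convolve an impulse response with a plasma curve sampled on a uniform
    grid of step ``dt_min`` (exact for piecewise-linear input)."""
    cp = np.asarray(cp, dtype=float)
    out = np.zeros_like(cp)
    for a, r in zip(irf.amps, irf.rates):
        if a == 0.0:
            continue
        out += a * _conv_single_exp(float(r), cp, dt_min)
    if irf.ramp_amp:
        y = _conv_single_exp(float(irf.ramp_rate), cp, dt_min)
        out += irf.ramp_amp * _conv_ramp_exp(float(irf.ramp_rate), cp, dt_min, y)
    return out


# ---------------------------------------------------------------------------
# Forward simulation and frame averaging
# ---------------------------------------------------------------------------

def _fine_grid(t_end_min: float, dt_min: float = FINE_DT_MIN) -> np.ndarray:
    n = int(np.ceil(t_end_min / dt_min + 0.5)) + 1
    return np.arange(n) * dt_min


def simulate_tissue_curve(params: KineticParameters, inputs: "InputFunctionSet",
                          eval_times_min: np.ndarray,
                          dt_min: float = FINE_DT_MIN) -> SampledCurve:
    """Simulate the tissue concentration curve

        C_T(t) = (1 - VB) * (IRF (*) C_p)(t) + VB * C_wb(t)

    on a uniform fine grid (trapezoidal/piecewise-linear quadrature) and
    sample it at ``eval_times_min``. ``inputs`` must already be
    delay-aligned to the tissue clock.
    """
    t = np.asarray(eval_times_min, dtype=float)
    if t.size == 0:
        raise ValueError("eval_times_min must be non-empty")
    if np.any(t < 0):
        raise ValueError("evaluation times must be >= 0 (injection time)")
    grid = _fine_grid(float(t.max()), dt_min)
    fine = _simulate_on_grid(params, inputs, grid, dt_min)
    return SampledCurve(t, np.interp(t, grid, fine))


def _simulate_on_grid(params: KineticParameters, inputs: "InputFunctionSet",
                      grid: np.ndarray, dt_min: float) -> np.ndarray:
    """Tissue curve evaluated on a prepared uniform grid (internal)."""
    cp = inputs.plasma_parent(grid)
    tissue = np.zeros_like(grid)
    if params.K1 > 0:
        irf = impulse_response(params)
        tissue = convolve_expsum(irf, cp, dt_min)
    out = (1.0 - params.VB) * tissue
    if params.VB > 0:
        out = out + params.VB * inputs.whole_blood(grid)
    return out


def frame_average(curve: SampledCurve, schedule: FrameSchedule) -> TissueTAC:
    """Average a piecewise-linear curve over each frame of a schedule.

    Exact for the linear interpolant (trapezoid with nodes at the frame
    boundaries and every curve sample inside the frame).
    """
    if schedule.total_span_s / 60.0 > curve.t_max + 1e-9:
        raise ValueError("schedule extends beyond the support of the curve")
    vals = np.empty(schedule.n_frames)
    for i, (a, b) in enumerate(zip(schedule.start_min, schedule.end_min)):
        inner = curve.time_min[(curve.time_min > a) & (curve.time_min < b)]
        nodes = np.concatenate(([a], inner, [b]))
        vals[i] = np.trapezoid(curve(nodes), nodes) / (b - a)
    return TissueTAC("", schedule, vals)


def average_grid_over_frames(grid: np.ndarray, fine: np.ndarray,
                             schedule: FrameSchedule) -> np.ndarray:
    """Frame averages of a curve already on a uniform fine grid.

    Uses the cumulative trapezoid of the grid curve; fast path used inside
    the fitting loop (frame boundaries need not coincide with grid nodes).
    """
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate(([0.0], cumulative_trapezoid(fine, grid)))
    f_start = np.interp(schedule.start_min, grid, cum)
    f_end = np.interp(schedule.end_min, grid, cum)
    return (f_end - f_start) / schedule.duration_min


# ---------------------------------------------------------------------------
# Macro parameters
# ---------------------------------------------------------------------------

def macro_parameters(params: KineticParameters) -> MacroParameters:
    """Macro parameters implied by a set of rate constants.

    VND = K1/k2 always; for the reversible two-tissue model BPND = k3/k4
    and VT = VND*(1 + BPND); for the single-tissue model VT = VND; for the
    irreversible model VT is undefined and the net influx rate
    Ki = K1*k3/(k2+k3) is reported instead.
    """
    if params.k2 <= 0:
        raise ZeroDivisionError("k2 must be positive to form K1/k2")
    vnd = params.K1 / params.k2
    if params.model_id == "1T2k":
        return MacroParameters(VT=vnd, VND=vnd, BPND=None, K1k2=vnd)
    if params.model_id == "2T3k":
        ki = params.K1 * params.k3 / (params.k2 + params.k3)
        return MacroParameters(VT=None, VND=vnd, BPND=None, K1k2=vnd, Ki=ki)
    if params.k4 <= 0:
        raise ZeroDivisionError("k4 must be positive to form BPND = k3/k4")
    bp = params.k3 / params.k4
    return MacroParameters(VT=vnd * (1.0 + bp), VND=vnd, BPND=bp, K1k2=vnd)
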