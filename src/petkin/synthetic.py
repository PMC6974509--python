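"""Synthetic subjects and cohorts for the dynamic-PET pipeline.

Generates everything a real acquisition would provide — a continuous
online whole-blood record, manual arterial samples with plasma activities
and parent fractions, and noisy frame-averaged regional TACs on the
22-frame, 90-min schedule — from a known ground truth, so that every
pipeline stage (input-function construction, model fitting, model
selection, reliability filtering, group comparison, scan truncation) can
be exercised end-to-end and checked against the generating parameters.

The plasma bolus follows the Feng model; the parent fraction declines
along a Hill curve; per-ROI rate constants are drawn from truncated
normals around published whole-brain group means (relapsing-remitting MS
patients vs healthy controls, grey vs white matter), with the
dissociation rate k4 drawn once per tissue class per subject and shared
across that class's ROIs — the physiological assumption (k4 = k_off is a
receptor property, not a regional one) that justifies the fixed-k4
second fitting stage. Patient subjects additionally carry T2 and
gadolinium-enhancing lesion ROIs with reduced specific binding (lower k3)
and, for enhancing lesions, elevated K1 reflecting blood-brain-barrier
disruption.

Frame noise is Gaussian with a count-statistics variance model,
``sd = sigma0 * sqrt(C(t_mid) / (dt * DF(t_mid)))`` with DF the
radioactive decay factor of carbon-11, so late frames — short of counts
once the tracer has decayed — are noisier than mid-scan frames at equal
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .core import (
    C11_HALF_LIFE_MIN,
    FrameSchedule,
    KineticParameters,
    SampledCurve,
    TissueTAC,
    default_schedule,
    frame_average,
    simulate_tissue_curve,
)
from .fitting import DEFAULT_BOUNDS, WeightScheme
from .input_function import (
    ContinuousBloodSeries,
    InputFunctionSet,
    ManualSample,
    ParentFractionModel,
    PlasmaRatioModel,
)

__all__ = [
    "MANUAL_SAMPLE_TIMES_MIN",
    "InputFunctionSpec",
    "PopulationSpec",
    "SubjectDataset",
    "generate_input_function",
    "generate_subject",
    "generate_cohort",
]

#: Manual arterial sampling times (minutes after injection).
MANUAL_SAMPLE_TIMES_MIN = (5.0, 10.0, 20.0, 40.0, 60.0, 75.0, 90.0)


@dataclass(frozen=True)
class InputFunctionSpec:
    """Ground truth for the arterial side of a synthetic subject.

    The total-plasma bolus is the Feng model
    ``Cp(t) = (A1*(t-tau) - A2 - A3)*exp(-l1*(t-tau))
              + A2*exp(-l2*(t-tau)) + A3*exp(-l3*(t-tau))`` for t >= tau,
    zero before arrival. Defaults describe a conventional bolus shape
    scaled to a ~360 MBq injection. The whole-blood curve is the plasma
    curve divided by the plasma/whole-blood ratio R(t); the parent plasma
    curve is the plasma curve times the Hill parent fraction f(t).
    """

    A1: float = 850.0      # kBq mL^-1 min^-1
    A2: float = 21.0       # kBq mL^-1
    A3: float = 20.0       # kBq mL^-1
    lam1: float = 4.1      # min^-1
    lam2: float = 0.12     # min^-1
    lam3: float = 0.01     # min^-1
    arrival_min: float = 0.5
    pf_a: float = 0.25     # parent-fraction asymptote
    pf_b: float = 1.5      # Hill steepness
    pf_c: float = 20.0     # Hill half-time (min)
    ratio_r0: float = 1.25
    ratio_r1: float = 0.002  # min^-1
    delay_s: float = 0.0
    sigma_blood: float = 0.02   # multiplicative noise, continuous & manual
    sigma_pf: float = 0.01      # additive noise on parent fractions

    def __post_init__(self) -> None:
        if not self.lam1 > self.lam2 > self.lam3 > 0:
            raise ValueError("require lam1 > lam2 > lam3 > 0")
        t = np.linspace(0.0, 91.0, 2000)
        if np.any(self.total_plasma(t) < -1e-9):
            raise ValueError("input spec produces negative plasma concentrations")

    def total_plasma(self, t) -> np.ndarray:
        """Feng total-plasma curve (parent + metabolites), kBq/mL."""
        t = np.asarray(t, dtype=float)
        u = t - self.arrival_min
        up = np.where(u > 0, u, 0.0)
        val = ((self.A1 * up - self.A2 - self.A3) * np.exp(-self.lam1 * up)
               + self.A2 * np.exp(-self.lam2 * up)
               + self.A3 * np.exp(-self.lam3 * up))
        return np.where(u > 0, val, 0.0)

    @property
    def parent_fraction(self) -> ParentFractionModel:
        return ParentFractionModel(self.pf_a, self.pf_b, self.pf_c)

    @property
    def plasma_ratio(self) -> PlasmaRatioModel:
        return PlasmaRatioModel(self.ratio_r0, self.ratio_r1)

    def true_input_set(self, t_end_min: float = 91.0,
                       dt_s: float = 1.0) -> InputFunctionSet:
        """Noise-free input-function set on the tissue clock."""
        t = np.arange(0.0, t_end_min * 60.0 + dt_s / 2, dt_s) / 60.0
        cp = self.total_plasma(t)
        wb = cp / self.plasma_ratio(t)
        parent = cp * self.parent_fraction(t)
        shift = self.delay_s / 60.0
        return InputFunctionSet(SampledCurve(t + shift, wb),
                                SampledCurve(t + shift, parent),
                                self.delay_s)


#: Published whole-brain group means +/- SD for the reversible two-tissue
#: model with blood volume and whole-brain-fixed k4 (the synthetic
#: population defaults): (group, tissue class) -> {param: (mean, sd)}.
REFERENCE_POPULATIONS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("RRMS", "GM"): {"K1": (0.087, 0.030), "k2": (0.535, 0.115),
                     "k3": (0.035, 0.010), "k4": (0.020, 0.008),
                     "VB": (0.075, 0.019)},
    ("HC", "GM"): {"K1": (0.085, 0.022), "k2": (0.686, 0.127),
                   "k3": (0.032, 0.012), "k4": (0.029, 0.009),
                   "VB": (0.075, 0.015)},
    ("RRMS", "WM"): {"K1": (0.062, 0.025), "k2": (0.378, 0.150),
                     "k3": (0.043, 0.017), "k4": (0.032, 0.012),
                     "VB": (0.057, 0.016)},
    ("HC", "WM"): {"K1": (0.062, 0.020), "k2": (0.526, 0.146),
                   "k3": (0.057, 0.021), "k4": (0.058, 0.019),
                   "VB": (0.054, 0.012)},
}

_DEFAULT_GM_ROIS = ("frontal_cortex", "temporal_cortex", "parietal_cortex",
                    "cingulate_cortex", "thalamus", "hippocampus")
_DEFAULT_WM_ROIS = ("nonlesional_WM",)


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level ground truth for a synthetic cohort."""

    populations: dict[tuple[str, str], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_POPULATIONS.items()})
    gm_rois: tuple[str, ...] = _DEFAULT_GM_ROIS
    wm_rois: tuple[str, ...] = _DEFAULT_WM_ROIS
    n_rrms: int = 5
    n_hc: int = 5
    sigma0: float = 0.05          # kBq^1/2 mL^-1/2 min^1/2 noise scale
    t2_k3_mult: float = 0.7       # T2 lesions: reduced specific binding
    gd_k3_mult: float = 0.5       # enhancing lesions: further reduction
    gd_k1_mult: float = 1.5       # enhancing lesions: BBB leakage raises K1/k2

    def __post_init__(self) -> None:
        for key, stats in self.populations.items():
            for name, (mean, sd) in stats.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid stats for {key}/{name}")


@dataclass(frozen=True)
class SubjectDataset:
    """One synthetic subject: ground truth plus simulated measurements."""

    subject_id: str
    group: str
    seed: int
    true_params: dict[str, KineticParameters]
    tissue_class: dict[str, str]
    true_inputs: InputFunctionSet
    continuous_blood: ContinuousBloodSeries
    manual_samples: tuple[ManualSample, ...]
    tacs: dict[str, TissueTAC]


# ---------------------------------------------------------------------------
# Blood-side generation
# ---------------------------------------------------------------------------

def generate_input_function(spec: InputFunctionSpec, seed: int,
                            duration_min: float = 91.0,
                            gap_half_width_s: float = 15.0,
                            ) -> tuple[InputFunctionSet, ContinuousBloodSeries,
                                       tuple[ManualSample, ...]]:
    """Simulate the arterial measurements of one subject.

    Returns the noise-free input-function set (the ground truth driving
    tissue simulation) together with the noisy continuous whole-blood
    record (1 s resolution, briefly interrupted around each manual draw)
    and the noisy manual samples. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    truth = spec.true_input_set(t_end_min=duration_min)

    t_s = np.arange(0.0, duration_min * 60.0 + 0.5, 1.0)
    t_min = t_s / 60.0
    wb_true = spec.total_plasma(t_min) / spec.plasma_ratio(t_min)
    keep = np.ones(t_s.size, dtype=bool)
    for tm in MANUAL_SAMPLE_TIMES_MIN:
        keep &= np.abs(t_s - tm * 60.0) > gap_half_width_s
    noise = 1.0 + spec.sigma_blood * rng.standard_normal(t_s.size)
    segment = np.where(t_min <= 5.0, 1, 2)
    continuous = ContinuousBloodSeries(t_s[keep], (wb_true * noise)[keep],
                                       segment[keep])

    samples = []
    f = spec.parent_fraction
    R = spec.plasma_ratio
    for tm in MANUAL_SAMPLE_TIMES_MIN:
        cp = float(spec.total_plasma(tm))
        wb = cp / float(R(tm))
        pf = float(f(tm))
        wb_n = wb * (1.0 + spec.sigma_blood * rng.standard_normal())
        pl_n = cp * (1.0 + spec.sigma_blood * rng.standard_normal())
        pf_n = float(np.clip(pf + spec.sigma_pf * rng.standard_normal(), 0.0, 1.0))
        samples.append(ManualSample(tm, max(wb_n, 0.0), max(pl_n, 0.0), pf_n))
    return truth, continuous, tuple(samples)


# ---------------------------------------------------------------------------
# Tissue-side generation
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, mean: float, sd: float,
          lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


_TRUNC_LO = 1e-4  # draws truncated at [1e-4, parameter upper bound]


def _draw_params(rng: np.random.Generator,
                 stats: dict[str, tuple[float, float]],
                 k4: float) -> KineticParameters:
    vals = {}
    for name in ("K1", "k2", "k3", "VB"):
        mean, sd = stats[name]
        vals[name] = _draw(rng, mean, sd, _TRUNC_LO, DEFAULT_BOUNDS[name][1])
    return KineticParameters("2T4k", K1=vals["K1"], k2=vals["k2"],
                             k3=vals["k3"], k4=k4, VB=vals["VB"])


def _noisy_tac(rng: np.random.Generator, roi: str, params: KineticParameters,
               inputs: InputFunctionSet, schedule: FrameSchedule,
               sigma0: float) -> TissueTAC:
    fine = simulate_tissue_curve(params, inputs,
                                 np.arange(0.0, schedule.total_span_s / 60.0
                                           + 1e-9, 1.0 / 60.0))
    clean = frame_average(fine, schedule).activity
    if sigma0 > 0:
        df = 2.0 ** (-schedule.mid_min / C11_HALF_LIFE_MIN)
        sd = sigma0 * np.sqrt(np.maximum(clean, 0.01) / (schedule.duration_min * df))
        clean = clean + sd * rng.standard_normal(clean.size)
    w = WeightScheme("frame").weights(schedule)
    return TissueTAC(roi, schedule, clean, w)


def generate_subject(pop: PopulationSpec, input_spec: InputFunctionSpec,
                     seed: int, group: str = "RRMS",
                     subject_id: str | None = None,
                     schedule: FrameSchedule | None = None) -> SubjectDataset:
    """Simulate one subject: blood data plus noisy TACs for every ROI.

    Whole-brain GM/WM TACs are generated from the tissue-class mean
    parameters (with the subject's drawn class k4); regional ROIs draw
    their own K1, k2, k3 and VB but share the class k4. RRMS subjects get
    T2 and gadolinium-enhancing lesion ROIs derived from white matter.
    """
    if group not in ("RRMS", "HC"):
        raise ValueError("group must be 'RRMS' or 'HC'")
    rng = np.random.default_rng(seed)
    schedule = schedule or default_schedule()
    subject_id = subject_id or f"{group}_{seed}"

    truth, continuous, samples = generate_input_function(
        input_spec, seed=int(rng.integers(2 ** 31)))

    k4_cls = {}
    for cls in ("GM", "WM"):
        mean, sd = pop.populations[(group, cls)]["k4"]
        k4_cls[cls] = _draw(rng, mean, sd, _TRUNC_LO, DEFAULT_BOUNDS["k4"][1])

    params: dict[str, KineticParameters] = {}
    classes: dict[str, str] = {}
    for cls, wb_label in (("GM", "whole_brain_GM"), ("WM", "whole_brain_WM")):
        stats = pop.populations[(group, cls)]
        params[wb_label] = KineticParameters(
            "2T4k", K1=stats["K1"][0], k2=stats["k2"][0], k3=stats["k3"][0],
            k4=k4_cls[cls], VB=stats["VB"][0])
        classes[wb_label] = cls
    for roi in pop.gm_rois:
        params[roi] = _draw_params(rng, pop.populations[(group, "GM")], k4_cls["GM"])
        classes[roi] = "GM"
    for roi in pop.wm_rois:
        params[roi] = _draw_params(rng, pop.populations[(group, "WM")], k4_cls["WM"])
        classes[roi] = "WM"
    if group == "RRMS":
        wm_stats = pop.populations[(group, "WM")]
        base_t2 = _draw_params(rng, wm_stats, k4_cls["WM"])
        params["T2_lesion"] = replace(base_t2, k3=base_t2.k3 * pop.t2_k3_mult)
        classes["T2_lesion"] = "T2lesion"
        base_gd = _draw_params(rng, wm_stats, k4_cls["WM"])
        params["Gd_lesion"] = replace(
            base_gd, k3=base_gd.k3 * pop.gd_k3_mult,
            K1=min(base_gd.K1 * pop.gd_k1_mult, DEFAULT_BOUNDS["K1"][1]))
        classes["Gd_lesion"] = "GdLesion"

    tacs = {roi: _noisy_tac(rng, roi, p, truth, schedule, pop.sigma0)
            for roi, p in params.items()}
    return SubjectDataset(subject_id=subject_id, group=group, seed=seed,
                          true_params=params, tissue_class=classes,
                          true_inputs=truth, continuous_blood=continuous,
                          manual_samples=samples, tacs=tacs)


def generate_cohort(pop: PopulationSpec, seed: int,
                    input_spec: InputFunctionSpec | None = None,
                    schedule: FrameSchedule | None = None) -> list[SubjectDataset]:
    """Simulate a full cohort (default 5 RRMS patients + 5 controls)."""
    input_spec = input_spec or InputFunctionSpec()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(pop.n_rrms):
        subjects.append(generate_subject(pop, input_spec,
                                         seed=int(rng.integers(2 ** 31)),
                                         group="RRMS", subject_id=f"MS{i + 1}",
                                         schedule=schedule))
    for i in range(pop.n_hc):
        subjects.append(generate_subject(pop, input_spec,
                                         seed=int(rng.integers(2 ** 31)),
                                         group="HC", subject_id=f"HC{i + 1}",
                                         schedule=schedule))
    return subjects
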