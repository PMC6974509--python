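"""Cohort-level analysis: reliability filtering, group comparison of the
macro endpoints (VT, BPND), lesion contrasts, and the scan-duration
truncation analysis with linear-regression and Bland-Altman agreement.

The cohort table is a plain pandas DataFrame with one row per
subject x ROI carrying the fitted micro parameters, the macro endpoints
and the per-parameter %SE values; every operation here consumes and
returns such tables, so results stay inspectable and serialisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import SE_CUTOFFS, DualStageResult, FitResult, WeightScheme, run_dual_stage
from .input_function import InputFunctionSet

__all__ = [
    "AgreementStats",
    "GroupComparison",
    "build_cohort_table",
    "apply_reliability_filter",
    "group_compare",
    "lesion_contrast",
    "bland_altman",
    "linear_agreement",
    "truncation_analysis",
]

COHORT_COLUMNS = [
    "subject", "group", "roi", "tissue_class",
    "K1", "k2", "k3", "k4", "VB",
    "VT", "BPND", "VND", "K1k2",
    "se_K1", "se_k2", "se_k3", "se_k4", "se_VB",
    "included", "exclusion_reason",
]


@dataclass(frozen=True)
class AgreementStats:
    """Linear-regression plus Bland-Altman agreement between two
    measurement conditions (y regressed on x; differences are y - x)."""

    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test on one endpoint in one ROI."""

    endpoint: str
    roi: str
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# Table construction and filtering
# ---------------------------------------------------------------------------

def build_cohort_table(per_subject: Mapping[str, tuple[str, Mapping[str, str],
                                                       Mapping[str, FitResult]]]
                       ) -> pd.DataFrame:
    """Assemble the cohort table from per-subject fit results.

    ``per_subject`` maps subject id -> (group, roi -> tissue class,
    roi -> FitResult).
    """
    rows = []
    for subject, (group, classes, fits) in per_subject.items():
        for roi, fit in fits.items():
            est = fit.estimates
            row = {
                "subject": subject, "group": group, "roi": roi,
                "tissue_class": classes.get(roi, "GM"),
                "K1": est.K1, "k2": est.k2, "k3": est.k3, "k4": est.k4,
                "VB": est.VB,
                "VT": fit.macro.VT, "BPND": fit.macro.BPND,
                "VND": fit.macro.VND, "K1k2": fit.macro.K1k2,
                "included": True, "exclusion_reason": "",
            }
            for name in ("K1", "k2", "k3", "k4", "VB"):
                row[f"se_{name}"] = fit.percent_se.get(name, np.nan)
            rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def apply_reliability_filter(table: pd.DataFrame,
                             cutoffs: Mapping[str, float] | None = None,
                             mode: str = "full",
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag subject x ROI rows with unreliable parameter estimates.

    ``full`` mode excludes a row when any parameter's %SE is strictly
    above its cutoff (25% for K1, k2, VB; 50% for k3, k4); ``k3-only``
    applies only the k3 > 50% rule. A %SE exactly at the cutoff is
    retained. Returns the annotated table and an exclusion log.
    """
    if mode not in ("full", "k3-only"):
        raise ValueError("mode must be 'full' or 'k3-only'")
    cutoffs = dict(cutoffs or SE_CUTOFFS)
    checked = ("k3",) if mode == "k3-only" else tuple(cutoffs)

    out = table.copy()
    out["included"] = True
    out["exclusion_reason"] = ""
    log_rows = []
    for idx, row in out.iterrows():
        reasons = []
        for name in checked:
            se = row.get(f"se_{name}", np.nan)
            if pd.isna(se):
                continue
            if se > cutoffs[name]:
                reasons.append(f"{name} %SE {se:.1f} > {cutoffs[name]:g}")
        if reasons:
            out.at[idx, "included"] = False
            out.at[idx, "exclusion_reason"] = "; ".join(reasons)
            log_rows.append({"subject": row["subject"], "roi": row["roi"],
                             "reason": "; ".join(reasons)})
    log = pd.DataFrame(log_rows, columns=["subject", "roi", "reason"])
    return out, log


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_compare(table: pd.DataFrame, endpoint: str, roi: str,
                  group_a: str = "RRMS", group_b: str = "HC",
                  variant: str = "student") -> GroupComparison:
    """Independent two-sample t-test on an endpoint within one ROI.

    ``student`` is the pooled-variance test; ``welch`` drops the
    equal-variance assumption. Only rows flagged ``included`` enter.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    sub = table[(table["roi"] == roi) & table["included"]]
    a = sub.loc[sub["group"] == group_a, endpoint].dropna().to_numpy(float)
    b = sub.loc[sub["group"] == group_b, endpoint].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"group(s) too small after filtering for {endpoint}/{roi}: "
            f"n({group_a})={len(a)}, n({group_b})={len(b)}")
    equal_var = variant == "student"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        dof = float(len(a) + len(b) - 2)
    else:
        dof = float(res.df)
    return GroupComparison(endpoint=endpoint, roi=roi, t=float(res.statistic),
                           df=dof, p=float(res.pvalue),
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           group_a=group_a, group_b=group_b,
                           n_a=len(a), n_b=len(b))


_LESION_ORDER = ("WM", "T2lesion", "GdLesion")


def lesion_contrast(subject_table: pd.DataFrame,
                    endpoints: Sequence[str] = ("BPND", "VT", "K1k2"),
                    ) -> dict[str, dict[str, float | None]]:
    """Descriptive lesion contrast for one subject.

    Returns, for each endpoint, the value in non-lesional white matter, T2
    lesions and gadolinium-enhancing lesions (tissue classes WM, T2lesion,
    GdLesion; averaged if several ROIs share a class). Missing or filtered
    compartments yield ``None`` — partial output is flagged, not an error.
    No inferential statistics are attached: with a handful of analysable
    subjects the contrast is descriptive.
    """
    out: dict[str, dict[str, float | None]] = {}
    inc = subject_table[subject_table["included"]]
    for ep in endpoints:
        vals: dict[str, float | None] = {}
        for cls in _LESION_ORDER:
            v = inc.loc[inc["tissue_class"] == cls, ep].dropna()
            vals[cls] = float(v.mean()) if len(v) else None
        out[ep] = vals
    return out


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(x: Iterable[float], y: Iterable[float]) -> AgreementStats:
    """Bland-Altman agreement: bias = mean(y - x), limits of agreement
    bias +/- 1.96 * SD(y - x) (sample SD, n-1). Regression fields are NaN;
    use :func:`linear_agreement` for the combined statistics."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired values")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(slope=np.nan, intercept=np.nan, r_squared=np.nan,
                          bias=bias, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd)


def linear_agreement(x: Iterable[float], y: Iterable[float]) -> AgreementStats:
    """Linear regression of y on x plus Bland-Altman statistics."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    ba = bland_altman(x, y)
    if np.allclose(x, x[0]):
        raise ValueError("regression undefined for constant x")
    reg = stats.linregress(x, y)
    return AgreementStats(slope=float(reg.slope), intercept=float(reg.intercept),
                          r_squared=float(reg.rvalue ** 2), bias=ba.bias,
                          loa_low=ba.loa_low, loa_high=ba.loa_high)


# ---------------------------------------------------------------------------
# Scan-duration truncation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncationResult:
    """Truncated-versus-full comparison of the macro endpoints."""

    cut_minutes: float
    table: pd.DataFrame                  # per subject x ROI, both durations
    agreement: dict[str, AgreementStats]  # endpoint -> stats


def truncation_analysis(subjects: Sequence, inputs: Sequence[InputFunctionSet],
                        full_results: Sequence[DualStageResult] | None = None,
                        cut_minutes: float = 60.0,
                        weights: WeightScheme | None = None,
                        n_starts: int = 10, seed: int = 0,
                        filter_mode: str = "full") -> TruncationResult:
    """Repeat the two-stage analysis on time-truncated data.

    Frames whose start time is at or beyond ``cut_minutes`` are dropped
    (whole frames only), the complete two-stage fixed-k4 pipeline is
    re-run per subject, and the truncated macro endpoints are compared
    with the full-duration ones by regression and Bland-Altman analysis
    across all subject x ROI pairs that pass the reliability filter under
    both durations.

    ``subjects`` are objects exposing ``subject_id``, ``group``, ``tacs``
    and ``tissue_class`` (e.g. :class:`petkin.synthetic.SubjectDataset`);
    ``inputs`` is the parallel list of input-function sets. Full-duration
    results are computed if not supplied.
    """
    if cut_minutes < 30.0:
        raise ValueError("cut time must be >= 30 min")
    if len(subjects) != len(inputs):
        raise ValueError("subjects and inputs must be parallel")

    def _to_table(results):
        per_subject = {
            s.subject_id: (s.group, s.tissue_class, r.stage2)
            for s, r in zip(subjects, results)
        }
        tab, _ = apply_reliability_filter(build_cohort_table(per_subject),
                                          mode=filter_mode)
        return tab

    if full_results is None:
        full_results = [
            run_dual_stage(s.tacs, s.tissue_class, inp, weights=weights,
                           n_starts=n_starts, seed=seed)
            for s, inp in zip(subjects, inputs)
        ]
    trunc_results = []
    for s, inp in zip(subjects, inputs):
        cut_tacs = {roi: tac.truncate(cut_minutes) for roi, tac in s.tacs.items()}
        if next(iter(cut_tacs.values())).schedule.n_frames < 8:
            raise ValueError("too few frames after truncation")
        trunc_results.append(run_dual_stage(cut_tacs, s.tissue_class, inp,
                                            weights=weights, n_starts=n_starts,
                                            seed=seed))

    full_tab = _to_table(full_results)
    trunc_tab = _to_table(trunc_results)
    merged = full_tab.merge(trunc_tab, on=["subject", "group", "roi", "tissue_class"],
                            suffixes=("_full", "_trunc"))
    agreement = {}
    for ep in ("VT", "BPND"):
        ok = merged[f"included_full"] & merged[f"included_trunc"]
        x = merged.loc[ok, f"{ep}_full"].to_numpy(float)
        y = merged.loc[ok, f"{ep}_trunc"].to_numpy(float)
        good = np.isfinite(x) & np.isfinite(y)
        agreement[ep] = linear_agreement(x[good], y[good])
    return TruncationResult(cut_minutes=cut_minutes, table=merged,
                            agreement=agreement)
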