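"""Diagnostics and group statistics.

* Mean-beta confound table: average beta per ROI and condition, with the
  absolute verbal - spatial difference per search type. A large uniform
  difference flags ROIs whose decoding may ride on response magnitude
  rather than multivoxel structure.
* 2x2 repeated-measures ANOVA (e.g. hemisphere x session) on decoding
  accuracies, each effect tested against its own subject-by-effect error
  term.
* Paired t-test with an explicit degenerate flag for zero-variance
  differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import CONDITIONS_OF_INTEREST, SEARCH_TYPES, domain_of, search_of


@dataclass
class ConfoundTable:
    """Mean betas per (ROI, condition) and |verbal - spatial| differences."""

    means: pd.DataFrame  # index roi, columns = conditions of interest
    sds: pd.DataFrame  # between-subject sd of the per-subject means
    differences: pd.DataFrame  # index roi, columns = search types

    def max_difference(self) -> tuple[str, str, float]:
        """(roi, search, value) of the largest absolute difference."""
        stacked = self.differences.stack()
        roi, search = stacked.idxmax()
        return str(roi), str(search), float(stacked.max())


def mean_beta_table(pattern_sets: dict[str, list]) -> ConfoundTable:
    """Average beta per ROI and condition across voxels, runs and subjects.

    ``pattern_sets`` maps ROI name to one complete 16-sample
    :class:`~rulemvpa.decoding.BetaPatternSet` per subject. Cell means
    average the per-subject means (voxels, then runs); cell sds are
    between-subject. Differences are |verbal - spatial| of cell means per
    search type.
    """
    means, sds, diffs = {}, {}, {}
    for roi_name, subject_sets in pattern_sets.items():
        per_subject = {c: [] for c in CONDITIONS_OF_INTEREST}
        for ps in subject_sets:
            for cond in CONDITIONS_OF_INTEREST:
                rows = (ps.domains == domain_of(cond)) & (ps.searches == search_of(cond))
                if not rows.any():
                    raise ValueError(
                        f"ROI {roi_name!r}, subject {ps.subject}: no samples for {cond!r}"
                    )
                per_subject[cond].append(float(ps.X[rows].mean()))
        means[roi_name] = {c: float(np.mean(v)) for c, v in per_subject.items()}
        sds[roi_name] = {
            c: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for c, v in per_subject.items()
        }
        diffs[roi_name] = {}
        for search in SEARCH_TYPES:
            verbal = means[roi_name][f"disc_verbal_{search}"]
            spatial = means[roi_name][f"disc_spatial_{search}"]
            diffs[roi_name][search] = abs(verbal - spatial)
    rois = list(pattern_sets)
    return ConfoundTable(
        means=pd.DataFrame(means).T.loc[rois, list(CONDITIONS_OF_INTEREST)],
        sds=pd.DataFrame(sds).T.loc[rois, list(CONDITIONS_OF_INTEREST)],
        differences=pd.DataFrame(diffs).T.loc[rois, list(SEARCH_TYPES)],
    )


@dataclass
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    factor_names: tuple[str, str]
    ss_total: float
    ss_components: dict[str, float] = field(default_factory=dict)


def rm_anova_2x2(
    data: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> AnovaResult:
    """Two-way repeated-measures ANOVA for a 2x2 within-subject design.

    ``data`` has shape (n_subjects, 2, 2), axis 1 = factor A, axis 2 =
    factor B. Each effect's F uses the matching subject-by-effect
    interaction as the error term; all dfs are (1, n_subjects - 1).
    Sphericity corrections are moot for 2-level factors.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1:] != (2, 2):
        raise ValueError("data must have shape (n_subjects, 2, 2)")
    if np.isnan(data).any():
        raise ValueError("missing cells: the design must be complete and balanced")
    n = data.shape[0]
    if n < 2:
        raise ValueError("at least 2 subjects required")

    grand = data.mean()
    m_a = data.mean(axis=(0, 2))  # level means of factor A
    m_b = data.mean(axis=(0, 1))
    m_s = data.mean(axis=(1, 2))  # subject means
    m_as = data.mean(axis=2)  # (n, 2)
    m_bs = data.mean(axis=1)  # (n, 2)
    m_ab = data.mean(axis=0)  # (2, 2)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)  # b levels * n subjects per mean
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_s = 4 * np.sum((m_s - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs)

    df_err = n - 1

    # sums of squares that are pure rounding noise are snapped to zero
    ss_tol = 1e-12 * max(float(ss_total), 1e-300)

    def effect(ss_eff: float, ss_err: float) -> EffectResult:
        ss_eff = 0.0 if ss_eff < ss_tol else ss_eff
        ss_err = 0.0 if ss_err < ss_tol else ss_err
        ms_eff = ss_eff / 1
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (np.inf if ms_eff > 0 else 0.0)
        p = float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        if F == 0.0:
            p = 1.0
        return EffectResult(F=float(F), df=(1, df_err), p=p, ss_effect=float(ss_eff), ss_error=float(ss_err))

    a_name, b_name = factor_names
    return AnovaResult(
        effects={
            a_name: effect(ss_a, ss_as),
            b_name: effect(ss_b, ss_bs),
            f"{a_name}*{b_name}": effect(ss_ab, ss_abs),
        },
        factor_names=(a_name, b_name),
        ss_total=float(ss_total),
        ss_components={
            a_name: float(ss_a),
            b_name: float(ss_b),
            f"{a_name}*{b_name}": float(ss_ab),
            "subject": float(ss_s),
            f"{a_name}*subject": float(ss_as),
            f"{b_name}*subject": float(ss_bs),
            f"{a_name}*{b_name}*subject": float(ss_abs),
        },
    )


@dataclass
class TTestResult:
    t: float
    df: int
    p: float  # two-tailed
    mean_difference: float
    degenerate: bool = False


def paired_t(x, y) -> TTestResult:
    """Paired t-test on the differences x - y, two-tailed.

    Zero-variance differences are flagged degenerate instead of raising:
    t = 0, p = 1 when the mean difference is also zero, else t = +/-inf,
    p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 2:
        raise ValueError("at least 2 pairs required")
    d = x - y
    n = len(d)
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(d) == 0.0:  # identical differences: exact zero variance
        md = float(d[0])
        if md == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, mean_difference=0.0, degenerate=True)
        t = np.inf if md > 0 else -np.inf
        return TTestResult(t=float(t), df=n - 1, p=0.0, mean_difference=md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, mean_difference=md)
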