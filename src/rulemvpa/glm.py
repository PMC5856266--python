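"""General linear model: canonical HRF, design matrices, per-voxel OLS,
t-contrasts, and the group-level one-sample t map.

Design matrices use the concatenated-run layout: one boxcar-convolved-HRF
column per (condition, run) pair for conditions present in that run, six
motion columns per run, and one constant column per run. With the eight
task conditions present in all four runs this yields the 8 x 4 = 32
condition betas per session that the decoder consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .conditions import ALL_CONDITIONS

logger = logging.getLogger(__name__)

#: Support of the canonical HRF in seconds.
HRF_DURATION_S = 32.0
#: Microtime oversampling factor for boxcar convolution.
DEFAULT_OVERSAMPLING = 16


@dataclass(frozen=True)
class HRFKernel:
    """Sampled double-gamma impulse response, rescaled to unit peak."""

    dt: float
    values: np.ndarray

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = HRF_DURATION_S,
) -> HRFKernel:
    """Canonical double-gamma HRF sampled on [0, duration] at step ``dt``.

    h(t) = Gamma(t; a1=peak_delay, b=dispersion)
         - ratio * Gamma(t; a2=undershoot_delay, b=dispersion),
    rescaled so the peak equals 1. The peak sits near 5 s; the undershoot
    near 15 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = sps.gamma.pdf(t, peak_delay, scale=dispersion) - undershoot_ratio * sps.gamma.pdf(
        t, undershoot_delay, scale=dispersion
    )
    return HRFKernel(dt=dt, values=h / h.max())


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # time x regressors
    labels: tuple[str, ...]  # one per column
    frame_times: np.ndarray  # seconds, concatenated runs
    run_slices: tuple[slice, ...] = ()  # row slice per run

    def __post_init__(self):
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("column labels must be unique")

    def column_index(self, label: str) -> int:
        return self.labels.index(label)

    def condition_columns(self, condition: str) -> list[int]:
        return [
            i
            for i, lab in enumerate(self.labels)
            if lab.startswith("run") and lab.split(":", 1)[1] == condition
        ]


def condition_regressors(
    epochs,
    tr: float,
    n_scans: int,
    hrf: HRFKernel | None = None,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> tuple[np.ndarray, list[str]]:
    """Boxcar-convolved-HRF regressors for one run, sampled at frame times.

    Returns (n_scans x n_conditions_present) array and the condition
    labels in canonical order. The boxcar is built on a microtime grid of
    ``tr / oversampling`` and sampled at frame onsets (t = i * tr).
    """
    dt = tr / oversampling
    hrf = hrf or canonical_hrf(dt)
    if abs(hrf.dt - dt) > 1e-12:
        hrf = canonical_hrf(dt)
    run_len = n_scans * tr
    n_fine = int(np.ceil(run_len / dt)) + 1
    fine_t = np.arange(n_fine) * dt

    present = [c for c in ALL_CONDITIONS if any(e.condition == c for e in epochs)]
    cols = np.zeros((n_scans, len(present)))
    for j, cond in enumerate(present):
        boxcar = np.zeros(n_fine)
        for e in epochs:
            if e.condition != cond:
                continue
            if e.onset + e.duration > run_len + 1e-9:
                raise ValueError(
                    f"epoch {cond!r} at {e.onset:.2f}s (+{e.duration:.2f}s) "
                    f"exceeds the run window of {run_len:.2f}s"
                )
            i0 = int(round(e.onset / dt))
            i1 = int(round((e.onset + e.duration) / dt))
            boxcar[i0:i1] = 1.0
        conv = np.convolve(boxcar, hrf.values)[:n_fine]
        frame_idx = (np.arange(n_scans) * oversampling).astype(int)
        cols[:, j] = conv[frame_idx]
    return cols, present


def build_design_matrix(
    run_designs,
    tr: float,
    n_scans,
    motion=None,
    hrf: HRFKernel | None = None,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> DesignMatrix:
    """Concatenated-run design matrix.

    Parameters
    ----------
    run_designs : sequence of epoch lists, one per run (run order = run id)
    n_scans : sequence of scan counts per run
    motion : optional sequence of (n_scans, 6) motion traces per run

    Columns, in order: condition columns grouped by run (canonical
    condition order within run, conditions absent from a run get no
    column), then motion columns per run, then one constant per run.
    """
    n_runs = len(run_designs)
    if motion is not None and len(motion) != n_runs:
        raise ValueError("one motion trace block per run required")
    total = int(np.sum(n_scans))
    row0 = np.concatenate([[0], np.cumsum(n_scans)]).astype(int)
    run_slices = tuple(slice(row0[r], row0[r + 1]) for r in range(n_runs))

    cond_blocks, cond_labels = [], []
    for r, epochs in enumerate(run_designs, start=1):
        try:
            cols, present = condition_regressors(
                epochs, tr, int(n_scans[r - 1]), hrf=hrf, oversampling=oversampling
            )
        except ValueError as err:
            raise ValueError(f"run {r}: {err}") from err
        cond_blocks.append(cols)
        cond_labels.extend(f"run{r}:{c}" for c in present)

    columns, labels = [], []
    for r in range(n_runs):
        block = np.zeros((total, cond_blocks[r].shape[1]))
        block[run_slices[r]] = cond_blocks[r]
        columns.append(block)
    labels.extend(cond_labels)

    if motion is not None:
        for r in range(n_runs):
            m = np.asarray(motion[r], dtype=float)
            if m.shape[0] != n_scans[r]:
                raise ValueError(f"run {r + 1}: motion rows != scan count")
            block = np.zeros((total, m.shape[1]))
            block[run_slices[r]] = m - m.mean(axis=0)  # center within run
            columns.append(block)
            labels.extend(f"run{r + 1}:motion{j + 1}" for j in range(m.shape[1]))

    for r in range(n_runs):
        block = np.zeros((total, 1))
        block[run_slices[r]] = 1.0
        columns.append(block)
        labels.append(f"run{r + 1}:constant")

    frame_times = np.concatenate(
        [np.arange(int(n_scans[r])) * tr for r in range(n_runs)]
    )
    return DesignMatrix(
        matrix=np.hstack(columns),
        labels=tuple(labels),
        frame_times=frame_times,
        run_slices=run_slices,
    )


@dataclass
class BetaMaps:
    """Per-column OLS estimates on a voxel grid, plus residual variance."""

    beta: np.ndarray  # (n_columns, *grid_shape)
    labels: tuple[str, ...]
    design: DesignMatrix
    dof: int
    resvar: np.ndarray  # grid_shape, RSS / dof
    grid_shape: tuple[int, int, int]

    def condition_beta(self, condition: str, run: int) -> np.ndarray:
        label = f"run{run}:{condition}"
        if label not in self.labels:
            raise KeyError(f"no beta for condition {condition!r} in run {run}")
        return self.beta[self.labels.index(label)]

    def condition_volumes(self, conditions, runs) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        missing = []
        for c in conditions:
            for r in runs:
                try:
                    out[(c, r)] = self.condition_beta(c, r)
                except KeyError:
                    missing.append((c, r))
        if missing:
            raise KeyError(f"missing (condition, run) betas: {missing}")
        return out


def fit_glm(bold_runs, X: DesignMatrix) -> BetaMaps:
    """Per-voxel ordinary least squares over concatenated runs.

    ``bold_runs`` is a sequence of 4D arrays (x, y, z, t), one per run.
    Rank-deficient designs are solved by pseudoinverse with a warning.
    """
    grids = {r.shape[:3] for r in bold_runs}
    if len(grids) != 1:
        raise ValueError("all runs must share the voxel grid")
    grid_shape = grids.pop()
    Y = np.concatenate([r.reshape(-1, r.shape[3]).T for r in bold_runs], axis=0)
    n, p = X.matrix.shape
    if Y.shape[0] != n:
        raise ValueError(
            f"design matrix has {n} rows but data have {Y.shape[0]} scans"
        )
    rank = int(np.linalg.matrix_rank(X.matrix))
    if rank < p:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            "using pseudoinverse",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("rank-deficient design matrix: rank %d < %d columns", rank, p)
    pinv = np.linalg.pinv(X.matrix)
    beta = pinv @ Y  # p x voxels
    resid = Y - X.matrix @ beta
    dof = n - rank
    rss = np.einsum("ij,ij->j", resid, resid)
    resvar = rss / dof if dof > 0 else np.full(rss.shape, np.nan)
    return BetaMaps(
        beta=beta.reshape(p, *grid_shape),
        labels=X.labels,
        design=X,
        dof=dof,
        resvar=resvar.reshape(grid_shape),
        grid_shape=grid_shape,
    )


@dataclass
class StatMap:
    values: np.ndarray  # 3D t (or z) volume
    dof: int
    contrast: np.ndarray | None = None


def _expand_contrast(betas: BetaMaps, weights: dict[str, float]) -> np.ndarray:
    """Expand per-condition weights over run columns, 1/n_runs each."""
    c = np.zeros(len(betas.labels))
    for cond, w in weights.items():
        cols = [
            i
            for i, lab in enumerate(betas.labels)
            if lab.startswith("run") and lab.split(":", 1)[1] == cond
        ]
        if not cols:
            raise KeyError(f"contrast weight on unknown condition {cond!r}")
        for i in cols:
            c[i] = w / len(cols)
    return c


def contrast_estimate(betas: BetaMaps, weights: dict[str, float]) -> np.ndarray:
    """Voxel-wise contrast of parameter estimates c'beta."""
    c = _expand_contrast(betas, weights)
    flat = betas.beta.reshape(len(betas.labels), -1)
    return (c @ flat).reshape(betas.grid_shape)


def contrast_t(betas: BetaMaps, weights: dict[str, float]) -> StatMap:
    """t = c'beta / sqrt(sigma^2 * c'(X'X)^- c), per voxel."""
    c = _expand_contrast(betas, weights)
    est = contrast_estimate(betas, weights)
    xtx_pinv = np.linalg.pinv(betas.design.matrix.T @ betas.design.matrix)
    var_scale = float(c @ xtx_pinv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(betas.resvar * var_scale)
    t[~np.isfinite(t) & (est == 0)] = 0.0
    return StatMap(values=t, dof=betas.dof, contrast=c)


#: Localizer contrast: rule-discovery conditions +1 each, controls -2 each.
LOCALIZER_WEIGHTS: dict[str, float] = {
    "disc_spatial_separate": 1.0,
    "disc_verbal_separate": 1.0,
    "disc_spatial_parallel": 1.0,
    "disc_verbal_parallel": 1.0,
    "ctrl_spatial": -2.0,
    "ctrl_verbal": -2.0,
}


def group_map(contrast_volumes) -> StatMap:
    """Voxel-wise one-sample t over subjects' contrast estimates.

    Zero-variance voxels with a nonzero mean are flagged infinite (with
    the mean's sign), never NaN; zero-mean zero-variance voxels get t=0.
    """
    vols = [np.asarray(v, dtype=float) for v in contrast_volumes]
    if len(vols) < 2:
        raise ValueError("group map needs at least 2 subjects")
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError("subject grids are misaligned")
    data = np.stack(vols)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # exact zero variance (np.std of a constant array can round to ~1e-16)
    zero_sd = np.ptp(data, axis=0) == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    return StatMap(values=t, dof=n - 1)
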