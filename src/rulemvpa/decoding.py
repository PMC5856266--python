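"""Multivoxel decoding of rule domain from beta patterns.

Patterns are per-ROI matrices of GLM betas (one row per condition x run,
16 rows when complete; 8 per search type). Domain (verbal vs spatial) is
decoded with a linear maximum-margin classifier under leave-one-run-out
cross-validation; significance comes from a within-run label-permutation
null (default 1000 permutations, 95th percentile criterion). Betas are
not normalized by default, so a uniform magnitude difference between the
classes is allowed to drive the classifier — that confound is diagnosed,
not removed (see :mod:`rulemvpa.stats`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.svm import SVC

from ._seeds import rng_for
from .conditions import CONDITIONS_OF_INTEREST, SEARCH_TYPES, domain_of, search_of

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0
DEFAULT_N_PERM = 1000
PERCENTILE = 95.0


@dataclass
class BetaPatternSet:
    """Samples x voxels betas for one subject/session/ROI, with labels."""

    X: np.ndarray  # (n_samples, n_voxels)
    domains: np.ndarray  # per-sample domain label
    searches: np.ndarray  # per-sample search label
    runs: np.ndarray  # per-sample run id
    subject: int = 0
    session: int = 0
    roi: str = ""

    def __post_init__(self):
        n = self.X.shape[0]
        for arr in (self.domains, self.searches, self.runs):
            if len(arr) != n:
                raise ValueError("label arrays must match the sample count")

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "BetaPatternSet":
        return BetaPatternSet(
            X=self.X[mask],
            domains=self.domains[mask],
            searches=self.searches[mask],
            runs=self.runs[mask],
            subject=self.subject,
            session=self.session,
            roi=self.roi,
        )

    def split_by_search(self) -> dict[str, "BetaPatternSet"]:
        """Two 8-sample subsets, one per search type."""
        return {s: self.subset(self.searches == s) for s in SEARCH_TYPES}

    def with_voxels(self, voxel_idx: np.ndarray) -> "BetaPatternSet":
        out = self.subset(np.ones(len(self.runs), dtype=bool))
        out.X = self.X[:, voxel_idx]
        return out


def extract_patterns(
    beta_source,
    roi_mask: np.ndarray,
    conditions=CONDITIONS_OF_INTEREST,
    runs=None,
    normalize: bool = False,
    subject: int = 0,
    session: int = 0,
    roi: str = "",
) -> BetaPatternSet:
    """Assemble the ROI's beta pattern matrix.

    ``beta_source`` is either a :class:`rulemvpa.glm.BetaMaps` or a
    mapping ``(condition, run) -> 3D beta volume``. Row order is
    deterministic: run-major, conditions in canonical order within run.
    Voxel order is the mask's scan (C) order. With ``normalize`` each row
    is z-scored across voxels (off by default: magnitude differences are
    reported downstream rather than removed).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    if hasattr(beta_source, "condition_beta"):
        if runs is None:
            run_ids = sorted(
                {
                    int(lab.split(":", 1)[0][3:])
                    for lab in beta_source.labels
                    if lab.split(":", 1)[1] in conditions
                }
            )
        else:
            run_ids = list(runs)
        volumes = beta_source.condition_volumes(conditions, run_ids)
    else:
        volumes = dict(beta_source)
        run_ids = sorted({r for (_, r) in volumes}) if runs is None else list(runs)
        missing = [(c, r) for c in conditions for r in run_ids if (c, r) not in volumes]
        if missing:
            raise KeyError(f"missing (condition, run) betas: {missing}")

    rows, dom, sea, rn = [], [], [], []
    for r in run_ids:
        for cond in conditions:
            vol = volumes[(cond, r)]
            if vol.shape != roi_mask.shape:
                raise ValueError("ROI mask shape does not match the beta grid")
            rows.append(vol[roi_mask])
            dom.append(domain_of(cond))
            sea.append(search_of(cond))
            rn.append(r)
    X = np.asarray(rows, dtype=float)
    if normalize:
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    return BetaPatternSet(
        X=X,
        domains=np.asarray(dom),
        searches=np.asarray(sea),
        runs=np.asarray(rn),
        subject=subject,
        session=session,
        roi=roi,
    )


def _predict_linear_svm(X_train, y_train, X_test, C: float) -> np.ndarray:
    """Linear max-margin prediction; decision ties go to the first class
    (lexicographic) and are logged."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_train, y_train)
    dec = clf.decision_function(X_test)
    n_ties = int(np.sum(dec == 0))
    if n_ties:
        logger.debug("%d tied decision values broken toward %r", n_ties, clf.classes_[0])
    return np.where(dec > 0, clf.classes_[1], clf.classes_[0])


@dataclass
class SubjectDecoding:
    fold_accuracies: np.ndarray  # one per held-out run
    subject: int = 0

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def loro_decode(
    patterns: BetaPatternSet,
    C: float = DEFAULT_C,
    labels: np.ndarray | None = None,
) -> SubjectDecoding:
    """Leave-one-run-out cross-validated domain decoding.

    Each fold trains on all runs but one and tests on the held-out run;
    the subject accuracy is the mean over folds. ``labels`` overrides the
    domain labels (used by the permutation machinery).
    """
    y = patterns.domains if labels is None else np.asarray(labels)
    run_ids = np.unique(patterns.runs)
    for r in run_ids:
        counts = {lab: int(np.sum(y[patterns.runs == r] == lab)) for lab in np.unique(y)}
        if len(counts) != 2 or set(counts.values()) != {1}:
            raise ValueError(
                f"run {r} must contribute exactly one sample per class, got {counts}"
            )
    folds = []
    for r in run_ids:
        test = patterns.runs == r
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"a class is missing from the training folds for run {r}")
        pred = _predict_linear_svm(patterns.X[train], y[train], patterns.X[test], C)
        folds.append(float(np.mean(pred == y[test])))
    return SubjectDecoding(fold_accuracies=np.asarray(folds), subject=patterns.subject)


@dataclass
class DecodingResult:
    subject_accuracies: np.ndarray
    fold_accuracies: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.subject_accuracies))

    @property
    def sem(self) -> float:
        n = len(self.subject_accuracies)
        if n < 2:
            return 0.0
        return float(np.std(self.subject_accuracies, ddof=1) / np.sqrt(n))


def group_decode(all_subject_patterns, C: float = DEFAULT_C) -> DecodingResult:
    """LORO decoding per subject, then group mean and SEM (= sd/sqrt(n))."""
    if not all_subject_patterns:
        raise ValueError("at least one subject required")
    per_subject = [loro_decode(p, C=C) for p in all_subject_patterns]
    return DecodingResult(
        subject_accuracies=np.asarray([s.accuracy for s in per_subject]),
        fold_accuracies=[s.fold_accuracies for s in per_subject],
    )


@dataclass
class NullDistribution:
    values: np.ndarray  # n_perm group-mean accuracies
    seed: int

    @property
    def critical_value(self) -> float:
        """Empirical 95th percentile, 'higher' interpolation (conservative)."""
        return float(np.percentile(self.values, PERCENTILE, method="higher"))

    def is_significant(self, observed: float) -> bool:
        return observed > self.critical_value


def _relabeling_accuracies(patterns: BetaPatternSet, C: float) -> np.ndarray:
    """LORO accuracy for every distinct within-run relabeling.

    With one verbal and one spatial sample per run, permuting labels
    within run means swapping (or not) each run's pair: 2^n_runs distinct
    relabelings. Their accuracies are precomputed so the permutation null
    samples exactly from this table.
    """
    run_ids = np.unique(patterns.runs)
    accs = np.empty(2 ** len(run_ids))
    for i, swaps in enumerate(product((False, True), repeat=len(run_ids))):
        y = patterns.domains.copy()
        for r, swap in zip(run_ids, swaps):
            if swap:
                idx = np.nonzero(patterns.runs == r)[0]
                y[idx] = y[idx][::-1]
        accs[i] = loro_decode(patterns, C=C, labels=y).accuracy
    return accs


def permutation_null(
    all_subject_patterns,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> NullDistribution:
    """Group-level permutation null of the LORO accuracy.

    Per iteration and independently per subject, domain labels are
    permuted within run (each run's verbal/spatial pair swapped or not,
    uniformly at random), the LORO accuracy is recomputed, and the group
    mean is recorded.
    """
    if n_perm < 100:
        warnings.warn(
            "n_perm < 100: the 95th-percentile critical value is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    tables = np.stack([_relabeling_accuracies(p, C) for p in all_subject_patterns])
    n_subjects, n_relab = tables.shape
    rng = rng_for(seed, "permutation-null")
    draws = rng.integers(0, n_relab, size=(n_perm, n_subjects))
    values = tables[np.arange(n_subjects)[None, :], draws].mean(axis=1)
    return NullDistribution(values=values, seed=seed)


def cross_session_decode(
    patterns_train,
    patterns_test,
    C: float = DEFAULT_C,
) -> DecodingResult:
    """Train on all samples of one session, test on all of the other.

    Both arguments are per-subject lists of 8-sample search subsets with
    identical ROI voxel ordering. No cross-validation folds are involved.
    """
    if len(patterns_train) != len(patterns_test):
        raise ValueError("per-subject pattern lists must align")
    accs = []
    for p_tr, p_te in zip(patterns_train, patterns_test):
        if p_tr.n_voxels != p_te.n_voxels:
            raise ValueError(
                f"voxel-count mismatch between sessions for subject {p_tr.subject}: "
                f"{p_tr.n_voxels} vs {p_te.n_voxels}"
            )
        pred = _predict_linear_svm(p_tr.X, p_tr.domains, p_te.X, C)
        accs.append(float(np.mean(pred == p_te.domains)))
    return DecodingResult(subject_accuracies=np.asarray(accs))


DEFAULT_FEATURE_SIZES: tuple[int, ...] = tuple(range(10, 101, 10))
DEFAULT_N_DRAWS = 10


@dataclass
class FeatureCurve:
    sizes: tuple[int, ...]  # sizes actually evaluated
    per_subject: np.ndarray  # (n_subjects, n_sizes) mean accuracy over draws
    n_draws: int

    @property
    def group_mean(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)


def feature_curve(
    all_subject_patterns,
    sizes=DEFAULT_FEATURE_SIZES,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> FeatureCurve:
    """Decoding accuracy as a function of random voxel-subset size.

    For each size, ``n_draws`` without-replacement voxel subsets are
    drawn per subject; the LORO accuracy is averaged over draws within
    subject, then across subjects. Sizes exceeding the ROI's voxel count
    are skipped with a warning.
    """
    if not all_subject_patterns:
        raise ValueError("at least one subject required")
    n_vox = all_subject_patterns[0].n_voxels
    usable = [s for s in sizes if s <= n_vox]
    skipped = [s for s in sizes if s > n_vox]
    if not usable:
        raise ValueError(f"all subset sizes exceed the ROI's {n_vox} voxels")
    if skipped:
        warnings.warn(
            f"subset sizes {skipped} exceed the ROI's {n_vox} voxels; skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("feature curve skipped sizes %s (ROI has %d voxels)", skipped, n_vox)

    per_subject = np.empty((len(all_subject_patterns), len(usable)))
    for i, patterns in enumerate(all_subject_patterns):
        for j, size in enumerate(usable):
            accs = []
            for draw in range(n_draws):
                rng = rng_for(seed, "feature-curve", patterns.subject, size, draw)
                voxels = rng.choice(patterns.n_voxels, size=size, replace=False)
                accs.append(loro_decode(patterns.with_voxels(voxels), C=C).accuracy)
            per_subject[i, j] = float(np.mean(accs))
    return FeatureCurve(sizes=tuple(usable), per_subject=per_subject, n_draws=n_draws)
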