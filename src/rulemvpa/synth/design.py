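"""Experiment designs: epoch timing for the rule-search task.

Each run is a shuffled sequence of blocks; a block is a rule-discovery
epoch followed by a confirmation and a working-memory control epoch of
the same domain. Every epoch is preceded by a blank of jittered length
drawn from a 250 ms grid. Epoch durations are jittered around a
session-specific mean (longer in session 1 than in session 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..conditions import (
    ALL_CONDITIONS,
    CONDITIONS_OF_INTEREST,
    ERROR_CONDITION,
    domain_of,
)
from .._seeds import rng_for

#: Trailing rest appended to every run so the hemodynamic response to the
#: last epoch is fully sampled.
POST_EPOCH_REST_S = 32.0


@dataclass(frozen=True)
class Epoch:
    condition: str
    onset: float  # seconds from run start
    duration: float  # seconds


@dataclass
class DesignParams:
    """Parameters of the task structure.

    mean_epoch_duration is per session (defaults: 17 s in session 1,
    10 s in session 2). Blanks are drawn uniformly from the
    [blank_range] grid in blank_step increments.
    """

    n_subjects: int = 13
    n_sessions: int = 2
    n_runs: int = 4
    tr: float = 2.0
    mean_epoch_duration: tuple[float, ...] = (17.0, 10.0)
    blank_range: tuple[float, float] = (2.0, 8.0)
    blank_step: float = 0.25
    epochs_per_condition_per_run: int = 1
    errors_per_session: int = 1
    duration_jitter: float = 0.3  # fractional half-width of epoch durations

    def validate(self) -> None:
        if min(self.n_subjects, self.n_sessions, self.n_runs) < 1:
            raise ValueError("subject/session/run counts must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.mean_epoch_duration) < self.n_sessions:
            raise ValueError(
                "mean_epoch_duration needs one value per session "
                f"({self.n_sessions} sessions, {len(self.mean_epoch_duration)} values)"
            )
        if any(d <= 0 for d in self.mean_epoch_duration):
            raise ValueError("epoch durations must be strictly positive")
        lo, hi = self.blank_range
        if not (0 < lo <= hi):
            raise ValueError("blank_range must satisfy 0 < lo <= hi")
        if self.blank_step <= 0:
            raise ValueError("blank_step must be positive")
        if self.epochs_per_condition_per_run < 1:
            raise ValueError("epochs_per_condition_per_run must be >= 1")
        if not 0 <= self.duration_jitter < 1:
            raise ValueError("duration_jitter must be in [0, 1)")

    def blank_grid(self) -> np.ndarray:
        lo, hi = self.blank_range
        n = int(math.floor((hi - lo) / self.blank_step + 1e-9)) + 1
        return lo + self.blank_step * np.arange(n)


RunKey = tuple[int, int, int]  # (subject, session, run), all 1-based


@dataclass
class ExperimentDesign:
    """Ordered epochs per (subject, session, run) plus run durations."""

    params: DesignParams
    epochs: dict[RunKey, tuple[Epoch, ...]] = field(default_factory=dict)
    run_duration_s: dict[RunKey, float] = field(default_factory=dict)

    @property
    def subjects(self) -> range:
        return range(1, self.params.n_subjects + 1)

    @property
    def sessions(self) -> range:
        return range(1, self.params.n_sessions + 1)

    @property
    def runs(self) -> range:
        return range(1, self.params.n_runs + 1)

    def n_scans(self, key: RunKey, tr: float | None = None) -> int:
        tr = self.params.tr if tr is None else tr
        return int(math.ceil(self.run_duration_s[key] / tr))

    def conditions_in_run(self, key: RunKey) -> tuple[str, ...]:
        present = {e.condition for e in self.epochs[key]}
        return tuple(c for c in ALL_CONDITIONS if c in present)


def _draw_duration(rng: np.random.Generator, mean: float, jitter: float) -> float:
    lo, hi = mean * (1 - jitter), mean * (1 + jitter)
    return float(rng.uniform(lo, hi))


def generate_design(params: DesignParams, seed: int) -> ExperimentDesign:
    """Generate a full multi-subject two-session design, deterministically.

    Every run contains ``epochs_per_condition_per_run`` epochs of each of
    the four rule-discovery conditions of interest (and hence of every
    non-error task condition), which the leave-one-run-out decoder needs.
    Error epochs occur ``errors_per_session`` times per session in a
    randomly chosen run.
    """
    params.validate()
    grid = params.blank_grid()
    design = ExperimentDesign(params=params)

    for subject in range(1, params.n_subjects + 1):
        for session in range(1, params.n_sessions + 1):
            mean_dur = params.mean_epoch_duration[session - 1]
            rng = rng_for(seed, "design", subject, session)
            # distribute error epochs over runs of this session
            error_runs = rng.integers(1, params.n_runs + 1, size=params.errors_per_session)
            for run in range(1, params.n_runs + 1):
                blocks: list[list[str]] = []
                for _ in range(params.epochs_per_condition_per_run):
                    for cond in CONDITIONS_OF_INTEREST:
                        dom = domain_of(cond)
                        blocks.append([cond, f"conf_{dom}", f"ctrl_{dom}"])
                order = rng.permutation(len(blocks))
                sequence: list[str] = []
                for i in order:
                    sequence.extend(blocks[i])
                for _ in range(int(np.sum(error_runs == run))):
                    sequence.append(ERROR_CONDITION)

                t = 0.0
                epochs: list[Epoch] = []
                for cond in sequence:
                    t += float(rng.choice(grid))
                    dur = _draw_duration(rng, mean_dur, params.duration_jitter)
                    epochs.append(Epoch(condition=cond, onset=t, duration=dur))
                    t += dur
                t += float(rng.choice(grid))
                key = (subject, session, run)
                design.epochs[key] = tuple(epochs)
                design.run_duration_s[key] = t + POST_EPOCH_REST_S
    return design
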