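"""Behavioral summaries: exemplars-to-discovery per cell.

The number of exemplars a participant needs before declaring the rule is
at least 1, right-skewed, and drops between sessions as participants
learn the task (defaults: grand means 2.1 in session 1, 1.3 in session
2). Cell values are modeled as 1 + Gamma with multiplicative
subject-level and subject-by-session effects, which keeps the >= 1
constraint by construction instead of clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..conditions import DOMAINS, SEARCH_TYPES
from .._seeds import rng_for


@dataclass
class BehaviorParams:
    n_subjects: int = 13
    #: grand mean exemplars per session
    session_means: tuple[float, ...] = (2.1, 1.3)
    #: additive domain effect per session: (spatial, verbal)
    domain_effects: tuple[tuple[float, float], ...] = ((0.1, -0.1), (0.15, -0.15))
    #: additive search effect per session: (separate, parallel)
    search_effects: tuple[tuple[float, float], ...] = ((-0.15, 0.15), (-0.05, 0.05))
    gamma_shape: float | None = 4.0  # None -> deterministic cell values
    subject_cv: float = 0.3  # lognormal sd of the subject effect
    subject_session_cv: float = 0.4  # lognormal sd of the subject-by-session effect

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(m <= 1.0 for m in self.session_means):
            raise ValueError("session means must exceed 1 (a rule needs >= 1 exemplar)")
        for s, gm in enumerate(self.session_means):
            for de in self.domain_effects[s]:
                for se in self.search_effects[s]:
                    if gm + de + se <= 1.0:
                        raise ValueError("every cell mean must exceed 1")

    def cell_mean(self, session: int, domain: str, search: str) -> float:
        s = session - 1
        return (
            self.session_means[s]
            + self.domain_effects[s][DOMAINS.index(domain)]
            + self.search_effects[s][SEARCH_TYPES.index(search)]
        )


@dataclass
class BehaviorTable:
    """Long table: subject, session, domain, search, exemplars (mean >= 1)."""

    params: BehaviorParams
    data: pd.DataFrame = field(repr=False, default=None)

    def session_means(self) -> pd.DataFrame:
        """Per-subject mean over the four cells, one column per session."""
        return self.data.pivot_table(
            index="subject", columns="session", values="exemplars", aggfunc="mean"
        )

    def cell_means(self) -> pd.DataFrame:
        return self.data.pivot_table(
            index=["session", "domain", "search"], values="exemplars", aggfunc="mean"
        )


def generate_behavior(params: BehaviorParams | None = None, seed: int = 0) -> BehaviorTable:
    """Draw per-subject, per-session, per-cell exemplar counts.

    value = 1 + Gamma(shape k, mean (cell_mean - 1) * subject gain *
    subject-session gain). With ``gamma_shape=None`` and zero
    between-subject spread the values equal the cell means exactly
    (degenerate case; a paired t on such data has a zero denominator and
    is flagged degenerate downstream).
    """
    params = params or BehaviorParams()
    params.validate()
    rows = []
    n_sessions = len(params.session_means)
    for subject in range(1, params.n_subjects + 1):
        rng = rng_for(seed, "behavior", subject)
        g_subj = (
            np.exp(params.subject_cv * rng.standard_normal() - params.subject_cv**2 / 2)
            if params.subject_cv > 0
            else 1.0
        )
        for session in range(1, n_sessions + 1):
            g_ss = (
                np.exp(
                    params.subject_session_cv * rng.standard_normal()
                    - params.subject_session_cv**2 / 2
                )
                if params.subject_session_cv > 0
                else 1.0
            )
            for domain in DOMAINS:
                for search in SEARCH_TYPES:
                    excess = (params.cell_mean(session, domain, search) - 1.0) * g_subj * g_ss
                    if params.gamma_shape is None:
                        value = 1.0 + excess
                    else:
                        k = params.gamma_shape
                        value = 1.0 + float(rng.gamma(k, excess / k))
                    rows.append(
                        {
                            "subject": subject,
                            "session": session,
                            "domain": domain,
                            "search": search,
                            "exemplars": value,
                        }
                    )
    return BehaviorTable(params=params, data=pd.DataFrame(rows))
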