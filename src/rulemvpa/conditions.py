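"""Condition vocabulary for the rule-search task.

Nine conditions: four rule-discovery conditions of interest (domain ×
search type), two confirmation and two working-memory control conditions
(one per domain), and a catch-all error condition.
"""

from __future__ import annotations

DOMAINS: tuple[str, str] = ("spatial", "verbal")
SEARCH_TYPES: tuple[str, str] = ("separate", "parallel")

#: The four rule-discovery conditions submitted to decoding, canonical order.
CONDITIONS_OF_INTEREST: tuple[str, ...] = (
    "disc_spatial_separate",
    "disc_verbal_separate",
    "disc_spatial_parallel",
    "disc_verbal_parallel",
)

#: The eight task conditions modeled with one regressor per run each.
TASK_CONDITIONS: tuple[str, ...] = CONDITIONS_OF_INTEREST + (
    "conf_spatial",
    "conf_verbal",
    "ctrl_spatial",
    "ctrl_verbal",
)

ERROR_CONDITION = "error"

#: All nine regressor labels, canonical order.
ALL_CONDITIONS: tuple[str, ...] = TASK_CONDITIONS + (ERROR_CONDITION,)


def domain_of(condition: str) -> str:
    """Domain (spatial/verbal) attribute of a non-error condition."""
    for d in DOMAINS:
        if f"_{d}" in condition:
            return d
    raise ValueError(f"condition {condition!r} carries no domain attribute")


def search_of(condition: str) -> str:
    """Search type (separate/parallel) of a rule-discovery condition."""
    for s in SEARCH_TYPES:
        if condition.endswith(f"_{s}"):
            return s
    raise ValueError(f"condition {condition!r} carries no search attribute")
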