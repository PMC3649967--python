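"""Shared result containers and vocabulary for the analysis pipeline.

Gene tables and variant tables are plain :class:`pandas.DataFrame` objects
(column contracts documented on the functions that build them); small typed
results (test outcomes, per-study permutation results, meta-analysis results)
are frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Effect-class vocabulary
# ---------------------------------------------------------------------------

#: SnpEff-style annotation tokens that count as "broad exonic missense".
BROAD_MISSENSE_TOKENS = frozenset(
    {
        "SPLICE_SITE_ACCEPTOR",
        "SPLICE_SITE_DONOR",
        "STOP_GAINED",
        "NON_SYNONYMOUS_CODING",
        "STOP_LOST",
        "START_LOST",
        "START_GAINED",
    }
)

#: Subset of the broad class that disrupts a stop codon or splice site.
LOF_TOKENS = frozenset(
    {"SPLICE_SITE_ACCEPTOR", "SPLICE_SITE_DONOR", "STOP_GAINED", "STOP_LOST"}
)

SYNONYMOUS_TOKEN = "SYNONYMOUS_CODING"

#: effect_class values carried on variant tables.
SYNONYMOUS = "SYNONYMOUS"
MISSENSE_BROAD = "MISSENSE_BROAD"
LOF = "LOF"
OTHER = "OTHER"

GENE_CLASSES = ("EG", "NLG", "OTHER")

#: Recognised de novo mutation-type tokens, most- to least-damaging.
#: Any coding type outranks "synonymous"; within coding the order is a
#: documented convention (the source data never needed a finer rule).
DENOVO_TYPE_PRECEDENCE = (
    "frameshift",
    "nonsense",
    "splice",
    "stoploss",
    "del_aa",
    "inframe",
    "missense",
    "synonymous",
)

DENOVO_CODING_TYPES = frozenset(DENOVO_TYPE_PRECEDENCE) - {"synonymous"}


def is_broad_missense(effect_class: str) -> bool:
    """LoF variants are a subset of the broad exonic-missense tally."""
    return effect_class in (MISSENSE_BROAD, LOF)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group or contingency test."""

    statistic: float
    p_value: float
    sidedness: str  # "one" | "two"
    paired: bool = False
    or_: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.or_ is not None and self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo <= self.or_ <= hi):
                raise ValueError("odds ratio outside its confidence interval")


@dataclass(frozen=True)
class StudyResult:
    """Per-study matched-permutation enrichment result."""

    study_id: str
    arm: str
    n_events: int
    obs_in_set: int
    exp_in_set: float
    log_adj_or: float
    se_log_or: float
    perm_p: float          # one-sided (enrichment), add-one convention
    perm_p_two: float      # doubled, capped at 1
    n_perm: int
    exact_exp_in_set: Optional[float] = None
    mean_replicate_or: Optional[float] = None

    @property
    def adjusted_or(self) -> float:
        return float(np.exp(self.log_adj_or))

    @property
    def ci95(self) -> tuple[float, float]:
        if not np.isfinite(self.se_log_or):
            return (float("nan"), float("nan"))
        half = 1.96 * self.se_log_or
        return (
            float(np.exp(self.log_adj_or - half)),
            float(np.exp(self.log_adj_or + half)),
        )


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effects combination of study log-ORs."""

    combined_or: float
    ci95: tuple[float, float]
    meta_p: float
    cochran_q: float
    q_df: int
    q_p: float
    log_combined: float
    se_combined: float
    n_studies: int

    def __post_init__(self) -> None:
        if self.q_df != max(self.n_studies - 1, 0):
            raise ValueError("q_df must equal n_studies - 1")
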