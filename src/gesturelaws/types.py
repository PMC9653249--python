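"""Core domain types for gesture-token streams and law-level statistics.

The unit of observation is the gesture *token*: one timed instance of a
gesture *type* produced by one signaller toward one recipient.  Tokens that
follow each other with a sub-threshold gap form a rapid *sequence*; the
repertoire table aggregates tokens by type.  Result containers at the bottom
hold the outputs of the brevity, compression, Menzerath and reliability
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

FRAME_S = 0.04  # video frame length in seconds; durations are multiples of this

MANUAL = "manual"
WHOLE_BODY = "whole_body"
FIXED = "fixed"
LOOSE = "loose"


@dataclass(frozen=True)
class GestureToken:
    """One timed, typed gesture instance by one signaller.

    ``end_s`` may be missing (``None``) when the coder could not identify the
    end of the gesture on video; the token is then retained for segmentation
    but its sequence is flagged incomplete.
    """

    signaller: str
    recipient: str
    date: str  # ISO-8601 calendar date
    video_id: str
    gesture_type: str
    category: str  # "manual" | "whole_body"
    duration_form: str  # "fixed" | "loose"
    start_s: float
    end_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in (MANUAL, WHOLE_BODY):
            raise ValueError(f"invalid category {self.category!r}")
        if self.duration_form not in (FIXED, LOOSE):
            raise ValueError(f"invalid duration_form {self.duration_form!r}")
        if self.end_s is not None and self.end_s < self.start_s:
            raise ValueError(
                f"end_s ({self.end_s}) < start_s ({self.start_s}) for token "
                f"{self.gesture_type!r} by {self.signaller!r}"
            )

    @property
    def duration_s(self) -> Optional[float]:
        """Token duration in seconds, or ``None`` when the end is unknown."""
        if self.end_s is None:
            return None
        return self.end_s - self.start_s


@dataclass
class GestureSequence:
    """An ordered run of tokens by one signaller with sub-threshold gaps.

    Singletons count as sequences of length one.  ``same_type`` is defined
    only for multi-token sequences; ``mean_duration_s`` is missing unless
    every member token has a known duration.
    """

    sequence_id: str
    tokens: list[GestureToken]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a sequence must contain at least one token")

    @property
    def size_n(self) -> int:
        return len(self.tokens)

    @property
    def signaller(self) -> str:
        return self.tokens[0].signaller

    @property
    def complete(self) -> bool:
        return all(t.duration_s is not None for t in self.tokens)

    @property
    def pwb(self) -> float:
        """Proportion of whole-body (vs manual) tokens, in [0, 1]."""
        return sum(t.category == WHOLE_BODY for t in self.tokens) / self.size_n

    @property
    def same_type(self) -> Optional[bool]:
        if self.size_n < 2:
            return None
        first = self.tokens[0].gesture_type
        return all(t.gesture_type == first for t in self.tokens)

    @property
    def mean_duration_s(self) -> Optional[float]:
        if not self.complete:
            return None
        return sum(t.duration_s for t in self.tokens) / self.size_n


@dataclass(frozen=True)
class RepertoireEntry:
    """Per-type token count, dataset proportion and duration summaries."""

    gesture_type: str
    category: str
    n_tokens: int
    proportion_p: float
    mean_duration_s: float
    median_duration_s: float


@dataclass(frozen=True)
class LengthCompositionRow:
    """One row of the length-by-composition contingency table."""

    length: int
    n_same_type: Optional[int]  # None for length 1, where composition is undefined
    n_different_type: Optional[int]
    n_total: int


@dataclass
class LengthCompositionTable:
    rows: list[LengthCompositionRow]

    @property
    def n_sequences(self) -> int:
        return sum(r.n_total for r in self.rows)

    @property
    def n_multi(self) -> int:
        """Number of sequences of length >= 2."""
        return sum(r.n_total for r in self.rows if r.length >= 2)

    @property
    def n_same_total(self) -> int:
        return sum(r.n_same_type or 0 for r in self.rows)

    @property
    def n_different_total(self) -> int:
        return sum(r.n_different_type or 0 for r in self.rows)


@dataclass(frozen=True)
class BrevityResult:
    """Rank correlation between type frequency and type duration.

    A brevity-law pattern is a negative coefficient: frequent types short.
    """

    coefficient: float
    p_value: float
    n_types: int
    duration_summary: str  # "mean" | "median"
    method: str  # "kendall" | "spearman"
    alternative: str
    n_perm: int
    seed: Optional[int]


@dataclass(frozen=True)
class CompressionResult:
    """Mean code length L = sum_i p_i d_i against its permutation null.

    ``optimization_eta`` locates L_obs between the permutation mean (0) and
    the optimal frequency-duration pairing L_min (1).
    """

    L_obs: float
    L_min: float
    L_max: float
    L_rand_mean: float
    L_rand_sd: float
    p_value: float
    n_perm: int
    exact: bool
    seed: Optional[int]

    @property
    def optimization_eta(self) -> float:
        denom = self.L_rand_mean - self.L_min
        if denom == 0:
            return math.nan
        return (self.L_rand_mean - self.L_obs) / denom


@dataclass(frozen=True)
class MenzerathResult:
    """Per-sequence (size, mean constituent duration) points and fits.

    ``mal_a``/``mal_b`` are the Menzerath–Altmann power law d = a * n^b
    fitted by least squares on the log–log scale.
    """

    points: list[tuple[int, float]]
    coefficient: Optional[float]
    p_value: Optional[float]
    mal_a: Optional[float]
    mal_b: Optional[float]
    n_perm: int
    seed: Optional[int]
    note: str = ""


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    n_items: int
    model: str = "ICC(3,1), two-way mixed, consistency, k=2"


@dataclass(frozen=True)
class CoefficientEstimate:
    """One fixed-effect estimate with its 95% uncertainty interval."""

    estimate: float
    sd: float
    interval_low: float
    interval_high: float


@dataclass
class ModelFitResult:
    """Fixed effects with 95% intervals from one hierarchical fit."""

    name: str
    coefficients: dict[str, CoefficientEstimate]
    n_tokens: int
    random_terms: list[str]
    variance_components: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    engine: str = "statsmodels-mixedlm"


@dataclass(frozen=True)
class ComparisonResult:
    """Full-vs-null predictive comparison.

    ``delta`` is the expected-log-predictive-density difference null minus
    full: negative values favour the full model (the orientation used by
    LOO-style comparisons where the weaker model is shown with a negative
    difference).
    """

    delta: float
    delta_sd: float
    term: str
    n_tokens: int


@dataclass
class RecoverySummary:
    """Simulate-fit-collect summary for one generator parameter."""

    parameter: str
    true_value: float
    estimates: list[float]
    interval_lows: list[float]
    interval_highs: list[float]
    seeds: list[int]
    n_failures: int = 0

    @property
    def mean_estimate(self) -> float:
        return sum(self.estimates) / len(self.estimates)

    @property
    def coverage(self) -> float:
        hits = sum(
            lo <= self.true_value <= hi
            for lo, hi in zip(self.interval_lows, self.interval_highs)
        )
        return hits / len(self.estimates)
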