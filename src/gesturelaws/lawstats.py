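"""Law-level statistics: brevity correlation, compression test, Menzerath
descriptives and power-law fit, and intra-observer ICC(3,1).

The compression test asks whether the frequency-weighted mean signal
duration L = sum_i p_i d_i sits low among the mean code lengths obtained by
permuting durations against frequencies across types: communicative codes
under pressure for compression pair frequent types with short signals, so
L_obs should fall in the lower tail of the permutation distribution.  The
brevity correlation is the rank-correlation analogue at the type level; the
Menzerath statistics relate sequence size to the mean duration of its
constituent gestures, including the Menzerath–Altmann power law d = a*n^b.

Permutation p-values use the add-one convention (r+1)/(n+1) so they are
never zero; for small repertoires both tests can enumerate all pairings
exactly instead of sampling.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    BrevityResult,
    CompressionResult,
    GestureSequence,
    MenzerathResult,
    ReliabilityResult,
    RepertoireEntry,
)

__all__ = [
    "brevity_correlation",
    "compression_test",
    "menzerath_stats",
    "icc3_single",
]

_MAX_EXACT_TYPES = 7  # 7! = 5040 pairings; beyond this, sample


def _rank_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "kendall":
        r = stats.kendalltau(x, y).statistic  # tau-b, tie-corrected
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    # a constant vector carries no rank signal; report zero rather than NaN
    return 0.0 if np.isnan(r) else float(r)


def _kendall_tau_b_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tau-b of fixed ``x`` against each row of ``Y`` (vectorized over rows).

    Works from pairwise sign products; the tie corrections for ``x`` are
    constant across rows and those for each row of ``Y`` are permutation
    invariant, so the denominator is a single scalar.
    """
    n = x.size
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])
    n_pairs = n * (n - 1) // 2
    tx = n_pairs - np.count_nonzero(sx)
    ty = n_pairs - np.count_nonzero(np.sign(Y[0, iu] - Y[0, ju]))
    denom = math.sqrt((n_pairs - tx) * (n_pairs - ty))
    if denom == 0:
        return np.zeros(Y.shape[0])
    # chunk over permutations: the (chunk, n_pairs) sign matrix is the
    # memory hot spot for long sequence lists
    chunk = max(1, int(2e7) // max(n_pairs, 1))
    num = np.empty(Y.shape[0])
    for lo in range(0, Y.shape[0], chunk):
        block = Y[lo : lo + chunk]
        num[lo : lo + chunk] = np.sign(block[:, iu] - block[:, ju]) @ sx
    return num / denom


def _spearman_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    rx = stats.rankdata(x)
    rY = stats.rankdata(Y, axis=1)
    rx = rx - rx.mean()
    rY = rY - rY.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum() * (rY**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        out = (rY @ rx) / denom
    return np.nan_to_num(out)


def _duration_vector(
    repertoire: Sequence[RepertoireEntry], duration_summary: str
) -> np.ndarray:
    if duration_summary == "mean":
        return np.array([e.mean_duration_s for e in repertoire])
    if duration_summary == "median":
        return np.array([e.median_duration_s for e in repertoire])
    raise ValueError(f"unknown duration_summary {duration_summary!r}")


def brevity_correlation(
    repertoire: Sequence[RepertoireEntry],
    method: str = "kendall",
    duration_summary: str = "median",
    n_perm: int = 9999,
    seed: Optional[int] = None,
    alternative: str = "two-sided",
    exact: Optional[bool] = None,
) -> BrevityResult:
    """Rank correlation of per-type frequency against per-type duration.

    The permutation null shuffles the duration vector against the frequency
    vector over types.  ``alternative='less'`` tests the brevity-law
    direction (negative correlation); the default is two-sided.  With
    ``exact`` (default: automatic for <= 7 types) all pairings are
    enumerated, in which case the p-value is the exact proportion
    r/n! (the identity pairing counts itself, so it is never zero).
    """
    if len(repertoire) < 3:
        raise ValueError("brevity correlation needs at least 3 types")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if alternative not in ("two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    freq = np.array([e.n_tokens for e in repertoire], dtype=float)
    dur = _duration_vector(repertoire, duration_summary)
    obs = _rank_corr(freq, dur, method)

    if exact is None:
        exact = len(repertoire) <= _MAX_EXACT_TYPES
    if exact:
        perms = np.array(list(itertools.permutations(range(len(dur)))))
        Y = dur[perms]
        denom = len(perms)
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        Y = np.array([rng.permutation(dur) for _ in range(n_perm)])
        denom = n_perm + 1
        add_one = 1

    corr_fn = _kendall_tau_b_many if method == "kendall" else _spearman_many
    null = corr_fn(freq, Y)
    tol = 1e-12
    if alternative == "two-sided":
        r = int(np.sum(np.abs(null) >= abs(obs) - tol))
    else:
        r = int(np.sum(null <= obs + tol))
    p = (r + add_one) / denom
    return BrevityResult(
        coefficient=float(obs),
        p_value=float(p),
        n_types=len(repertoire),
        duration_summary=duration_summary,
        method=method,
        alternative=alternative,
        n_perm=len(Y) if exact else n_perm,
        seed=seed,
    )


def compression_test(
    repertoire: Sequence[RepertoireEntry],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    exact: Optional[bool] = None,
    duration_summary: str = "mean",
) -> CompressionResult:
    """Mean code length L_obs = sum_i p_i d_i against its permutation null.

    ``d_i`` is the per-type mean duration by default (L is an expectation;
    with proportions as weights L_obs equals the overall mean token
    duration).  ``L_min`` pairs the largest p with the smallest d (sorted
    pairing), ``L_max`` the reverse; the null permutes the duration vector
    across types with frequencies fixed.  ``p_value`` is the probability
    of a permuted mean code length at or below the observed one.
    """
    if len(repertoire) < 2:
        raise ValueError("compression test needs at least 2 types")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    p = np.array([e.proportion_p for e in repertoire])
    d = _duration_vector(repertoire, duration_summary)
    L_obs = float(p @ d)
    p_desc = np.sort(p)[::-1]
    L_min = float(p_desc @ np.sort(d))
    L_max = float(p_desc @ np.sort(d)[::-1])

    if exact is None:
        exact = len(repertoire) <= _MAX_EXACT_TYPES
    tol = 1e-12
    if exact:
        perms = np.array(list(itertools.permutations(range(len(d)))))
        L_null = d[perms] @ p
        p_val = float(np.sum(L_null <= L_obs + tol) / len(L_null))
        n_used = len(L_null)
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, len(d))), axis=1)
        L_null = d[idx] @ p
        p_val = float((1 + np.sum(L_null <= L_obs + tol)) / (n_perm + 1))
        n_used = n_perm
    return CompressionResult(
        L_obs=L_obs,
        L_min=L_min,
        L_max=L_max,
        L_rand_mean=float(L_null.mean()),
        L_rand_sd=float(L_null.std(ddof=1)),
        p_value=p_val,
        n_perm=n_used,
        exact=bool(exact),
        seed=seed,
    )


def menzerath_stats(
    sequences: Sequence[GestureSequence],
    n_perm: int = 9999,
    seed: Optional[int] = None,
    method: str = "kendall",
) -> MenzerathResult:
    """Sequence-level Menzerath descriptives.

    One point per complete sequence: (size n, mean constituent duration).
    Reports the rank correlation of duration on size with a permutation p
    (shuffling mean durations across sequences) and the Menzerath–Altmann
    power law d = a*n^b fitted by least squares on the log–log scale.  A
    Menzerath-consistent pattern gives a negative correlation and b < 0.
    """
    pts = [(s.size_n, s.mean_duration_s) for s in sequences if s.complete]
    if not pts:
        raise ValueError("no complete sequences")
    sizes = np.array([p[0] for p in pts], dtype=float)
    durs = np.array([p[1] for p in pts], dtype=float)

    if len(np.unique(sizes)) < 2:
        return MenzerathResult(
            points=pts, coefficient=None, p_value=None, mal_a=None, mal_b=None,
            n_perm=0, seed=seed,
            note="all sequences share one size; correlation and fit undefined",
        )

    obs = _rank_corr(sizes, durs, method)
    rng = np.random.default_rng(seed)
    Y = np.array([rng.permutation(durs) for _ in range(n_perm)])
    corr_fn = _kendall_tau_b_many if method == "kendall" else _spearman_many
    null = corr_fn(sizes, Y)
    p = (1 + int(np.sum(np.abs(null) >= abs(obs) - 1e-12))) / (n_perm + 1)

    slope, intercept = np.polyfit(np.log(sizes), np.log(durs), 1)
    return MenzerathResult(
        points=pts,
        coefficient=float(obs),
        p_value=float(p),
        mal_a=float(np.exp(intercept)),
        mal_b=float(slope),
        n_perm=n_perm,
        seed=seed,
    )


def icc3_single(pairs: Sequence[tuple[float, float]]) -> ReliabilityResult:
    """Intra-observer ICC(3,1): two-way mixed, consistency, single measure.

    ``pairs`` holds the first and second coding of each item (k = 2
    occasions).  From the two-way ANOVA decomposition,
    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err); the consistency
    form is insensitive to an additive shift between codings.
    """
    if len(pairs) < 3:
        raise ValueError("ICC needs at least 3 items")
    x = np.asarray(pairs, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC requires finite values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return ReliabilityResult(icc=float(icc), n_items=n)
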