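"""Hierarchical regressions for the brevity and Menzerath analyses.

Two token-level models on the natural log of gesture duration:

* Zipf-model — fixed effects: type proportion in the dataset and gesture
  category (manual vs whole-body control); random intercepts: signaller,
  sequence and gesture type.  A brevity pattern is a negative proportion
  coefficient.
* Menzerath-model — fixed effects: sequence size and the proportion of
  whole-body gestures in the sequence (PWB control); random intercepts:
  signaller and sequence.  A Menzerath pattern is a negative size
  coefficient.

For the prolific-individual subset the signaller intercept is dropped
(one level) and the recording date enters as a random intercept instead.

Fits use restricted maximum likelihood (statsmodels MixedLM) with the
random structure expressed through variance components, which handles both
the nested case (sequence within signaller or date) and the crossed case
(gesture type crossed with signaller).  Full/null comparison estimates the
out-of-sample expected log predictive density by K-fold cross-validation
with whole sequences held out together; ``delta`` is null minus full, so
negative favours the full model — the orientation of LOO-style
comparisons — with a fold-clustered standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synthetic import SimulationConfig, simulate_tokens
from .types import (
    WHOLE_BODY,
    CoefficientEstimate,
    ComparisonResult,
    GestureSequence,
    ModelFitResult,
    RecoverySummary,
)

__all__ = [
    "ModelSpec",
    "StructuralError",
    "build_model_frame",
    "fit_model",
    "compare_full_null",
    "run_subset_analyses",
    "recovery_experiment",
]

Z95 = 1.959963984540054  # normal 97.5% quantile for the 95% interval


class StructuralError(ValueError):
    """The random/fixed structure is underdetermined; the message names the term."""


@dataclass(frozen=True)
class ModelSpec:
    """Which model, on which subset, with which random structure."""

    name: str  # "zipf" | "menzerath"
    subset: str = "all"  # "all" | "prolific_only" | "exclude_prolific"
    date_as_random: Optional[bool] = None  # default: True iff prolific_only
    include_type_random: bool = False  # optional gesture-type term (menzerath)

    def __post_init__(self) -> None:
        if self.name not in ("zipf", "menzerath"):
            raise ValueError(f"unknown model name {self.name!r}")
        if self.subset not in ("all", "prolific_only", "exclude_prolific"):
            raise ValueError(f"unknown subset {self.subset!r}")

    @property
    def use_date(self) -> bool:
        if self.date_as_random is None:
            return self.subset == "prolific_only"
        return self.date_as_random

    @property
    def term_of_interest(self) -> str:
        return "proportion" if self.name == "zipf" else "size_n"

    @property
    def fixed_terms(self) -> list[str]:
        if self.name == "zipf":
            return ["proportion", "whole_body"]
        return ["size_n", "pwb"]

    @property
    def random_terms(self) -> list[str]:
        terms = [] if self.subset == "prolific_only" else ["signaller"]
        if self.use_date:
            terms.append("date")
        terms.append("sequence_id")
        if self.name == "zipf" or self.include_type_random:
            terms.append("gesture_type")
        return terms


def build_model_frame(sequences: Sequence[GestureSequence]) -> pd.DataFrame:
    """One row per token of a complete sequence, with all model covariates.

    Type proportions are computed on this analysis dataset (i.e. after the
    completeness exclusion).
    """
    rows = []
    for s in sequences:
        if not s.complete:
            continue
        for t in s.tokens:
            rows.append(
                {
                    "log_duration": np.log(t.duration_s),
                    "gesture_type": t.gesture_type,
                    "whole_body": 1.0 if t.category == WHOLE_BODY else 0.0,
                    "size_n": float(s.size_n),
                    "pwb": s.pwb,
                    "signaller": s.signaller,
                    "sequence_id": s.sequence_id,
                    "date": t.date,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise StructuralError("no complete sequences to fit")
    counts = frame["gesture_type"].value_counts()
    frame["proportion"] = frame["gesture_type"].map(counts / len(frame))
    return frame


def _apply_subset(frame: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return frame
    prolific = frame["signaller"].value_counts().idxmax()
    if subset == "prolific_only":
        out = frame[frame["signaller"] == prolific]
    else:
        out = frame[frame["signaller"] != prolific]
    if out.empty:
        raise StructuralError(f"subset {subset!r} contains no tokens")
    # proportions are recomputed on the subset actually analysed
    out = out.drop(columns="proportion").copy()
    counts = out["gesture_type"].value_counts()
    out["proportion"] = out["gesture_type"].map(counts / len(out))
    return out.reset_index(drop=True)


def _design(frame: pd.DataFrame, spec: ModelSpec, drop_term: Optional[str] = None):
    terms = [t for t in spec.fixed_terms if t != drop_term]
    X = pd.DataFrame({"Intercept": np.ones(len(frame))})
    for t in terms:
        X[t] = frame[t].to_numpy()
    return X


def _vc_spec(frame: pd.DataFrame, factors: list[str]) -> VCSpec:
    names, colnames, mats = [], [], []
    for f in factors:
        dummies = pd.get_dummies(frame[f], dtype=float)
        names.append(f)
        colnames.append([list(dummies.columns)])
        mats.append([dummies.to_numpy()])
    return VCSpec(names, colnames, mats)


def _check_structure(frame: pd.DataFrame, spec: ModelSpec) -> None:
    for term in spec.random_terms:
        if frame[term].nunique() < 2:
            raise StructuralError(
                f"random term {term!r} has a single level; remove it from the "
                "random structure"
            )


def fit_model(
    sequences: Sequence[GestureSequence],
    spec: ModelSpec,
    frame: Optional[pd.DataFrame] = None,
    drop_term: Optional[str] = None,
) -> ModelFitResult:
    """Fit one hierarchical model and report fixed effects with 95% intervals.

    ``frame`` may be passed to reuse a prebuilt token table (the subset is
    then assumed to be applied already); ``drop_term`` removes one fixed
    term, which is how the null model of the full/null comparison is built.
    """
    if frame is None:
        frame = _apply_subset(build_model_frame(sequences), spec.subset)
    _check_structure(frame, spec)

    y = frame["log_duration"].to_numpy()
    X = _design(frame, spec, drop_term)

    # noiseless degenerate data: the mixed model likelihood is singular,
    # but the fixed effects are exactly identified by least squares
    beta_ls, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta_ls
    if float(resid @ resid) / len(y) < 1e-12:
        coefs = {
            name: CoefficientEstimate(float(b), 0.0, float(b), float(b))
            for name, b in zip(X.columns, beta_ls)
        }
        fit = ModelFitResult(
            name=spec.name, coefficients=coefs, n_tokens=len(frame),
            random_terms=spec.random_terms, converged=True,
            engine="least-squares (degenerate noiseless data)",
        )
        fit._fe_params = beta_ls  # type: ignore[attr-defined]
        fit._fe_names = list(X.columns)  # type: ignore[attr-defined]
        fit._var_total = 0.0  # type: ignore[attr-defined]
        return fit

    # When one random factor contains the others (sequence nested in
    # signaller or date), using it as the MixedLM grouping factor makes the
    # marginal covariance block-diagonal and the fit much faster; otherwise
    # (gesture type crossed with signaller) fall back to a single group.
    group_term = _nesting_group(frame, spec.random_terms)
    vc_terms = [t for t in spec.random_terms if t != group_term]
    if group_term is not None:
        groups = frame[group_term].to_numpy()
        order = np.argsort(groups, kind="stable")
        frame_s = frame.iloc[order].reset_index(drop=True)
        y_s = y[order]
        X_s = X.iloc[order].reset_index(drop=True)
        model = MixedLM(
            y_s,
            X_s.to_numpy(),
            groups=frame_s[group_term].to_numpy(),
            exog_re=np.ones((len(frame_s), 1)),
            exog_vc=_vc_spec_grouped(frame_s, vc_terms, group_term),
            use_sqrt=True,
        )
    else:
        y_s, X_s = y, X
        model = MixedLM(
            y_s,
            X_s.to_numpy(),
            groups=np.zeros(len(frame)),
            exog_vc=_vc_spec(frame, vc_terms),
            exog_re=None,
            use_sqrt=True,
        )
    model.data.xnames = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method="lbfgs", maxiter=500)
        if not result.converged:
            result = model.fit(reml=True, method="cg", maxiter=500)

    coefs = {}
    for j, name in enumerate(X.columns):
        b = float(result.fe_params[j])
        se = float(result.bse_fe[j])
        coefs[name] = CoefficientEstimate(b, se, b - Z95 * se, b + Z95 * se)
    vcomp = {name: float(v) for name, v in zip(vc_terms, result.vcomp)}
    if group_term is not None:
        vcomp[group_term] = float(np.asarray(result.cov_re)[0, 0])
    vcomp["residual"] = float(result.scale)
    fit = ModelFitResult(
        name=spec.name,
        coefficients=coefs,
        n_tokens=len(frame),
        random_terms=spec.random_terms,
        variance_components=vcomp,
        converged=bool(result.converged),
    )
    fit._fe_params = np.asarray(result.fe_params)  # type: ignore[attr-defined]
    fit._fe_names = list(X.columns)  # type: ignore[attr-defined]
    fit._var_total = sum(vcomp.values())  # type: ignore[attr-defined]
    return fit


def _nesting_group(frame: pd.DataFrame, random_terms: list[str]) -> Optional[str]:
    """A random factor whose levels contain every other random factor, if any."""
    for cand in ("signaller", "date"):
        if cand not in random_terms:
            continue
        others = [t for t in random_terms if t != cand]
        if all(
            (frame.groupby(t, observed=True)[cand].nunique() == 1).all()
            for t in others
        ):
            return cand
    return None


def _vc_spec_grouped(
    frame: pd.DataFrame, factors: list[str], group_term: str
) -> Optional[VCSpec]:
    """Variance-component design matrices, one block per grouping level."""
    if not factors:
        return None
    group_labels = frame[group_term].to_numpy()
    levels = pd.unique(group_labels)
    names, colnames, mats = [], [], []
    for f in factors:
        cn, mm = [], []
        for g in levels:
            sub = frame.loc[group_labels == g, f]
            dummies = pd.get_dummies(sub, dtype=float)
            cn.append(list(dummies.columns))
            mm.append(dummies.to_numpy())
        names.append(f)
        colnames.append(cn)
        mats.append(mm)
    return VCSpec(names, colnames, mats)


def _pointwise_lpd(
    fe_params: np.ndarray, X: np.ndarray, y: np.ndarray, var_total: float
) -> np.ndarray:
    """Marginal per-token log predictive density N(x_i b, total variance)."""
    mu = X @ fe_params
    return sps.norm.logpdf(y, loc=mu, scale=np.sqrt(var_total))


def compare_full_null(
    sequences: Sequence[GestureSequence],
    spec: ModelSpec,
    frame: Optional[pd.DataFrame] = None,
    k_folds: int = 5,
    cv_seed: int = 0,
    term: Optional[str] = None,
) -> ComparisonResult:
    """Full model vs the null without the term of interest, on identical rows.

    The criterion is the out-of-sample expected log predictive density
    estimated by K-fold cross-validation with whole sequences held out
    together (respecting the sequence random intercept).  ``delta`` is
    elpd(null) − elpd(full) summed over held-out tokens: negative favours
    the full model (the orientation of LOO-style comparisons, where the
    weaker model carries the negative difference).  The standard error is
    the elpd-style sqrt(n)·sd of the pointwise differences.
    """
    if frame is None:
        frame = _apply_subset(build_model_frame(sequences), spec.subset)
    if term is None:
        term = spec.term_of_interest
    n = len(frame)

    rng = np.random.default_rng(cv_seed)
    seq_ids = pd.unique(frame["sequence_id"])
    fold_of_seq = dict(
        zip(seq_ids, rng.permutation(np.arange(len(seq_ids)) % k_folds))
    )
    folds = frame["sequence_id"].map(fold_of_seq).to_numpy()

    lpd_full = np.empty(n)
    lpd_null = np.empty(n)
    fold_sums = []
    for k in range(k_folds):
        test = folds == k
        train = frame.loc[~test].reset_index(drop=True)
        test_frame = frame.loc[test]
        if test_frame.empty:
            continue
        y_test = test_frame["log_duration"].to_numpy()
        for drop, store in ((None, lpd_full), (term, lpd_null)):
            fit = fit_model(sequences, spec, frame=train, drop_term=drop)
            X_test = _design(test_frame, spec, drop)
            store[test] = _pointwise_lpd(
                fit._fe_params, X_test.to_numpy(), y_test,  # type: ignore[attr-defined]
                max(fit._var_total, 1e-12),  # type: ignore[attr-defined]
            )
        fold_sums.append(float(np.sum(lpd_null[test] - lpd_full[test])))
    diff = lpd_null - lpd_full
    # tokens within a fold share one pair of fold fits, so the uncertainty
    # is clustered at the fold level: Var(sum) = K * Var(fold sums)
    K = len(fold_sums)
    sd = (
        float(np.sqrt(K) * np.std(fold_sums, ddof=1)) if K > 1 else 0.0
    )
    return ComparisonResult(
        delta=float(np.sum(diff)),
        delta_sd=sd,
        term=term,
        n_tokens=n,
    )


def run_subset_analyses(
    sequences: Sequence[GestureSequence],
    subsets: Sequence[str] = ("all", "prolific_only", "exclude_prolific"),
    compare: bool = True,
) -> dict[str, dict]:
    """Zipf- and Menzerath-model fits plus full/null deltas per subset.

    The prolific individual is the signaller with the most tokens; for the
    prolific-only subset the signaller intercept is replaced by date.  A
    subset that cannot be fitted is skipped with a warning.
    """
    base = build_model_frame(sequences)
    out: dict[str, dict] = {}
    for subset in subsets:
        try:
            frame = _apply_subset(base, subset)
            entry: dict = {"n_tokens": len(frame)}
            for name in ("zipf", "menzerath"):
                spec = ModelSpec(name=name, subset=subset)
                entry[name] = fit_model(sequences, spec, frame=frame)
                if compare:
                    entry[f"{name}_delta"] = compare_full_null(
                        sequences, spec, frame=frame
                    )
            out[subset] = entry
        except StructuralError as exc:
            warnings.warn(f"subset {subset!r} skipped: {exc}")
    return out


def recovery_experiment(
    config: SimulationConfig,
    parameter: str = "beta_size",
    n_seeds: int = 10,
    spec: Optional[ModelSpec] = None,
) -> RecoverySummary:
    """Simulate → segment → fit, collecting estimate and interval per seed.

    ``beta_size`` is recovered by the Menzerath-model, ``beta_freq`` by the
    Zipf-model.  Seeds run config.seed .. config.seed+n_seeds-1; a failed
    fit is recorded, not fatal.
    """
    from .sequences import filter_complete, segment_sequences

    if parameter not in ("beta_freq", "beta_size"):
        raise ValueError("parameter must be 'beta_freq' or 'beta_size'")
    if spec is None:
        spec = ModelSpec(name="zipf" if parameter == "beta_freq" else "menzerath")
    term = "proportion" if parameter == "beta_freq" else "size_n"

    estimates, lows, highs, seeds = [], [], [], []
    n_failures = 0
    for i in range(n_seeds):
        seed = config.seed + i
        cfg = replace(config, seed=seed)
        try:
            tokens = simulate_tokens(cfg)
            kept, _ = filter_complete(segment_sequences(tokens))
            fit = fit_model(kept, spec)
            est = fit.coefficients[term]
        except (StructuralError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"seed {seed}: fit failed ({exc})")
            n_failures += 1
            continue
        estimates.append(est.estimate)
        lows.append(est.interval_low)
        highs.append(est.interval_high)
        seeds.append(seed)
    if not estimates:
        raise StructuralError("every seed failed to fit")
    return RecoverySummary(
        parameter=parameter,
        true_value=getattr(config, parameter),
        estimates=estimates,
        interval_lows=lows,
        interval_highs=highs,
        seeds=seeds,
        n_failures=n_failures,
    )
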