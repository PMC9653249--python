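"""Synthetic gesture-token streams with known ground truth.

The generator mirrors the hierarchical structure the downstream analyses
assume: sequences of gesture tokens whose log-durations are a linear
function of type frequency (brevity / Zipf effect), sequence size
(Menzerath effect) and gesture category, plus Gaussian random intercepts
for signaller, sequence and gesture type and a residual term.  Durations
are exponentiated and quantized up to the video frame (0.04 s), and tokens
are laid out on a timeline so that within-sequence gaps stay below the
segmentation threshold and between-sequence gaps stay above it — feeding
the output back through the segmenter recovers the simulated partition
exactly.

Defaults (``default_study_config``) reproduce the marginal structure of the
chimpanzee sexual-solicitation study: 16 signallers with one prolific
individual contributing about half the tokens, 26 gesture types (21 manual,
5 whole-body), 377 sequences with the published size distribution over
lengths 1–6, and lognormal-like durations spanning roughly 0.04–15 s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .types import FIXED, LOOSE, MANUAL, WHOLE_BODY, GestureToken

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "simulate_tokens",
    "simulate_with_truth",
    "default_study_config",
    "table1_fixture_tokens",
    "write_tokens_csv",
    "write_truth_json",
]

#: Published per-length sequence counts (lengths 1..6) of the analysed data.
TABLE1_TOTALS = (244, 82, 21, 3, 7, 2)
#: Same-type / different-type split per length >= 2 (lengths 2..6).
TABLE1_SAME = (24, 1, 0, 1, 0)
TABLE1_DIFFERENT = (58, 20, 3, 6, 2)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the generative model.

    Log-duration of each token is
    ``mu0 + beta_freq*p(type) + beta_size*n + beta_category*[whole_body]
    + u_signaller + u_sequence + u_type + eps``,
    with ``p(type)`` the *expected* type proportion implied by
    ``type_frequency_weights`` (so the ground-truth slope is well defined),
    ``n`` the sequence size, each ``u ~ Normal(0, sd)`` and
    ``eps ~ Normal(0, sd_resid)``.  Durations are ``exp(.)`` rounded up to
    the nearest ``frame`` (never below one frame).
    """

    n_signallers: int = 16
    prolific_fraction: float = 290 / 560
    n_types: int = 26
    n_manual: int = 21
    type_frequency_weights: list[float] = field(default_factory=list)
    beta_freq: float = 0.0
    beta_size: float = -0.18
    beta_category: float = 0.0
    sd_signaller: float = 0.30
    sd_sequence: float = 0.35
    sd_type: float = 0.35
    sd_resid: float = 0.70
    mu0: float = 0.75
    sequence_size_distribution: list[float] = field(default_factory=list)
    n_sequences: int = 377
    within_gap_max: float = 0.90
    between_gap_min: float = 5.0
    frame: float = 0.04
    seed: int = 0
    # optional structure: per-type duration form and category; filled by
    # __post_init__ when left empty
    type_forms: list[str] = field(default_factory=list)
    whole_body_types: list[int] = field(default_factory=list)
    n_recipients: int = 26
    sequences_per_date: float = 3.0

    def __post_init__(self) -> None:
        if not self.type_frequency_weights:
            self.type_frequency_weights = [
                (i + 1) ** -0.9 for i in range(self.n_types)
            ]
        if not self.sequence_size_distribution:
            total = sum(TABLE1_TOTALS)
            self.sequence_size_distribution = [c / total for c in TABLE1_TOTALS]
        if not self.whole_body_types:
            n_wb = self.n_types - self.n_manual
            if n_wb > 0:
                # spread whole-body types across the frequency ranks so
                # category is not confounded with frequency
                step = max(1, self.n_types // n_wb)
                self.whole_body_types = [
                    min(2 + step * k, self.n_types - 1) for k in range(n_wb)
                ]
        if not self.type_forms:
            self.type_forms = [LOOSE] * self.n_types
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_signallers < 1:
            raise ConfigError("n_signallers must be >= 1")
        if not (0.0 <= self.prolific_fraction <= 1.0):
            raise ConfigError("prolific_fraction must be in [0, 1]")
        if self.n_types < 1:
            raise ConfigError("n_types must be >= 1")
        if not (0 <= self.n_manual <= self.n_types):
            raise ConfigError("n_manual must be in [0, n_types]")
        if len(self.type_frequency_weights) != self.n_types:
            raise ConfigError("type_frequency_weights must have n_types entries")
        if any(w <= 0 for w in self.type_frequency_weights):
            raise ConfigError("type_frequency_weights must be positive")
        for name in ("sd_signaller", "sd_sequence", "sd_type", "sd_resid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        p = self.sequence_size_distribution
        if any(q < 0 for q in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigError("sequence_size_distribution must be a probability vector")
        if self.n_sequences < 0:
            raise ConfigError("n_sequences must be >= 0")
        if not self.within_gap_max < self.between_gap_min:
            raise ConfigError("within_gap_max must be < between_gap_min")
        if self.frame <= 0:
            raise ConfigError("frame must be > 0")
        if len(self.type_forms) != self.n_types:
            raise ConfigError("type_forms must have n_types entries")
        if any(f not in (FIXED, LOOSE) for f in self.type_forms):
            raise ConfigError("type_forms entries must be 'fixed' or 'loose'")
        if len(set(self.whole_body_types)) != self.n_types - self.n_manual:
            raise ConfigError("whole_body_types must list n_types - n_manual indices")
        if any(not (0 <= i < self.n_types) for i in self.whole_body_types):
            raise ConfigError("whole_body_types indices out of range")

    # -- expected type proportions (ground truth for beta_freq) ----------
    @property
    def type_proportions(self) -> np.ndarray:
        w = np.asarray(self.type_frequency_weights, dtype=float)
        return w / w.sum()

    # -- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=None)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Configuration matching the printed marginals of the solicitation study.

    16 signallers with the prolific individual at 290/560 token share; 26
    types (21 manual / 5 whole-body) with Zipf-like frequency weights; 377
    sequences drawn from the published length distribution; six mid-rank
    types marked fixed-duration so the expected fixed token share is about
    104/560.
    """
    cfg = SimulationConfig(seed=seed)
    forms = [LOOSE] * cfg.n_types
    for i in range(6, 12):  # mid-frequency ranks; expected token share ~0.18
        forms[i] = FIXED
    cfg.type_forms = forms
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generative model
# ---------------------------------------------------------------------------

def _signaller_weights(cfg: SimulationConfig) -> np.ndarray:
    """Per-signaller sequence weights: one prolific individual, geometric tail."""
    if cfg.n_signallers == 1:
        return np.array([1.0])
    rest = np.array([0.85 ** k for k in range(cfg.n_signallers - 1)])
    rest = rest / rest.sum() * (1.0 - cfg.prolific_fraction)
    return np.concatenate([[cfg.prolific_fraction], rest])


def _quantize_up(x: np.ndarray, frame: float) -> np.ndarray:
    """Round durations up to the nearest frame, never below one frame."""
    n_frames = np.maximum(1, np.ceil(x / frame - 1e-12).astype(np.int64))
    return n_frames


def simulate_with_truth(cfg: SimulationConfig) -> tuple[list[GestureToken], dict]:
    """Simulate a token stream; also return the ground-truth bookkeeping.

    The truth dict records the configured parameters plus the realized
    sequence partition (list of token-index lists), per-token sequence ids
    and sizes, and the expected type proportions.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frame = cfg.frame

    n_seq = cfg.n_sequences
    sizes_support = np.arange(1, len(cfg.sequence_size_distribution) + 1)
    sizes = rng.choice(sizes_support, size=n_seq, p=cfg.sequence_size_distribution)

    signaller_ids = [f"S{i + 1:02d}" for i in range(cfg.n_signallers)]
    seq_signaller_idx = rng.choice(
        cfg.n_signallers, size=n_seq, p=_signaller_weights(cfg)
    )

    # recording days: each signaller has a small pool of dates so a
    # date random term is meaningful for prolific individuals
    base = np.datetime64("2008-01-01")
    date_pools: list[np.ndarray] = []
    for s in range(cfg.n_signallers):
        expected = max(1.0, float(np.sum(seq_signaller_idx == s)))
        n_dates = max(1, int(round(expected / cfg.sequences_per_date)))
        offsets = np.sort(rng.choice(2200, size=n_dates, replace=False))
        date_pools.append(base + offsets.astype("timedelta64[D]"))
    seq_dates = np.array(
        [rng.choice(date_pools[s]) for s in seq_signaller_idx],
        dtype="datetime64[D]",
    )
    recipients = [f"F{i + 1:02d}" for i in range(cfg.n_recipients)]
    seq_recipient = rng.choice(cfg.n_recipients, size=n_seq)

    n_tokens = int(sizes.sum())
    p_type = cfg.type_proportions
    tok_type = rng.choice(cfg.n_types, size=n_tokens, p=p_type)

    u_sig = rng.normal(0.0, cfg.sd_signaller, size=cfg.n_signallers)
    u_seq = rng.normal(0.0, cfg.sd_sequence, size=n_seq)
    u_typ = rng.normal(0.0, cfg.sd_type, size=cfg.n_types)
    eps = rng.normal(0.0, cfg.sd_resid, size=n_tokens)

    tok_seq = np.repeat(np.arange(n_seq), sizes)
    wb = np.zeros(cfg.n_types, dtype=bool)
    wb[list(cfg.whole_body_types)] = True

    log_d = (
        cfg.mu0
        + cfg.beta_freq * p_type[tok_type]
        + cfg.beta_size * sizes[tok_seq]
        + cfg.beta_category * wb[tok_type]
        + u_sig[seq_signaller_idx[tok_seq]]
        + u_seq[tok_seq]
        + u_typ[tok_type]
        + eps
    )
    dur_frames = _quantize_up(np.exp(log_d), frame)

    # gaps, in frames: within-sequence gaps < threshold, between >= threshold
    within_f = int(cfg.within_gap_max / frame)  # floor: strictly below the cap
    gap_within = rng.integers(0, max(within_f, 1), size=n_tokens)
    between_f = int(math.ceil(cfg.between_gap_min / frame))
    gap_between = between_f + rng.integers(0, int(2.0 / frame) + 1, size=n_seq)

    type_names = [f"G{i + 1:02d}" for i in range(cfg.n_types)]

    # lay sequences out video by video; one video per (signaller, date)
    order = np.lexsort((seq_dates, seq_signaller_idx))
    tokens: list[Optional[GestureToken]] = [None] * n_tokens
    seq_token_indices: list[list[int]] = [[] for _ in range(n_seq)]
    tok_ptr = np.concatenate([[0], np.cumsum(sizes)])
    prev_key = None
    t = 0  # current time in frames
    for s_idx in order:
        sig = signaller_ids[seq_signaller_idx[s_idx]]
        date = str(seq_dates[s_idx])
        key = (sig, date)
        if key != prev_key:
            t = 0
            prev_key = key
        else:
            t += int(gap_between[s_idx])
        video = f"{sig}_{date}"
        rec = recipients[seq_recipient[s_idx]]
        for j in range(tok_ptr[s_idx], tok_ptr[s_idx + 1]):
            if j > tok_ptr[s_idx]:
                t += int(gap_within[j])
            start = t * frame
            end = (t + int(dur_frames[j])) * frame
            tokens[j] = GestureToken(
                signaller=sig,
                recipient=rec,
                date=date,
                video_id=video,
                gesture_type=type_names[tok_type[j]],
                category=WHOLE_BODY if wb[tok_type[j]] else MANUAL,
                duration_form=cfg.type_forms[tok_type[j]],
                start_s=round(start, 6),
                end_s=round(end, 6),
            )
            seq_token_indices[s_idx].append(j)
            t += int(dur_frames[j])

    truth = {
        "config": cfg.to_dict(),
        "type_proportions": p_type.tolist(),
        "sequence_sizes": sizes.tolist(),
        "sequence_signaller": [signaller_ids[i] for i in seq_signaller_idx],
        "sequence_token_indices": seq_token_indices,
        "n_tokens": n_tokens,
    }
    return [t for t in tokens if t is not None], truth


def simulate_tokens(cfg: SimulationConfig) -> list[GestureToken]:
    """Simulate a gesture-token stream; same seed and config give identical output."""
    tokens, _ = simulate_with_truth(cfg)
    return tokens


def simulate_null_repertoire(
    seed: int,
    n_types: int = 26,
    n_tokens: int = 530,
    meanlog: float = 0.45,
    sdlog: float = 0.6,
) -> list:
    """A repertoire whose duration summaries are exchangeable across types.

    Frequencies follow the default Zipf-like weights (multinomial over
    ``n_tokens``); each type's duration summary is an independent lognormal
    draw, so duration carries no information about frequency.  This is the
    null under which the brevity and compression permutation tests are
    calibrated: both tests permute the *type-level* duration vector, so
    their null assumes the d_i are exchangeable.  (Per-type duration means
    computed from very unequal token counts are heteroscedastic — frequent
    types have stabler means — which makes the one-sided compression test
    conservative rather than miscalibrated; see the methods notes.)
    """
    from .types import MANUAL, RepertoireEntry

    rng = np.random.default_rng(seed)
    w = np.array([(i + 1) ** -0.9 for i in range(n_types)])
    counts = rng.multinomial(n_tokens, w / w.sum())
    counts = np.maximum(counts, 1)  # every type observed at least once
    durs = rng.lognormal(meanlog, sdlog, size=n_types)
    total = counts.sum()
    return [
        RepertoireEntry(
            gesture_type=f"G{i + 1:02d}", category=MANUAL,
            n_tokens=int(c), proportion_p=float(c / total),
            mean_duration_s=float(d), median_duration_s=float(d),
        )
        for i, (c, d) in enumerate(zip(counts, durs))
    ]


# ---------------------------------------------------------------------------
# published contingency fixture
# ---------------------------------------------------------------------------

def table1_fixture_tokens(n_incomplete: int = 18) -> list[GestureToken]:
    """Deterministic stream realizing the published length/composition table.

    Builds 359 complete sequences — per-length totals (244, 82, 21, 3, 7, 2)
    with the published same-type/different-type split — plus ``n_incomplete``
    singleton sequences whose token end time is unknown, echoing the 377
    detected vs 359 analysed sequences of the study.
    """
    tokens: list[GestureToken] = []
    t = 0.0  # running clock, seconds; frame-aligned durations
    durations = [0.52, 1.00, 1.48, 2.00, 0.76]  # multiples of 0.04

    def emit(seq_types: list[str], incomplete: bool = False) -> None:
        nonlocal t
        for k, g in enumerate(seq_types):
            d = durations[(len(tokens) + k) % len(durations)]
            last = k == len(seq_types) - 1
            tokens.append(
                GestureToken(
                    signaller="S01",
                    recipient="F01",
                    date="2010-06-15",
                    video_id="V001",
                    gesture_type=g,
                    category=MANUAL,
                    duration_form=LOOSE,
                    start_s=round(t, 6),
                    end_s=None if (incomplete and last) else round(t + d, 6),
                )
            )
            t += d + (0.48 if not last else 3.0)  # within-gap 0.48 s, between 3 s

    spec_rows = [
        (1, 244, 0, 244),
        (2, 82, TABLE1_SAME[0], TABLE1_DIFFERENT[0]),
        (3, 21, TABLE1_SAME[1], TABLE1_DIFFERENT[1]),
        (4, 3, TABLE1_SAME[2], TABLE1_DIFFERENT[2]),
        (5, 7, TABLE1_SAME[3], TABLE1_DIFFERENT[3]),
        (6, 2, TABLE1_SAME[4], TABLE1_DIFFERENT[4]),
    ]
    for length, total, n_same, n_diff in spec_rows:
        if length == 1:
            for _ in range(total):
                emit(["A"])
            continue
        for _ in range(n_same):
            emit(["A"] * length)
        for _ in range(n_diff):
            emit(["A", "B"] * (length // 2) + ["A"] * (length % 2))
    for _ in range(n_incomplete):
        emit(["A"], incomplete=True)
    return tokens


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "signaller",
    "recipient",
    "date",
    "video_id",
    "gesture_type",
    "category",
    "duration_form",
    "start_s",
    "end_s",
]


def write_tokens_csv(tokens: list[GestureToken], path: str | Path) -> None:
    """Write the canonical token CSV (missing end times as empty cells)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "signaller": t.signaller,
                "recipient": t.recipient,
                "date": t.date,
                "video_id": t.video_id,
                "gesture_type": t.gesture_type,
                "category": t.category,
                "duration_form": t.duration_form,
                "start_s": t.start_s,
                "end_s": t.end_s,
            }
            for t in tokens
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_truth_json(truth: dict, path: str | Path) -> None:
    """Write the ground-truth sidecar (configured parameters + realization)."""
    Path(path).write_text(json.dumps(truth, indent=1))
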