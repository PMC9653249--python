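"""Token ingestion, sequence segmentation and repertoire summaries.

Segmentation implements the rapid-sequence rule: consecutive tokens by the
same signaller in the same video belong to one sequence when the gap
between them is strictly less than the threshold (default 1.0 s); a gap of
exactly the threshold, a change of signaller or video, or a token whose end
time is unknown (gap undefined) closes the sequence.  The gap is measured
end-to-start by default; start-to-start is available for sensitivity
analyses since the original coding convention is not documented.
"""

from __future__ import annotations

import statistics
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    FIXED,
    FRAME_S,
    LOOSE,
    GestureSequence,
    GestureToken,
    LengthCompositionRow,
    LengthCompositionTable,
    RepertoireEntry,
)

__all__ = [
    "read_tokens",
    "segment_sequences",
    "filter_complete",
    "length_composition_table",
    "repertoire_summary",
    "composition_by_size",
    "write_repertoire_csv",
    "write_contingency_csv",
    "write_sequences_csv",
    "TokenParseError",
]

REQUIRED_COLUMNS = [
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


class TokenParseError(ValueError):
    """Malformed token table; the message names the offending row/column."""


def read_tokens(path: str | Path, frame: float = FRAME_S) -> list[GestureToken]:
    """Read and validate the canonical token CSV.

    A blank ``end_s`` yields a token with missing duration (kept for
    segmentation, its sequence flagged incomplete).  Malformed times,
    ``end_s < start_s``, or durations that are not positive multiples of
    the video frame are rejected with the row number (1-based, excluding
    the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"date": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TokenParseError(f"missing required column(s): {', '.join(missing)}")

    tokens: list[GestureToken] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start = pd.to_numeric(pd.Series([row.start_s]), errors="coerce").iloc[0]
        if pd.isna(start):
            raise TokenParseError(f"row {i}: non-numeric start_s {row.start_s!r}")
        end_raw = row.end_s
        if pd.isna(end_raw) or (isinstance(end_raw, str) and not end_raw.strip()):
            end = None
        else:
            end = pd.to_numeric(pd.Series([end_raw]), errors="coerce").iloc[0]
            if pd.isna(end):
                raise TokenParseError(f"row {i}: non-numeric end_s {end_raw!r}")
            if end < start:
                raise TokenParseError(f"row {i}: end_s {end} < start_s {start}")
            d = end - start
            if abs(d / frame - round(d / frame)) > 1e-6 or d < frame - 1e-9:
                raise TokenParseError(
                    f"row {i}: duration {d:.6f} s is not a positive multiple "
                    f"of the {frame} s frame"
                )
        try:
            tokens.append(
                GestureToken(
                    signaller=str(row.signaller),
                    recipient=str(row.recipient),
                    date=str(row.date),
                    video_id=str(row.video_id),
                    gesture_type=str(row.gesture_type),
                    category=str(row.category),
                    duration_form=str(row.duration_form),
                    start_s=float(start),
                    end_s=None if end is None else float(end),
                )
            )
        except ValueError as exc:
            raise TokenParseError(f"row {i}: {exc}") from exc
    return tokens


def segment_sequences(
    tokens: Iterable[GestureToken],
    gap_threshold_s: float = 1.0,
    gap_mode: str = "end_to_start",
) -> list[GestureSequence]:
    """Partition a token stream into rapid sequences.

    Tokens are grouped by (signaller, video) and ordered by start time;
    within a group, a gap strictly below ``gap_threshold_s`` joins
    consecutive tokens into one sequence.  Overlapping tokens (negative
    gap) therefore always share a sequence.  A missing end time makes the
    next gap undefined and closes the sequence after that token.
    """
    if gap_threshold_s <= 0:
        raise ValueError("gap_threshold_s must be > 0")
    if gap_mode not in ("end_to_start", "start_to_start"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")

    ordered = sorted(tokens, key=lambda t: (t.signaller, t.video_id, t.start_s))
    sequences: list[GestureSequence] = []
    current: list[GestureToken] = []

    def flush() -> None:
        if current:
            sequences.append(
                GestureSequence(sequence_id=f"seq{len(sequences) + 1:04d}",
                                tokens=list(current))
            )
            current.clear()

    prev: GestureToken | None = None
    for tok in ordered:
        if prev is None:
            current.append(tok)
        else:
            same_group = (
                tok.signaller == prev.signaller and tok.video_id == prev.video_id
            )
            if same_group:
                ref = prev.start_s if gap_mode == "start_to_start" else prev.end_s
                gap = None if ref is None else tok.start_s - ref
            else:
                gap = None
            if gap is not None and gap < gap_threshold_s:
                current.append(tok)
            else:
                flush()
                current.append(tok)
        prev = tok
    flush()
    return sequences


def filter_complete(
    sequences: list[GestureSequence],
) -> tuple[list[GestureSequence], int]:
    """Drop every sequence containing a token of unknown duration.

    Returns the retained sequences and the number excluded; exclusion is
    per-sequence, mirroring the requirement that the duration of *all*
    consecutive tokens be identifiable.
    """
    kept = [s for s in sequences if s.complete]
    return kept, len(sequences) - len(kept)


def length_composition_table(
    sequences: list[GestureSequence],
) -> LengthCompositionTable:
    """Per-length totals with the same-type / different-type split (length >= 2)."""
    if not sequences:
        return LengthCompositionTable(rows=[])
    max_len = max(s.size_n for s in sequences)
    rows = []
    for length in range(1, max_len + 1):
        group = [s for s in sequences if s.size_n == length]
        if length == 1:
            rows.append(
                LengthCompositionRow(length, None, None, len(group))
            )
        else:
            n_same = sum(bool(s.same_type) for s in group)
            rows.append(
                LengthCompositionRow(length, n_same, len(group) - n_same, len(group))
            )
    return LengthCompositionTable(rows=rows)


def repertoire_summary(tokens: Iterable[GestureToken]) -> list[RepertoireEntry]:
    """Per-type counts, dataset proportions and duration summaries.

    Sorted by descending token count, ties broken alphabetically.  All
    tokens must carry a duration.
    """
    by_type: dict[str, list[GestureToken]] = {}
    for t in tokens:
        if t.duration_s is None:
            raise ValueError(
                f"token of type {t.gesture_type!r} has unknown duration; "
                "run filter_complete first"
            )
        by_type.setdefault(t.gesture_type, []).append(t)
    total = sum(len(v) for v in by_type.values())
    entries = [
        RepertoireEntry(
            gesture_type=g,
            category=toks[0].category,
            n_tokens=len(toks),
            proportion_p=len(toks) / total,
            mean_duration_s=statistics.fmean(t.duration_s for t in toks),
            median_duration_s=statistics.median(t.duration_s for t in toks),
        )
        for g, toks in by_type.items()
    ]
    entries.sort(key=lambda e: (-e.n_tokens, e.gesture_type))
    return entries


def composition_by_size(
    sequences: list[GestureSequence],
) -> dict[int, dict[str, float]]:
    """Per-size fractions of all-loose, all-fixed and mixed sequences.

    Probes whether long sequences merely swap fixed-duration gesture forms
    for loose ones; fractions sum to 1 within each size.
    """
    out: dict[int, dict[str, float]] = {}
    by_size: dict[int, list[GestureSequence]] = {}
    for s in sequences:
        by_size.setdefault(s.size_n, []).append(s)
    for size in sorted(by_size):
        group = by_size[size]
        n = len(group)
        n_loose = sum(all(t.duration_form == LOOSE for t in s.tokens) for s in group)
        n_fixed = sum(all(t.duration_form == FIXED for t in s.tokens) for s in group)
        out[size] = {
            "all_loose": n_loose / n,
            "all_fixed": n_fixed / n,
            "mixed": (n - n_loose - n_fixed) / n,
        }
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_repertoire_csv(entries: list[RepertoireEntry], path: str | Path) -> None:
    pd.DataFrame([e.__dict__ for e in entries]).to_csv(path, index=False)


def write_contingency_csv(table: LengthCompositionTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "length": r.length,
                "n_same_type": r.n_same_type,
                "n_different_type": r.n_different_type,
                "n_total": r.n_total,
            }
            for r in table.rows
        ]
    ).to_csv(path, index=False)


def write_sequences_csv(sequences: list[GestureSequence], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sequence_id": s.sequence_id,
                "signaller": s.signaller,
                "size_n": s.size_n,
                "pwb": s.pwb,
                "same_type": s.same_type,
                "mean_duration_s": s.mean_duration_s,
            }
            for s in sequences
        ]
    ).to_csv(path, index=False)
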