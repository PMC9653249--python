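"""End-to-end analysis pipeline: tokens → sequences → law tests → models.

`run_analysis` is the library face of the ``analyze`` CLI verb: it reads a
token CSV, segments and filters sequences, computes repertoire/contingency
summaries, runs the brevity, compression and Menzerath statistics, fits the
Zipf- and Menzerath-models per subset with full/null comparisons, and
writes a bundle of CSV/JSON outputs plus a human-readable summary.

All randomness derives from a single configured seed, fanned out to the
permutation tests and any simulation stages, so two runs with the same
inputs produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .lawstats import brevity_correlation, compression_test, menzerath_stats
from .sequences import (
    composition_by_size,
    filter_complete,
    length_composition_table,
    read_tokens,
    repertoire_summary,
    segment_sequences,
    write_contingency_csv,
    write_repertoire_csv,
    write_sequences_csv,
)
from .models import run_subset_analyses
from .types import ModelFitResult

log = logging.getLogger("gesturelaws")

__all__ = ["PipelineConfig", "run_analysis"]


@dataclass
class PipelineConfig:
    input_path: str
    out_dir: str
    gap_threshold_s: float = 1.0
    n_perm: int = 9999
    seed: int = 0
    subsets: list[str] = field(
        default_factory=lambda: ["all", "prolific_only", "exclude_prolific"]
    )
    fit_models: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.gap_threshold_s <= 0:
            raise ValueError("gap_threshold_s must be > 0")


def _coef_dict(fit: ModelFitResult) -> dict:
    return {
        "coefficients": {
            k: dataclasses.asdict(v) for k, v in fit.coefficients.items()
        },
        "n_tokens": fit.n_tokens,
        "random_terms": fit.random_terms,
        "variance_components": fit.variance_components,
        "converged": fit.converged,
        "engine": fit.engine,
    }


def run_analysis(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle into ``out_dir``.

    Returns the summary dictionary that is also serialized to
    ``analysis.json``.  Raises on empty input or unreadable tokens.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tokens = read_tokens(cfg.input_path)
    if not tokens:
        raise ValueError(f"no tokens found in {cfg.input_path}")
    log.info("read %d tokens from %s", len(tokens), cfg.input_path)

    sequences = segment_sequences(tokens, gap_threshold_s=cfg.gap_threshold_s)
    kept, n_excluded = filter_complete(sequences)
    log.info(
        "segmented %d sequences; %d excluded as incomplete, %d analysed",
        len(sequences), n_excluded, len(kept),
    )

    table = length_composition_table(kept)
    kept_tokens = [t for s in kept for t in s.tokens]
    repertoire = repertoire_summary(kept_tokens)
    composition = composition_by_size(kept)

    write_repertoire_csv(repertoire, out / "repertoire.csv")
    write_contingency_csv(table, out / "contingency.csv")
    write_sequences_csv(kept, out / "sequences.csv")

    t0 = time.time()

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw), None
        except ValueError as exc:
            log.warning("%s skipped: %s", fn.__name__, exc)
            return None, str(exc)

    brevity, brevity_err = _try(
        brevity_correlation, repertoire, n_perm=cfg.n_perm, seed=cfg.seed,
        exact=False,
    )
    compression, compression_err = _try(
        compression_test, repertoire, n_perm=cfg.n_perm, seed=cfg.seed + 1,
        exact=False,
    )
    menzerath, menzerath_err = _try(
        menzerath_stats, kept, n_perm=cfg.n_perm, seed=cfg.seed + 2
    )
    log.info("law statistics done in %.1f s", time.time() - t0)

    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "gap_threshold_s": cfg.gap_threshold_s,
        "n_tokens": len(tokens),
        "n_tokens_analysed": len(kept_tokens),
        "n_types": len(repertoire),
        "n_sequences_detected": len(sequences),
        "n_sequences_excluded": n_excluded,
        "n_sequences_analysed": len(kept),
        "length_composition": {
            r.length: {
                "same": r.n_same_type,
                "different": r.n_different_type,
                "total": r.n_total,
            }
            for r in table.rows
        },
        "composition_by_size": composition,
        "brevity": dataclasses.asdict(brevity) if brevity
        else {"error": brevity_err},
        "compression": dataclasses.asdict(compression)
        | {"optimization_eta": compression.optimization_eta}
        if compression else {"error": compression_err},
        "menzerath": dataclasses.asdict(menzerath)
        | {"points": None, "n_points": len(menzerath.points)}
        if menzerath else {"error": menzerath_err},
    }

    if cfg.fit_models:
        t0 = time.time()
        fits = run_subset_analyses(kept, subsets=cfg.subsets)
        summary["models"] = {
            subset: {
                "n_tokens": entry["n_tokens"],
                "zipf": _coef_dict(entry["zipf"]),
                "menzerath": _coef_dict(entry["menzerath"]),
                "zipf_delta": dataclasses.asdict(entry["zipf_delta"]),
                "menzerath_delta": dataclasses.asdict(entry["menzerath_delta"]),
            }
            for subset, entry in fits.items()
        }
        log.info("model fits done in %.1f s", time.time() - t0)

    summary["runtime_s"] = round(time.time() - t_start, 2)
    (out / "analysis.json").write_text(json.dumps(summary, indent=1))
    (out / "summary.txt").write_text(_format_summary(summary))
    return summary


def _interval(c: dict) -> str:
    return (
        f"{c['estimate']:+.3f} (sd {c['sd']:.3f}, "
        f"95% [{c['interval_low']:+.3f}, {c['interval_high']:+.3f}])"
    )


def _format_summary(s: dict) -> str:
    lines = [
        f"gesturelaws v{s['version']} analysis (seed {s['seed']}, "
        f"n_perm {s['n_perm']})",
        "",
        f"tokens read: {s['n_tokens']}  |  analysed: {s['n_tokens_analysed']} "
        f"across {s['n_types']} gesture types",
        f"sequences: {s['n_sequences_detected']} detected, "
        f"{s['n_sequences_excluded']} excluded (incomplete durations), "
        f"{s['n_sequences_analysed']} analysed",
        "",
        "Zipf's law of brevity (type frequency vs duration):",
        f"  rank correlation ({s['brevity']['method']}, "
        f"{s['brevity']['duration_summary']} durations): "
        f"{s['brevity']['coefficient']:+.3f}, p = {s['brevity']['p_value']:.4f}"
        if "error" not in s["brevity"]
        else f"  not computed: {s['brevity']['error']}",
        "Compression (mean code length vs permutation null):",
        f"  L_obs = {s['compression']['L_obs']:.3f} s, "
        f"null mean = {s['compression']['L_rand_mean']:.3f} s, "
        f"p = {s['compression']['p_value']:.4f}"
        if "error" not in s["compression"]
        else f"  not computed: {s['compression']['error']}",
        "Menzerath's law (sequence size vs constituent duration):",
        f"  rank correlation: {_fmt(s['menzerath']['coefficient'])}, "
        f"p = {_fmt(s['menzerath']['p_value'])}; "
        f"MAL fit d = a*n^b: b = {_fmt(s['menzerath']['mal_b'])}"
        if "error" not in s["menzerath"]
        else f"  not computed: {s['menzerath']['error']}",
    ]
    for subset, entry in s.get("models", {}).items():
        lines += ["", f"models on subset '{subset}' ({entry['n_tokens']} tokens):"]
        zc = entry["zipf"]["coefficients"].get("proportion")
        mc = entry["menzerath"]["coefficients"].get("size_n")
        zd, md = entry["zipf_delta"], entry["menzerath_delta"]
        lines.append(f"  zipf proportion:    {_interval(zc)}")
        note = "interval spans 0" if zc["interval_low"] <= 0 <= zc["interval_high"] \
            else "substantial effect"
        lines.append(f"    -> {note}; full-null delta {zd['delta']:+.1f} "
                     f"± {zd['delta_sd']:.1f}")
        lines.append(f"  menzerath size_n:   {_interval(mc)}")
        note = "interval spans 0" if mc["interval_low"] <= 0 <= mc["interval_high"] \
            else "substantial effect"
        lines.append(f"    -> {note}; full-null delta {md['delta']:+.1f} "
                     f"± {md['delta_sd']:.1f}")
    lines.append("")
    lines.append(f"runtime: {s['runtime_s']} s")
    return "\n".join(lines)


def _fmt(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{x:+.3f}"
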