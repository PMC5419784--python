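"""Event matching, precision/false-negative bookkeeping, delay statistics
and Bland-Altman agreement summaries.

Detected events are matched one-to-one to reference (or ground-truth)
events of the same leg and type by greedy nearest-in-time assignment within
a window (default 350 ms).  Unmatched detections are false positives,
unmatched references false negatives; precision = TP / (TP + FP).  Delays
are ``t_detected - t_reference`` in ms (positive = algorithm late); left
and right legs are pooled.  Bland-Altman limits are mean +/- 1.96 * SD of
the paired differences.

The first ``exclude_warmup_cycles`` gait cycles of each leg (delimited by
the reference IC events) are excluded *after* matching, so adaptive
threshold convergence at gait onset does not pollute the statistics nor
create boundary artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait_signals import EVENT_TYPES, GaitEvent

logger = logging.getLogger(__name__)

__all__ = ["MatchConfig", "DelayReport", "match_events", "evaluate_events",
           "summarize_pairs", "bland_altman_limits", "report_table",
           "bland_altman_plots"]

REPORT_EVENTS = ("IC", "FF", "HO", "TO")

SUMMARY_COLUMNS = ["variant", "event", "n_tp", "n_fp", "n_fn", "precision",
                   "mean_delay_ms", "sd_ms", "ba_lo_ms", "ba_hi_ms"]


@dataclass
class MatchConfig:
    window_ms: float = 350.0
    exclude_warmup_cycles: int = 1

    def validate(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("matching window must be > 0")
        if self.exclude_warmup_cycles < 0:
            raise ValueError("exclude_warmup_cycles must be >= 0")


def match_events(detected, reference, cfg: MatchConfig | None = None):
    """Greedy one-to-one nearest-in-time matching per leg and event type.

    Returns ``(pairs, false_positives, false_negatives)`` where each pair
    is ``(detected_event, reference_event, delay_ms)``.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    window_s = cfg.window_ms / 1000.0
    pairs: list[tuple[GaitEvent, GaitEvent, float]] = []
    fps: list[GaitEvent] = []
    fns: list[GaitEvent] = []
    keys = {(e.leg, e.event_type) for e in detected} | \
           {(e.leg, e.event_type) for e in reference}
    for leg, etype in sorted(keys):
        det = [e for e in detected if e.leg == leg and e.event_type == etype]
        ref = [e for e in reference if e.leg == leg and e.event_type == etype]
        cands = []
        for i, d in enumerate(det):
            for j, r in enumerate(ref):
                dt = d.time - r.time
                if abs(dt) <= window_s:
                    cands.append((abs(dt), i, j))
        cands.sort()
        used_d: set[int] = set()
        used_r: set[int] = set()
        for _, i, j in cands:
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            pairs.append((det[i], ref[j], (det[i].time - ref[j].time) * 1000.0))
        fps.extend(det[i] for i in range(len(det)) if i not in used_d)
        fns.extend(ref[j] for j in range(len(ref)) if j not in used_r)
    return pairs, fps, fns


def _warmup_boundaries(reference, n_cycles: int) -> dict[str, float]:
    """Per-leg time of the ``n_cycles``-th reference IC (0 if unavailable)."""
    bounds: dict[str, float] = {}
    if n_cycles <= 0:
        return bounds
    for leg in {e.leg for e in reference}:
        ics = sorted(e.time for e in reference
                     if e.leg == leg and e.event_type == "IC")
        if len(ics) > n_cycles:
            bounds[leg] = ics[n_cycles]
        elif ics:
            bounds[leg] = ics[-1]
    return bounds


def evaluate_events(detected, reference, cfg: MatchConfig | None = None):
    """Match, apply warm-up exclusion, and return (pairs, fps, fns)."""
    cfg = cfg or MatchConfig()
    pairs, fps, fns = match_events(detected, reference, cfg)
    bounds = _warmup_boundaries(reference, cfg.exclude_warmup_cycles)
    if bounds:
        def keep(ev: GaitEvent) -> bool:
            return ev.time >= bounds.get(ev.leg, 0.0)
        pairs = [p for p in pairs if keep(p[1])]
        fps = [e for e in fps if keep(e)]
        fns = [e for e in fns if keep(e)]
    return pairs, fps, fns


def pairs_frame(pairs, variant: str) -> pd.DataFrame:
    rows = [{
        "variant": variant, "event": r.event_type, "leg": r.leg,
        "t_detected_s": d.time, "t_reference_s": r.time,
        "delay_ms": delay, "avg_s": 0.5 * (d.time + r.time),
        "secondary": d.secondary,
    } for d, r, delay in pairs]
    return pd.DataFrame(rows, columns=["variant", "event", "leg",
                                       "t_detected_s", "t_reference_s",
                                       "delay_ms", "avg_s", "secondary"])


def bland_altman_limits(differences) -> tuple[float, float, float]:
    """(mean, lower, upper) with limits mean +/- 1.96 * sample SD."""
    arr = np.asarray(list(differences), float)
    if arr.size == 0:
        raise ValueError("no differences")
    mean = float(arr.mean())
    if arr.size == 1:
        logger.warning("single paired difference: SD degenerate, reported as 0")
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


@dataclass
class DelayReport:
    """Pooled matched-pair delays plus per-(variant, event) summary rows."""

    pairs: pd.DataFrame
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell(self, variant: str, event: str, column: str):
        sel = self.summary[(self.summary.variant == variant)
                           & (self.summary.event == event)]
        return sel[column].iloc[0] if len(sel) else None


def summarize_pairs(pairs_df: pd.DataFrame, fp_counts: dict, fn_counts: dict,
                    events=None) -> pd.DataFrame:
    """Summary rows per (variant, event): counts, precision, delay stats.

    ``fp_counts``/``fn_counts`` map (variant, event) -> int.  Precision is
    1.0 when there are TPs and no FPs, and absent (NaN) when TP + FP = 0.
    A (variant, event) with no pairs still gets a row when it has FP or FN
    counts, with absent delay cells.
    """
    rows = []
    variants = sorted(set(pairs_df.variant) | {v for v, _ in fp_counts}
                      | {v for v, _ in fn_counts})
    for variant in variants:
        evs = events or [e for e in EVENT_TYPES
                         if e in set(pairs_df.event) | {k[1] for k in fp_counts}
                         | {k[1] for k in fn_counts}]
        for event in evs:
            sel = pairs_df[(pairs_df.variant == variant)
                           & (pairs_df.event == event)]
            n_tp = len(sel)
            n_fp = int(fp_counts.get((variant, event), 0))
            n_fn = int(fn_counts.get((variant, event), 0))
            precision = n_tp / (n_tp + n_fp) if n_tp + n_fp > 0 else np.nan
            if n_tp > 0:
                mean, lo, hi = bland_altman_limits(sel.delay_ms)
                sd = float(sel.delay_ms.std(ddof=1)) if n_tp > 1 else 0.0
            else:
                mean = sd = lo = hi = np.nan
            rows.append({"variant": variant, "event": event, "n_tp": n_tp,
                         "n_fp": n_fp, "n_fn": n_fn, "precision": precision,
                         "mean_delay_ms": mean, "sd_ms": sd,
                         "ba_lo_ms": lo, "ba_hi_ms": hi})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def report_table(summary: pd.DataFrame, events=REPORT_EVENTS) -> pd.DataFrame:
    """Wide 'mean (SD)' table, one row per variant, one column per event.

    Cells with no matched pairs are rendered as absent (empty string),
    never as 0.
    """
    out = {}
    for variant, grp in summary.groupby("variant", sort=True):
        row = {}
        for event in events:
            sel = grp[grp.event == event]
            if len(sel) == 0 or sel.n_tp.iloc[0] == 0:
                row[event] = ""
            else:
                row[event] = (f"{sel.mean_delay_ms.iloc[0]:.2f} "
                              f"({sel.sd_ms.iloc[0]:.2f})")
        out[variant] = row
    df = pd.DataFrame(out).T[list(events)]
    df.index.name = "variant"
    return df


def bland_altman_plots(pairs_df: pd.DataFrame, outdir: str,
                       events=REPORT_EVENTS) -> list[str]:
    """Write one difference-vs-average plot per (variant, event); returns
    the written paths.  Plotting is side-effect only."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    written = []
    for (variant, event), sel in pairs_df.groupby(["variant", "event"]):
        if event not in events or len(sel) == 0:
            continue
        mean, lo, hi = bland_altman_limits(sel.delay_ms)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(sel.avg_s, sel.delay_ms, s=8, alpha=0.6)
        ax.axhline(mean, color="grey")
        for y in (lo, hi):
            ax.axhline(y, color="black", linestyle="--")
        ax.set_xlabel("average time (s)")
        ax.set_ylabel("delay (ms)")
        ax.set_title(f"{variant} {event}")
        fig.tight_layout()
        path = os.path.join(outdir, f"ba_{variant}_{event}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
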