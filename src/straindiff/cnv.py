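"""Depth-ratio copy-number analysis between two strains.

Read counts for a test and a reference strain, both mapped to the same
reference genome, are tiled into fixed windows (default 414 bp). The
log2 of the library-size-scaled depth ratio is normalized so the average
ratio per chromosome is 1, and each window is assigned a two-sided
p-value for departure from ratio 1 using the Geary-Hinkley transformation
of a ratio of Poisson counts:

    t = (x - r0 * R * y) / sqrt(x + r0^2 * R^2 * y),   R = N_test / N_ref

with null ratio r0 = 1 and Poisson variance = mean, so t is approximately
standard normal under the null. Runs of consecutive extreme windows
(|log2| >= 0.6, >= 3 windows) are merged into CNV segments with a Fisher
combined p-value.

The -4 display cap on log2 ratios applies to serialization only, never to
the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval

LOG2_DISPLAY_CAP = -4.0
DEFAULT_WINDOW = 414
DEFAULT_THRESHOLD = 0.6


@dataclass
class DepthWindow:
    interval: GenomicInterval
    count_test: float
    count_ref: float
    ratio: float
    log2_ratio: float
    p_value: float
    flagged: bool = False  # reference count of 0 (excluded from normalization)


@dataclass
class CnvSegment:
    interval: GenomicInterval
    mean_log2: float
    direction: str  # gain | loss
    p_value: float
    n_windows: int
    genes: tuple = ()


def window_counts(depth: dict[str, np.ndarray], window: int = DEFAULT_WINDOW,
                  lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Sum a per-base depth track into non-overlapping windows.

    The last partial window is kept with its true width. ``lengths`` guards
    against a track/genome mismatch."""
    if window < 50:
        raise ValueError("window must be >= 50")
    out = {}
    for chrom, arr in depth.items():
        arr = np.asarray(arr, dtype=float)
        if lengths is not None and chrom in lengths and len(arr) != lengths[chrom]:
            raise ValueError(f"depth track length mismatch on {chrom}")
        n_win = (len(arr) + window - 1) // window
        pad = n_win * window - len(arr)
        out[chrom] = np.pad(arr, (0, pad)).reshape(n_win, window).sum(axis=1)
    return out


def window_pvalue(count_test, count_ref, total_test, total_ref):
    """Two-sided Geary-Hinkley p-value for a window's depth ratio vs 1.

    Vectorized over window counts. A reference count of 0 is tested against
    a pseudo-count of 0.5 (callers flag such windows)."""
    if total_test <= 0 or total_ref <= 0:
        raise ValueError("library totals must be positive")
    x = np.asarray(count_test, dtype=float)
    y = np.asarray(count_ref, dtype=float)
    y = np.where(y == 0, 0.5, y)
    R = total_test / total_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x - R * y) / np.sqrt(x + R * R * y)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(t))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def log2_ratio_track(
    test_windows: dict[str, np.ndarray],
    ref_windows: dict[str, np.ndarray],
    window: int = DEFAULT_WINDOW,
    lengths: dict[str, int] | None = None,
    normalization: str = "ratio",  # ratio | track | none
) -> list[DepthWindow]:
    """Per-window normalized log2 depth ratio with Geary-Hinkley p-values.

    ``normalization='ratio'`` divides each chromosome's ratios by their mean
    so the average ratio per chromosome is 1 (windows with zero reference
    count are flagged and excluded from the mean); ``'track'`` instead
    rescales the test track to the reference track mean per chromosome
    before forming the ratio; ``'none'`` applies library-size scaling only.
    """
    if set(test_windows) != set(ref_windows):
        raise ValueError("test/reference window tilings disagree")
    total_test = sum(float(v.sum()) for v in test_windows.values())
    total_ref = sum(float(v.sum()) for v in ref_windows.values())
    out: list[DepthWindow] = []
    for chrom in test_windows:
        x = np.asarray(test_windows[chrom], dtype=float)
        y = np.asarray(ref_windows[chrom], dtype=float)
        if len(x) != len(y):
            raise ValueError(f"window count mismatch on {chrom}")
        if y.sum() == 0:
            import logging

            logging.getLogger(__name__).warning(
                "chromosome %s has an all-zero reference track; skipped", chrom
            )
            continue
        flagged = y == 0
        if normalization == "track":
            x = x * (y[~flagged].mean() / max(x[~flagged].mean(), 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (x / total_test) / np.where(y == 0, np.nan, y) * total_ref
        if normalization == "ratio":
            m = np.nanmean(ratio[~flagged])
            ratio = ratio / m
        ratio = np.where(np.isnan(ratio), 0.0, ratio)
        with np.errstate(divide="ignore"):
            log2 = np.log2(ratio)
        p = window_pvalue(x, y, total_test, total_ref)
        n = lengths[chrom] if lengths else len(x) * window
        for i in range(len(x)):
            s = i * window
            e = min(s + window, n) if lengths else s + window
            out.append(
                DepthWindow(
                    GenomicInterval(chrom, s, e), float(x[i]), float(y[i]),
                    float(ratio[i]), float(log2[i]), float(p[i]), bool(flagged[i]),
                )
            )
    return out


def call_segments(
    windows: list[DepthWindow],
    threshold: float = DEFAULT_THRESHOLD,
    min_windows: int = 3,
    genes=None,
) -> list[CnvSegment]:
    """Merge maximal runs of >= min_windows consecutive same-sign windows
    with |log2 ratio| >= threshold into CNV segments (Fisher combined p)."""
    segs: list[CnvSegment] = []
    by_chrom: dict[str, list[DepthWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.interval.seq_id, []).append(w)
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.interval.start)
        run: list[DepthWindow] = []
        run_sign = 0

        def flush():
            if len(run) >= min_windows:
                _, p = stats.combine_pvalues([w.p_value for w in run], method="fisher")
                iv = GenomicInterval(chrom, run[0].interval.start, run[-1].interval.end)
                seg_genes = tuple(
                    g.gene_id for g in (genes or []) if g.interval.overlaps(iv)
                )
                segs.append(
                    CnvSegment(
                        iv,
                        float(np.mean([w.log2_ratio for w in run])),
                        "gain" if run_sign > 0 else "loss",
                        float(p),
                        len(run),
                        seg_genes,
                    )
                )

        for w in ws:
            sign = 1 if w.log2_ratio >= threshold else (-1 if w.log2_ratio <= -threshold else 0)
            if sign and sign == run_sign:
                run.append(w)
            else:
                flush()
                run = [w] if sign else []
                run_sign = sign
        flush()
    segs.sort(key=lambda s: (s.interval.seq_id, s.interval.start))
    return segs


def windows_to_frame(windows: list[DepthWindow], cap: float = LOG2_DISPLAY_CAP) -> pd.DataFrame:
    """Serializable table of windows; log2 ratios capped at ``cap`` for
    display (statistics are never capped)."""
    return pd.DataFrame(
        {
            "chr": [w.interval.seq_id for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
            "count_test": [w.count_test for w in windows],
            "count_ref": [w.count_ref for w in windows],
            "log2_ratio": [max(w.log2_ratio, cap) for w in windows],
            "p_value": [w.p_value for w in windows],
        }
    )


def segments_to_frame(segments: list[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chr": [s.interval.seq_id for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "p_value": [s.p_value for s in segments],
            "log2_ratio": [s.mean_log2 for s in segments],
            "direction": [s.direction for s in segments],
            "n_windows": [s.n_windows for s in segments],
            "genes": [",".join(s.genes) for s in segments],
        }
    )
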