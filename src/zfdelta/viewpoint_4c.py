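"""Viewpoint-anchored (4C) interaction profiles and condition ratios.

Raw per-fragment ligation counts are normalized to reads per million over
the included fragments (the viewpoint and its immediate neighbors are
excluded: self-ligation and undigested template dominate there), then
smoothed with a centered running mean.  Enhancer–promoter interaction
change between conditions is the ratio of mean smoothed signal over the
fragments overlapping each target interval.  This is a deliberately
transparent, parameter-light normalization; it supports ratio-of-conditions
comparisons, not significance claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FragmentProfile:
    """Normalized, smoothed viewpoint interaction profile."""

    fragments: pd.DataFrame      # contig, start, end (0-based half-open)
    raw: np.ndarray
    viewpoint: int
    excluded: np.ndarray         # fragment indices carrying no value
    normalized: np.ndarray       # RPM over included fragments; NaN excluded
    smoothed: np.ndarray         # running mean; NaN at excluded


def normalize_viewpoint_profile(fragments: pd.DataFrame, counts,
                                viewpoint: int, exclude: int = 2,
                                smooth_w: int = 5) -> FragmentProfile:
    """RPM-normalize and smooth a viewpoint fragment-count profile.

    Fragments within ``exclude`` of the viewpoint are excluded; included
    counts are scaled to sum to 1e6; the smoothed value at an included
    fragment is the mean of normalized values over the centered window of
    width ``smooth_w`` (edges truncated, excluded fragments skipped).
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if len(fragments) != n:
        raise ValueError("fragments and counts length mismatch")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if not 0 <= viewpoint < n:
        raise ValueError("viewpoint fragment out of range")
    if smooth_w < 1 or smooth_w % 2 == 0:
        raise ValueError("smooth_w must be a positive odd integer")
    excluded = np.arange(max(0, viewpoint - exclude),
                         min(n, viewpoint + exclude + 1))
    included = np.ones(n, dtype=bool)
    included[excluded] = False
    total = counts[included].sum()
    if total <= 0:
        raise ValueError("all included counts are zero")
    normalized = np.full(n, np.nan)
    normalized[included] = counts[included] / total * 1e6
    h = (smooth_w - 1) // 2
    smoothed = np.full(n, np.nan)
    for i in np.flatnonzero(included):
        window = normalized[max(0, i - h):min(n, i + h + 1)]
        smoothed[i] = np.nanmean(window)
    return FragmentProfile(fragments=fragments.reset_index(drop=True),
                           raw=counts, viewpoint=viewpoint,
                           excluded=excluded, normalized=normalized,
                           smoothed=smoothed)


def interaction_delta(p_ref: FragmentProfile, p_alt: FragmentProfile,
                      targets: pd.DataFrame) -> pd.DataFrame:
    """Per-target interaction signal in each condition and their ratio.

    ``targets`` needs contig/start/end columns on the shared fragment grid.
    Signal = mean smoothed value over fragments overlapping the target
    (excluded fragments omitted); ratio = alt / ref, NaN when the reference
    signal is zero or the target is fully excluded.
    """
    if len(p_ref.fragments) != len(p_alt.fragments):
        raise ValueError("profiles must share the fragment grid")
    frags = p_ref.fragments
    rows = []
    for _, t in targets.iterrows():
        overlap = ((frags["contig"] == t["contig"])
                   & (frags["end"] > t["start"])
                   & (frags["start"] < t["end"])).values
        usable = overlap & np.isfinite(p_ref.smoothed) \
            & np.isfinite(p_alt.smoothed)
        if not usable.any():
            rows.append({"contig": t["contig"], "start": t["start"],
                         "end": t["end"], "signal_ref": np.nan,
                         "signal_alt": np.nan, "ratio": np.nan})
            continue
        s_ref = float(p_ref.smoothed[usable].mean())
        s_alt = float(p_alt.smoothed[usable].mean())
        ratio = s_alt / s_ref if s_ref > 0 else np.nan
        rows.append({"contig": t["contig"], "start": t["start"],
                     "end": t["end"], "signal_ref": s_ref,
                     "signal_alt": s_alt, "ratio": ratio})
    return pd.DataFrame(rows)


def read_fragment_counts(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a fragment-count TSV (contig, start, end, count)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    frags = df[["contig", "start", "end"]]
    return frags, df["count"].to_numpy(dtype=float)


def write_profile_bedgraph(profile: FragmentProfile, path,
                           which: str = "smoothed") -> None:
    """Write the normalized or smoothed profile as bedGraph."""
    vals = getattr(profile, which)
    keep = np.isfinite(vals)
    out = profile.fragments.loc[keep, ["contig", "start", "end"]].copy()
    out["value"] = vals[keep]
    out.to_csv(path, sep="\t", index=False, header=False)
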