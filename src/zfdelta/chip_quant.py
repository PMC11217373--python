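"""Spike-in normalized differential ChIP quantification.

Two-condition coverage comparison in the spike-in design: an equal amount of
exogenous chromatin is added to each ChIP, so after sequencing-depth (RPGC)
normalization any residual difference in the exogenous signal reflects
global efficiency/depth imbalance.  The averaged spike-in peak profile's
summit ratio (reference / sample) is the per-sample scale factor; the
reference sample's factor is fixed at 1.  Scaled tracks are then compared
per site by summit coverage, yielding a log2 fold change, a four-group
classification and a downregulation flag (log2(ref/alt) > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORM_STATES = ("raw", "rpgc", "rpgc+scaled")


@dataclass
class ScaledTrack:
    """Per-contig binned coverage carrying its normalization state."""

    data: dict[str, np.ndarray]
    bin_size: int
    norm_state: str = "raw"
    applied_factor: float | None = None

    def __post_init__(self):
        if self.norm_state not in NORM_STATES:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")
        for contig, vals in self.data.items():
            vals = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"coverage on {contig} must be finite and >= 0")
            self.data[contig] = vals

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy_with(self, scale: float, norm_state: str,
                  applied_factor: float | None = None) -> "ScaledTrack":
        return ScaledTrack({c: v * scale for c, v in self.data.items()},
                           bin_size=self.bin_size, norm_state=norm_state,
                           applied_factor=applied_factor)


@dataclass
class ScaleFactors:
    """Per-sample spike-in scale factors; the reference factor is 1."""

    reference: str
    summit_ref: float
    summits: dict[str, float]          # sample -> spike meta-profile summit
    factors: dict[str, float] = field(init=False)

    def __post_init__(self):
        if self.summit_ref <= 0:
            raise ValueError("reference summit must be positive")
        self.factors = {self.reference: 1.0}
        for sample, summit in self.summits.items():
            if summit <= 0:
                raise ValueError(f"summit for {sample} must be positive")
            self.factors[sample] = self.summit_ref / summit

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "factor": f,
                 "summit": self.summit_ref if s == self.reference
                 else self.summits[s]}
                for s, f in self.factors.items()]
        return pd.DataFrame(rows)


def normalize_rpgc(track: ScaledTrack, effective_genome_size: int) -> ScaledTrack:
    """Reads-per-genome-coverage normalization: mean per-bp coverage becomes 1.

    Multiplies every bin by ``effective_genome_size / (total * bin_size)``.
    """
    if track.norm_state != "raw":
        raise ValueError("RPGC normalization applies to raw tracks only "
                         f"(got state {track.norm_state!r})")
    if effective_genome_size <= 0:
        raise ValueError("effective genome size must be positive")
    total = track.total()
    if total <= 0:
        raise ValueError("cannot RPGC-normalize a track with zero coverage")
    scale = effective_genome_size / (total * track.bin_size)
    return track.copy_with(scale, "rpgc")


def spikein_meta_profile(track: ScaledTrack, spike_contig: str,
                         spike_peaks, half_width: int) -> np.ndarray:
    """Average summit-centered coverage windows over spike-in peaks.

    ``spike_peaks`` is an iterable of (start, end) bp intervals on the spike
    contig.  Each peak's summit is the (leftmost) argmax bin within the peak;
    windows of ``half_width`` bp either side of the summit are averaged
    element-wise.  Peaks whose window leaves the contig are skipped with a
    warning.
    """
    if half_width < track.bin_size:
        raise ValueError("half_width must be at least one bin")
    if spike_contig not in track.data:
        raise KeyError(f"spike contig {spike_contig!r} not in track")
    cov = track.data[spike_contig]
    bs = track.bin_size
    hw = half_width // bs
    windows = []
    skipped = 0
    for start, end in spike_peaks:
        b0, b1 = start // bs, max(start // bs + 1, -(-end // bs))
        b1 = min(b1, len(cov))
        if b1 <= b0:
            skipped += 1
            continue
        summit = b0 + int(np.argmax(cov[b0:b1]))
        if summit - hw < 0 or summit + hw + 1 > len(cov):
            skipped += 1
            continue
        windows.append(cov[summit - hw: summit + hw + 1])
    if skipped:
        warnings.warn(f"{skipped} spike peak(s) skipped (window off contig)")
    if not windows:
        raise ValueError("no usable spike peaks")
    return np.mean(windows, axis=0)


def compute_scale_factor(profile_ref: np.ndarray, profile_sample: np.ndarray,
                         reference: str = "ref",
                         sample: str = "alt") -> ScaleFactors:
    """Scale factor = summit(reference profile) / summit(sample profile)."""
    summit_ref = float(np.max(profile_ref))
    summit_sample = float(np.max(profile_sample))
    if summit_ref <= 0 or summit_sample <= 0:
        raise ValueError("spike profiles must be positive at their summit")
    return ScaleFactors(reference=reference, summit_ref=summit_ref,
                        summits={sample: summit_sample})


def apply_scale(track: ScaledTrack, factors: ScaleFactors,
                sample_id: str) -> ScaledTrack:
    """Multiply an RPGC track by its sample's spike-in scale factor."""
    if track.norm_state != "rpgc":
        raise ValueError("scale factors apply to RPGC tracks only "
                         f"(got state {track.norm_state!r})")
    if sample_id not in factors.factors:
        raise KeyError(f"unknown sample id {sample_id!r}")
    f = factors.factors[sample_id]
    return track.copy_with(f, "rpgc+scaled", applied_factor=f)


def quantify_site_strength(track_ref: ScaledTrack, track_alt: ScaledTrack,
                           peaks: pd.DataFrame,
                           epsilon: float | None = None,
                           epsilon_frac: float = 0.01) -> pd.DataFrame:
    """Per-peak summit strengths in both conditions and log2 fold change.

    ``peaks`` needs columns contig/start/end (0-based half-open).  The summit
    is the leftmost argmax of *reference* coverage within the peak; strengths
    are the scaled coverage at that summit bin in each condition.  log2fc =
    log2((ref + eps) / (alt + eps)) with eps defaulting to 1% of the
    genome-wide mean scaled coverage (pseudocount against empty bins).
    """
    if track_ref.bin_size != track_alt.bin_size:
        raise ValueError("tracks must share bin_size")
    bs = track_ref.bin_size
    if epsilon is None:
        nbins = sum(len(v) for v in track_ref.data.values())
        epsilon = epsilon_frac * track_ref.total() / max(nbins, 1)
        epsilon = max(epsilon, 1e-9)
    rows = []
    for _, peak in peaks.iterrows():
        contig = peak["contig"]
        if contig not in track_ref.data or contig not in track_alt.data:
            raise KeyError(f"peak contig {contig!r} not covered by tracks")
        cov_r = track_ref.data[contig]
        cov_a = track_alt.data[contig]
        b0 = int(peak["start"]) // bs
        b1 = -(-int(peak["end"]) // bs)
        if b0 < 0 or b1 > len(cov_r) or b1 <= b0:
            raise ValueError(f"peak {contig}:{peak['start']}-{peak['end']} "
                             "outside track")
        summit_bin = b0 + int(np.argmax(cov_r[b0:b1]))  # leftmost on ties
        s_ref = float(cov_r[summit_bin])
        s_alt = float(cov_a[summit_bin]) if summit_bin < len(cov_a) else 0.0
        rows.append({
            "contig": contig, "start": int(peak["start"]),
            "end": int(peak["end"]),
            "summit": summit_bin * bs - int(peak["start"]),
            "strength_ref": s_ref, "strength_alt": s_alt,
            "log2fc": float(np.log2((s_ref + epsilon) / (s_alt + epsilon))),
        })
    table = pd.DataFrame(rows)
    for col in peaks.columns:
        if col not in table.columns:
            table[col] = peaks[col].values
    return table


def classify_fc_groups(table: pd.DataFrame, mode: str = "quartile",
                       thresholds=None,
                       downreg_cutoff: float = 1.0) -> pd.DataFrame:
    """Assign each site a fold-change group (1..4) and a downregulation flag.

    Group 4 collects the strongest binding losses (largest log2(ref/alt));
    group 1 the smallest.  ``quartile`` mode ranks sites by log2fc ascending
    and splits them into four equal-count groups (remainder to earlier
    groups); ``fixed`` mode cuts at three user thresholds.  A site is
    downregulated iff log2fc > ``downreg_cutoff``.
    """
    if not np.all(np.isfinite(table["log2fc"])):
        raise ValueError("log2fc must be finite for all sites")
    table = table.copy()
    n = len(table)
    if mode == "quartile":
        if n < 4:
            raise ValueError("quartile mode needs at least 4 sites")
        # order-invariant ranking: ties broken by genomic position
        order = np.lexsort((table["start"].values, table["contig"].values,
                            table["log2fc"].values))
        sizes = [n // 4] * 4
        for i in range(n % 4):
            sizes[i] += 1
        groups = np.empty(n, dtype=int)
        pos = 0
        for g, size in enumerate(sizes, start=1):
            groups[order[pos:pos + size]] = g
            pos += size
    elif mode == "fixed":
        t = np.asarray(thresholds, dtype=float)
        if t.shape != (3,) or np.any(np.diff(t) <= 0):
            raise ValueError("fixed mode needs 3 strictly increasing "
                             "thresholds")
        groups = 1 + np.searchsorted(t, table["log2fc"].values, side="right")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table["group"] = groups
    table["downregulated"] = table["log2fc"].values > downreg_cutoff
    return table


def write_site_table(table: pd.DataFrame, path) -> None:
    """Write the site table as a BED6+ TSV."""
    out = table.copy()
    out["name"] = [f"site{i}" for i in range(len(out))]
    out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    cols = ["contig", "start", "end", "name", "score", "strand", "summit",
            "strength_ref", "strength_alt", "log2fc"]
    for extra in ("group", "downregulated"):
        if extra in out.columns:
            cols.append(extra)
    out[cols].to_csv(path, sep="\t", index=False)
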