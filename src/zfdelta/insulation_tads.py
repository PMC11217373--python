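"""Contact-matrix balancing, insulation scores, TAD boundaries and the
four-way two-condition TAD change taxonomy.

Boundaries are insulation-score minima whose drop from the flanking maxima
exceeds a strength cutoff (default 0.7, on the log2 insulation scale).  A
TAD is the region between two nearby boundaries.  Comparing boundary sets
between conditions, each region between consecutive shared boundaries is
classed stable (no change inside), fusion (boundary lost), separation
(boundary gained) or confusion (both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContactMatrix:
    """Symmetric per-contig contact matrix with bin size, weights and mask."""

    matrix: np.ndarray
    bin_size: int = 50_000
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None  # boolean, True = excluded bin

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.any(m < 0):
            raise ValueError("contacts must be nonnegative")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def balanced(self) -> bool:
        return self.weights is not None

    def balanced_matrix(self) -> np.ndarray:
        """Weight-scaled matrix with masked rows/columns set to NaN."""
        if self.weights is None:
            raise ValueError("matrix not balanced")
        b = self.matrix * np.outer(self.weights, self.weights)
        b[self.mask, :] = np.nan
        b[:, self.mask] = np.nan
        return b


def mask_low_coverage(cm: ContactMatrix, pct: float = 5.0) -> ContactMatrix:
    """Mask zero-coverage bins plus the lowest ``pct``% of nonzero bins.

    Coverage is the raw row marginal.  Zero-marginal bins are always masked;
    of the remaining bins, the ``floor(pct% * n_nonzero)`` with the smallest
    marginals are masked too.
    """
    if not 0 <= pct < 100:
        raise ValueError("pct must be in [0, 100)")
    marg = cm.matrix.sum(axis=1)
    mask = marg == 0
    nonzero = np.flatnonzero(~mask)
    k = int(np.floor(pct / 100.0 * len(nonzero)))
    if k > 0:
        order = nonzero[np.argsort(marg[nonzero], kind="stable")]
        mask[order[:k]] = True
    return ContactMatrix(cm.matrix, bin_size=cm.bin_size,
                         weights=cm.weights, mask=mask)


def balance_matrix(cm: ContactMatrix, tol: float = 1e-10,
                   max_iter: int = 5000, name: str = "contig"
                   ) -> ContactMatrix:
    """Symmetric (Knight–Ruiz style) balancing to unit row sums.

    Finds weights x with x_i M_ij x_j having row sums 1 on unmasked bins, by
    the fixed-point iteration x <- x / sqrt(rowsum(diag(x) M diag(x))).
    """
    keep = ~cm.mask
    sub = cm.matrix[np.ix_(keep, keep)]
    n = sub.shape[0]
    if n == 0:
        raise ValueError(f"{name}: all bins masked")
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError(f"{name}: zero-coverage bin in unmasked region; "
                         "mask low coverage first")
    x = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = x * (sub @ x)
        err = np.abs(s - 1.0).max()
        if err <= tol:
            converged = True
            break
        x = x / np.sqrt(s)
    if not converged:
        raise RuntimeError(f"balancing did not converge on {name} "
                           f"within {max_iter} iterations (err={err:.3g})")
    weights = np.full(cm.n_bins, np.nan)
    weights[keep] = x
    return ContactMatrix(cm.matrix, bin_size=cm.bin_size, weights=weights,
                         mask=cm.mask)


@dataclass
class InsulationTrack:
    """Per-bin insulation score (log2 ratio to the contig mean)."""

    scores: np.ndarray          # NaN where undefined
    window: int                 # bp
    bin_size: int

    @property
    def w_bins(self) -> int:
        return self.window // self.bin_size


def insulation_score(cm: ContactMatrix, window: int = 400_000,
                     max_masked_frac: float = 0.5) -> InsulationTrack:
    """Sliding-square insulation profile of a balanced matrix.

    For each bin b, the mean balanced contact in the square
    [b-w, b) x [b, b+w) with w = window / bin_size, log2-ratioed to the
    contig-wide mean of these square means.  Undefined within w of the
    contig ends and wherever the square is more than ``max_masked_frac``
    masked.
    """
    if window % cm.bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    w = window // cm.bin_size
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = cm.n_bins
    if 2 * w > n:
        raise ValueError("window larger than contig")
    B = cm.balanced_matrix()
    raw = np.full(n, np.nan)
    for b in range(w, n - w):
        square = B[b - w:b, b:b + w]
        nan_frac = np.isnan(square).mean()
        if nan_frac > max_masked_frac:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            raw[b] = np.nanmean(square)
    defined = np.isfinite(raw) & (raw > 0)
    if not defined.any():
        return InsulationTrack(np.full(n, np.nan), window, cm.bin_size)
    mean = np.nanmean(raw[defined])
    scores = np.full(n, np.nan)
    scores[defined] = np.log2(raw[defined] / mean)
    return InsulationTrack(scores, window, cm.bin_size)


@dataclass
class BoundarySet:
    """Called boundary bins with their insulation-drop strengths."""

    bins: np.ndarray
    strengths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=int)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if len(self.strengths) == 0 and len(self.bins) > 0:
            self.strengths = np.full(len(self.bins), np.nan)
        order = np.argsort(self.bins, kind="stable")
        self.bins = self.bins[order]
        self.strengths = self.strengths[order]
        if len(np.unique(self.bins)) != len(self.bins):
            raise ValueError("boundary bins must be unique")


def _local_minima(v: np.ndarray) -> list[int]:
    """Indices of local minima of a finite 1-D array; leftmost of plateaus."""
    mins = []
    n = len(v)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] > v[i]
        right_ok = j == n - 1 or v[j + 1] > v[i]
        interior = i > 0 and j < n - 1
        if left_ok and right_ok and interior:
            mins.append(i)
        i = j + 1
    return mins


def call_boundaries(ins: InsulationTrack,
                    strength_cutoff: float = 0.7) -> BoundarySet:
    """Boundaries = insulation minima with drop >= ``strength_cutoff``.

    The strength of a minimum is min(left flank max, right flank max) minus
    the minimum value, with each flank bounded by the neighboring minimum
    (or the end of the defined run).  Masked stretches split the track into
    independent runs, so no boundary falls inside a masked region.
    """
    bins, strengths = [], []
    scores = ins.scores
    defined = np.isfinite(scores)
    n = len(scores)
    start = 0
    while start < n:
        if not defined[start]:
            start += 1
            continue
        stop = start
        while stop < n and defined[stop]:
            stop += 1
        run = scores[start:stop]
        mins = _local_minima(run)
        edges = [0] + mins + [len(run) - 1]
        for k, m in enumerate(mins):
            left = run[edges[k]:m + 1].max()
            right = run[m:edges[k + 2] + 1].max()
            strength = min(left, right) - run[m]
            if strength >= strength_cutoff:
                bins.append(start + m)
                strengths.append(strength)
        start = stop
    return BoundarySet(np.array(bins, dtype=int), np.array(strengths))


def derive_tads(bs: BoundarySet) -> list[tuple[int, int]]:
    """Consecutive boundary pairs become TAD intervals (bin coordinates)."""
    if len(bs.bins) < 2:
        warnings.warn("fewer than 2 boundaries; no TADs derivable")
        return []
    return [(int(a), int(b)) for a, b in zip(bs.bins[:-1], bs.bins[1:])]


@dataclass
class TadChangeCall:
    """A region between shared boundaries with its change class."""

    start_bin: int
    end_bin: int
    change: str                        # stable | fusion | separation | confusion
    lost: list[int] = field(default_factory=list)
    gained: list[int] = field(default_factory=list)


def match_boundaries(bs_ref: BoundarySet, bs_alt: BoundarySet,
                     tol_bins: int = 1):
    """Greedy nearest matching of boundaries across conditions.

    Each reference boundary is matched to the nearest unmatched alternate
    boundary within ``tol_bins``; equidistant candidates resolve leftmost.
    Returns (shared pairs, lost reference bins, gained alternate bins).
    """
    alt = list(bs_alt.bins)
    taken = [False] * len(alt)
    shared, lost = [], []
    for rb in bs_ref.bins:
        best_j, best_d = None, None
        for j, ab in enumerate(alt):
            if taken[j]:
                continue
            d = abs(int(ab) - int(rb))
            if d > tol_bins:
                continue
            if best_d is None or d < best_d or (d == best_d and ab < alt[best_j]):
                best_j, best_d = j, d
        if best_j is None:
            lost.append(int(rb))
        else:
            taken[best_j] = True
            shared.append((int(rb), int(alt[best_j])))
    gained = [int(ab) for j, ab in enumerate(alt) if not taken[j]]
    return shared, lost, gained


def classify_tad_changes(bs_ref: BoundarySet, bs_alt: BoundarySet,
                         tol_bins: int = 1) -> list[TadChangeCall]:
    """Classify each region between consecutive shared boundaries.

    stable: no boundary lost or gained inside; fusion: >=1 reference
    boundary lost and none gained; separation: >=1 gained and none lost;
    confusion: both.  Regions outside the outermost shared boundaries are
    not analyzed.
    """
    shared, lost, gained = match_boundaries(bs_ref, bs_alt, tol_bins)
    anchors = sorted(rb for rb, _ in shared)
    calls = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        lost_in = [x for x in lost if a < x < b]
        gained_in = [x for x in gained if a < x < b]
        if lost_in and gained_in:
            change = "confusion"
        elif lost_in:
            change = "fusion"
        elif gained_in:
            change = "separation"
        else:
            change = "stable"
        calls.append(TadChangeCall(a, b, change, lost_in, gained_in))
    return calls


def tad_change_proportions(calls: list[TadChangeCall]) -> pd.Series:
    """Fraction of analyzed regions in each change class (sums to 1)."""
    classes = ["stable", "fusion", "separation", "confusion"]
    counts = pd.Series(0, index=classes, dtype=float)
    for call in calls:
        counts[call.change] += 1
    total = counts.sum()
    return counts / total if total else counts


def read_matrix_tsv(path, bin_size: int = 50_000) -> ContactMatrix:
    """Read a dense TSV contact matrix (header row/col = bin index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContactMatrix(df.values.astype(float), bin_size=bin_size)


def write_matrix_tsv(cm: ContactMatrix, path) -> None:
    idx = np.arange(cm.n_bins)
    pd.DataFrame(cm.matrix, index=idx, columns=idx).to_csv(path, sep="\t")
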