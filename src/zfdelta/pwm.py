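"""Position weight matrices with exact log-odds score p-values.

The scanner reports, for every window, an exact tail probability of its
log-odds score under an i.i.d. background model.  Exactness is obtained by
discretizing per-position log-odds to an integer grid and convolving the
per-position score distributions (the standard dynamic program used by
FIMO-class scanners); the scanner scores windows on the *same* integer grid,
so the DP tail and the score of any concrete word agree by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_GRANULARITY = 1e-3  # log2-odds units per integer score step


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8: A,C,G,T -> 0..3, anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(idx: np.ndarray) -> str:
    return "".join("ACGTN"[i if i >= 0 else 4] for i in idx)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class PWM:
    """A probability PWM over ACGT with a background model.

    Parameters
    ----------
    probs
        (L, 4) matrix of per-position base probabilities (rows sum to 1) or
        raw counts; counts are converted with ``pseudocount`` added per base.
    background
        Background base frequencies, summing to 1 (uniform by default).
    pseudocount
        Added per base and position when ``probs`` are counts.
    """

    def __init__(self, probs, background=None, pseudocount: float = 0.25,
                 name: str = "pwm"):
        mat = np.asarray(probs, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if np.any(mat < 0):
            raise ValueError("PWM entries must be nonnegative")
        if np.any(mat.sum(axis=1) <= 0):
            raise ValueError("PWM columns must have positive sums")
        row_sums = mat.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-6):
            # treat as counts
            mat = mat + pseudocount
            mat = mat / mat.sum(axis=1, keepdims=True)
        else:
            mat = mat / mat.sum(axis=1, keepdims=True)
        self.probs = mat
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        if np.any(background <= 0):
            raise ValueError("background frequencies must be positive")
        self.background = background
        self.pseudocount = pseudocount
        self.name = name
        if self.length < 4:
            raise ValueError("motif length must be >= 4")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p / background); zero probabilities floored."""
        p = np.maximum(self.probs, 1e-12)
        return np.log2(p / self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits (2 + sum p log2 p)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), background=self.background,
                   name=self.name + "_rc")

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[str]:
        """Draw n words from the PWM (independent positions)."""
        cum = self.probs.cumsum(axis=1)
        u = rng.random((n, self.length))
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        return [decode(row) for row in idx]

    @classmethod
    def from_consensus(cls, consensus: str, dominant: float = 0.9,
                       background=None, name: str = "pwm") -> "PWM":
        """Build a PWM from a consensus string; ``N`` positions are uniform.

        Non-N positions put ``dominant`` probability on the consensus base and
        split the remainder over the other three.
        """
        rows = []
        off = (1.0 - dominant) / 3.0
        for b in consensus.upper():
            if b == "N":
                rows.append([0.25] * 4)
            else:
                row = [off] * 4
                row[BASE_INDEX[b]] = dominant
                rows.append(row)
        return cls(np.array(rows), background=background, name=name)


@dataclass
class ScoreDistribution:
    """Exact null distribution of a PWM log-odds score on an integer grid."""

    granularity: float
    int_scores: np.ndarray      # (L, 4) integer per-position scores
    min_total: int              # smallest achievable integer total
    pmf: np.ndarray             # pmf[t] = P(total == min_total + t)
    tail: np.ndarray = field(init=False)  # tail[t] = P(total >= min_total + t)

    def __post_init__(self):
        self.tail = self.pmf[::-1].cumsum()[::-1]

    def score_word(self, word_idx: np.ndarray) -> int:
        """Integer score of an encoded word (no ambiguity codes)."""
        L = self.int_scores.shape[0]
        return int(self.int_scores[np.arange(L), word_idx].sum())

    def pvalue(self, int_score: int) -> float:
        """P(score >= int_score) under the background model."""
        t = int_score - self.min_total
        if t < 0:
            return 1.0
        if t >= len(self.tail):
            return 0.0
        return float(self.tail[t])

    def threshold_for_alpha(self, alpha: float) -> int:
        """Smallest integer score whose tail probability is <= alpha."""
        # tail is nonincreasing; find first index with tail <= alpha
        idx = np.searchsorted(-self.tail, -alpha, side="left")
        return self.min_total + int(idx)


def pwm_score_distribution(pwm: PWM,
                           granularity: float = DEFAULT_GRANULARITY
                           ) -> ScoreDistribution:
    """Exact distribution of the log-odds score under the background model.

    Discretizes each per-position log-odds to ``round(lo / granularity)`` and
    convolves the per-position pmfs (probabilities from the background).  The
    resulting tail function is exact on the integer grid shared with
    :func:`scan_sequence`.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    ints = np.round(pwm.log_odds / granularity).astype(np.int64)
    bg = pwm.background
    pmf = np.array([1.0])
    min_total = 0
    for pos in range(pwm.length):
        row = ints[pos]
        lo, hi = int(row.min()), int(row.max())
        vec = np.zeros(hi - lo + 1)
        for b in range(4):
            vec[row[b] - lo] += bg[b]
        pmf = np.convolve(pmf, vec)
        min_total += lo
    return ScoreDistribution(granularity=granularity, int_scores=ints,
                             min_total=min_total, pmf=pmf)


@dataclass
class MotifMatch:
    """A scored PWM match on a sequence."""

    contig: str
    start: int          # 0-based half-open core interval on the + strand
    end: int
    strand: str         # '+' or '-'
    score: float        # log2-odds
    pvalue: float
    primary: bool = False
    site_id: str | None = None


def _window_int_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer scores for every window; windows containing N get INT_MIN."""
    L = ints.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = ints[np.arange(L)[None, :], safe].sum(axis=1)
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def scan_sequence(seq: str, pwm: PWM, alpha: float = 1e-4,
                  contig: str = "seq",
                  dist: ScoreDistribution | None = None,
                  granularity: float = DEFAULT_GRANULARITY
                  ) -> list[MotifMatch]:
    """Scan both strands for PWM matches with exact p-value <= alpha.

    Returns matches sorted by position; the best match (lowest p, ties broken
    leftmost then '+' strand) carries ``primary=True``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    L = pwm.length
    if len(seq) < L:
        warnings.warn(f"sequence shorter than motif ({len(seq)} < {L}); "
                      "no matches possible")
        return []
    if dist is None:
        dist = pwm_score_distribution(pwm, granularity)
    thresh = dist.threshold_for_alpha(alpha)
    codes = encode(seq)
    ints_fwd = dist.int_scores
    ints_rc = ints_fwd[::-1, ::-1]
    matches: list[MotifMatch] = []
    for strand, ints in (("+", ints_fwd), ("-", ints_rc)):
        scores = _window_int_scores(codes, ints)
        for pos in np.flatnonzero(scores >= thresh):
            s = int(scores[pos])
            matches.append(MotifMatch(
                contig=contig, start=int(pos), end=int(pos) + L,
                strand=strand, score=s * dist.granularity,
                pvalue=dist.pvalue(s)))
    matches.sort(key=lambda m: (m.start, m.strand))
    if matches:
        best = min(matches, key=lambda m: (m.pvalue, m.start,
                                           0 if m.strand == "+" else 1))
        best.primary = True
    return matches


def best_window(seq: str, pwm: PWM,
                dist: ScoreDistribution | None = None) -> MotifMatch | None:
    """Best-scoring window on either strand, regardless of significance.

    Used for weak-motif regions where no window passes the scan threshold.
    """
    L = pwm.length
    if len(seq) < L:
        return None
    if dist is None:
        dist = pwm_score_distribution(pwm)
    codes = encode(seq)
    best: MotifMatch | None = None
    for strand, ints in (("+", dist.int_scores),
                         ("-", dist.int_scores[::-1, ::-1])):
        scores = _window_int_scores(codes, ints)
        if len(scores) == 0:
            continue
        pos = int(scores.argmax())
        s = int(scores[pos])
        if s == np.iinfo(np.int64).min:
            continue
        cand = MotifMatch(contig="region", start=pos, end=pos + L,
                          strand=strand, score=s * dist.granularity,
                          pvalue=dist.pvalue(s))
        key = (-cand.score, cand.start, 0 if cand.strand == "+" else 1)
        if best is None or key < (-best.score, best.start,
                                  0 if best.strand == "+" else 1):
            best = cand
    if best is not None:
        best.primary = True
    return best
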