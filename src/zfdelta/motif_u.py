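"""Upstream (U) motif analysis of CTCF binding sites.

CTCF reads its core consensus with central zinc fingers while ZFs 9-11
engage a second motif ~20 bp upstream of the core (the U motif).  This
module finds the core motif in each binding site (PWM scan with exact
p-values, default threshold 1e-4), extracts the 20 bp immediately 5' of the
core on the match strand, clusters those 20-mers by Hamming distance
(k-medoids, default k=10), labels information-rich clusters as U-motif
types (U1 = canonical, U2..Un = noncanonical variants by size) and tallies
the U-motif percentage within each fold-change group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import (PWM, MotifMatch, ScoreDistribution, best_window, encode,
                  pwm_score_distribution, revcomp, scan_sequence)

__all__ = [
    "PWM", "MotifMatch", "ScoreDistribution", "pwm_score_distribution",
    "scan_sequence", "scan_core_motif", "extract_upstream", "UpstreamSet",
    "hamming_distance_matrix", "hamming_cluster", "SubclusterResult",
    "assign_u_types", "u_proportions", "flank_logo",
]


def scan_core_motif(genome: dict[str, str], peaks: pd.DataFrame, pwm: PWM,
                    alpha: float = 1e-4) -> pd.DataFrame:
    """Primary core-motif match per peak.

    Scans both strands of each peak sequence; windows with exact p-value
    <= ``alpha`` are matches and the best one per peak (lowest p, then
    leftmost, then '+' strand) is retained as the site's core motif.
    Returns a frame aligned to ``peaks`` with match coordinates in genome
    space; peaks without a passing match get NaN rows.
    """
    dist = pwm_score_distribution(pwm)
    rows = []
    for i, peak in peaks.iterrows():
        seq = genome[peak["contig"]][int(peak["start"]):int(peak["end"])]
        matches = scan_sequence(seq, pwm, alpha=alpha, dist=dist,
                                contig=peak["contig"])
        primary = next((m for m in matches if m.primary), None)
        if primary is None:
            rows.append({"site_id": i, "contig": peak["contig"],
                         "core_start": np.nan, "core_end": np.nan,
                         "strand": None, "score": np.nan, "pvalue": np.nan})
        else:
            rows.append({"site_id": i, "contig": peak["contig"],
                         "core_start": int(peak["start"]) + primary.start,
                         "core_end": int(peak["start"]) + primary.end,
                         "strand": primary.strand, "score": primary.score,
                         "pvalue": primary.pvalue})
    return pd.DataFrame(rows).set_index("site_id")


@dataclass
class UpstreamSet:
    """Strand-oriented upstream flanks, one per retained site."""

    sequences: pd.Series            # site_id -> 20-mer (motif strand)
    flank_len: int
    n_excluded: int = 0


def extract_upstream(genome: dict[str, str], matches: pd.DataFrame,
                     flank_len: int = 20) -> UpstreamSet:
    """The ``flank_len`` bp immediately 5' of each core match, match strand.

    A '+' strand core at [s, e) yields genomic [s - flank, s); a '-' strand
    core yields the reverse complement of [e, e + flank).  Sites whose flank
    runs off the contig (or with no core match) are excluded and counted.
    """
    seqs = {}
    excluded = 0
    for site_id, m in matches.iterrows():
        if m["strand"] not in ("+", "-") or not np.isfinite(m["core_start"]):
            excluded += 1
            continue
        contig_seq = genome[m["contig"]]
        s, e = int(m["core_start"]), int(m["core_end"])
        if m["strand"] == "+":
            if s - flank_len < 0:
                excluded += 1
                continue
            seqs[site_id] = contig_seq[s - flank_len:s]
        else:
            if e + flank_len > len(contig_seq):
                excluded += 1
                continue
            seqs[site_id] = revcomp(contig_seq[e:e + flank_len])
    if excluded:
        warnings.warn(f"{excluded} site(s) excluded from upstream "
                      "extraction (no match or flank off contig)")
    return UpstreamSet(pd.Series(seqs, dtype=object), flank_len, excluded)


def hamming_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise Hamming distances; comparisons involving N weigh 1/2."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal length")
    enc = np.stack([encode(s) for s in seqs])  # N -> -1
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        a = enc[i]
        diff = (enc[i + 1:] != a[None, :]).astype(float)
        any_n = (enc[i + 1:] < 0) | (a[None, :] < 0)
        diff[any_n] = 0.5
        d = diff.sum(axis=1)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return dist


@dataclass
class SubclusterResult:
    """Hamming-distance subclusters of upstream sequences."""

    k: int
    assignment: pd.Series                 # site_id -> cluster id (0-based)
    medoids: list[str]
    pfms: list[np.ndarray]                # (L, 4) count matrices per cluster
    consensus: list[str]
    information: list[np.ndarray]         # per-position IC (bits)
    sizes: list[int] = field(default_factory=list)
    u_labels: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.sizes:
            self.sizes = [int((self.assignment == c).sum())
                          for c in range(self.k)]


def _pfm_from_seqs(seqs: list[str]) -> np.ndarray:
    """Count PFM; N contributes 1/4 to each base."""
    L = len(seqs[0])
    pfm = np.zeros((L, 4))
    for s in seqs:
        enc = encode(s)
        for pos, b in enumerate(enc):
            if b < 0:
                pfm[pos] += 0.25
            else:
                pfm[pos, b] += 1.0
    return pfm


def _information_content(pfm: np.ndarray) -> np.ndarray:
    """Per-position information relative to the cluster's own composition.

    Kullback–Leibler divergence (bits) of each position's base distribution
    from the position-averaged distribution of the same cluster.  Measuring
    against the cluster's own composition rather than a uniform background
    keeps compositionally skewed (e.g. AT-rich) clusters from mimicking a
    motif: a motif has position-specific bases, skew does not.
    """
    counts = pfm.sum(axis=1)
    p = pfm / counts[:, None]
    q = np.maximum(p.mean(axis=0), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    ic = terms.sum(axis=1)
    # small-sample correction: the plug-in estimator is biased upward by
    # ~(K-1)/(2 N ln 2) bits for N sequences over K=4 letters
    n_seqs = float(counts.mean())
    if n_seqs > 0:
        ic = ic - 3.0 / (2.0 * np.log(2) * n_seqs)
    return np.maximum(ic, 0.0)


def hamming_cluster(upstream: UpstreamSet, k: int = 10,
                    seed: int = 0, max_iter: int = 100) -> SubclusterResult:
    """k-medoids clustering of upstream sequences under Hamming distance.

    Deterministic given the seed and invariant to input order: candidates
    are ranked canonically (lexicographically by sequence), the start medoid
    is a seeded draw from that canonical order, the remaining initial
    medoids are farthest-point picks, and all ties break canonically.
    Clusters left empty are dissolved (k reduced, with a warning).  Final
    cluster ids are ordered by decreasing size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    site_ids = list(upstream.sequences.index)
    seqs = [str(s) for s in upstream.sequences.values]
    n = len(seqs)
    if n < k:
        raise ValueError(f"need at least k={k} sequences, got {n}")
    dist = hamming_distance_matrix(seqs)
    # canonical rank: lexicographic by sequence, stable across input order
    canon = sorted(range(n), key=lambda i: (seqs[i],))
    rank = np.empty(n, dtype=int)
    for r, i in enumerate(canon):
        rank[i] = r

    rng = np.random.default_rng(seed)
    medoids = [canon[int(rng.integers(n))]]
    while len(medoids) < k:
        d_min = dist[:, medoids].min(axis=1)
        best = max(range(n), key=lambda i: (d_min[i], -rank[i]))
        if d_min[best] == 0:
            break  # fewer distinct sequences than k
        medoids.append(best)
    k_eff = len(medoids)

    def assign(meds):
        d = dist[:, meds]
        # nearest medoid; ties to the canonically smallest medoid sequence
        order = sorted(range(len(meds)), key=lambda j: rank[meds[j]])
        best = np.full(n, -1)
        best_d = np.full(n, np.inf)
        for j in order:
            better = d[:, j] < best_d
            best[better] = j
            best_d[better] = d[better, j]
        return best

    labels = assign(medoids)
    prev_obj = np.inf
    for _ in range(max_iter):
        new_medoids = []
        for j in range(len(medoids)):
            members = np.flatnonzero(labels == j)
            if len(members) == 0:
                continue
            intra = dist[np.ix_(members, members)].sum(axis=1)
            best = min(range(len(members)),
                       key=lambda t: (intra[t], rank[members[t]]))
            new_medoids.append(int(members[best]))
        labels_new = assign(new_medoids)
        obj = sum(dist[i, new_medoids[labels_new[i]]] for i in range(n))
        if set(new_medoids) == set(medoids) or obj >= prev_obj:
            medoids, labels = new_medoids, labels_new
            break
        medoids, labels, prev_obj = new_medoids, labels_new, obj
    if len(medoids) < k:
        warnings.warn(f"k reduced from {k} to {len(medoids)} "
                      "(duplicate sequences or empty clusters)")
    k_eff = len(medoids)

    # canonical output order: by decreasing size, ties by medoid rank
    sizes = [int((labels == j).sum()) for j in range(k_eff)]
    order = sorted(range(k_eff), key=lambda j: (-sizes[j], rank[medoids[j]]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[j] for j in labels])
    medoids = [medoids[j] for j in order]

    pfms, consensus, ics = [], [], []
    for j in range(k_eff):
        members = [seqs[i] for i in np.flatnonzero(labels == j)]
        pfm = _pfm_from_seqs(members)
        pfms.append(pfm)
        consensus.append("".join("ACGT"[b] for b in pfm.argmax(axis=1)))
        ics.append(_information_content(pfm))
    return SubclusterResult(
        k=k_eff,
        assignment=pd.Series(labels, index=site_ids),
        medoids=[seqs[m] for m in medoids],
        pfms=pfms, consensus=consensus, information=ics,
        u_labels=[None] * k_eff)


def _best_alignment_similarity(cluster_pfm: np.ndarray,
                               canonical: PWM) -> float:
    """Best ungapped mean per-position Pearson r to the canonical U PWM.

    Only the canonical motif's informative positions (IC >= 0.1 bits) enter
    the correlation, so uniform spacer columns do not dilute the signal.
    Zero-variance column pairs contribute r = 0.
    """
    p_cluster = cluster_pfm / cluster_pfm.sum(axis=1, keepdims=True)
    p_canon = canonical.probs
    keep = canonical.information_content() >= 0.1
    if not keep.any():
        keep = np.ones(canonical.length, dtype=bool)
    Lc, Lu = p_cluster.shape[0], p_canon.shape[0]
    if Lu > Lc:
        raise ValueError("canonical U motif longer than the flank")
    best = -np.inf
    for off in range(Lc - Lu + 1):
        rs = []
        for pos in np.flatnonzero(keep):
            a = p_cluster[off + pos]
            b = p_canon[pos]
            sa, sb = a.std(), b.std()
            rs.append(float(np.corrcoef(a, b)[0, 1])
                      if sa > 0 and sb > 0 else 0.0)
        best = max(best, float(np.mean(rs)))
    return best


def assign_u_types(result: SubclusterResult, canonical_u: PWM,
                   ic_min: float = 0.3, sim_min: float = 0.8,
                   min_run: int = 6) -> SubclusterResult:
    """Label clusters as U-motif types.

    A cluster is U-like iff it has >= ``min_run`` consecutive positions with
    information content >= ``ic_min`` bits.  U-like clusters whose best
    ungapped alignment to the canonical U PWM reaches mean per-position
    Pearson r >= ``sim_min`` are labeled U1; the remaining U-like clusters
    get U2..Un ordered by decreasing size; non-U clusters get None.
    """
    u_like = []
    for j in range(result.k):
        ic = result.information[j]
        run = best = 0
        for v in ic:
            run = run + 1 if v >= ic_min else 0
            best = max(best, run)
        u_like.append(best >= min_run)
    labels: list[str | None] = [None] * result.k
    noncanon = []
    for j in range(result.k):
        if not u_like[j]:
            continue
        if _best_alignment_similarity(result.pfms[j], canonical_u) >= sim_min:
            labels[j] = "U1"
        else:
            noncanon.append(j)
    noncanon.sort(key=lambda j: -result.sizes[j])
    for rank_i, j in enumerate(noncanon, start=2):
        labels[j] = f"U{rank_i}"
    result.u_labels = labels
    return result


def u_proportions(sites: pd.DataFrame, result: SubclusterResult
                  ) -> pd.DataFrame:
    """Percent of U-motif sites per fold-change group.

    ``sites`` must carry ``group`` and ``downregulated`` columns indexed
    like the cluster assignment.  A site counts as U if its cluster carries
    any U label; the canonical-only tally (U1 clusters) is reported
    alongside.  Rows: groups 1..4 plus a ``downregulated`` summary row.
    Empty groups report NaN percents rather than 0.
    """
    is_u_cluster = np.array([lab is not None for lab in result.u_labels])
    is_u1_cluster = np.array([lab == "U1" for lab in result.u_labels])
    assigned = result.assignment
    site_u = assigned.map(lambda c: bool(is_u_cluster[c]))
    site_u1 = assigned.map(lambda c: bool(is_u1_cluster[c]))
    rows = []
    groups = sorted(sites["group"].unique())
    for g in groups:
        members = sites.index[sites["group"] == g]
        members = members.intersection(assigned.index)
        n = len(members)
        n_u = int(site_u.loc[members].sum()) if n else 0
        n_u1 = int(site_u1.loc[members].sum()) if n else 0
        rows.append({"group": str(g), "n_sites": n, "n_u": n_u,
                     "percent_u": 100.0 * n_u / n if n else np.nan,
                     "percent_u1": 100.0 * n_u1 / n if n else np.nan})
    down = sites.index[sites["downregulated"]].intersection(assigned.index)
    n = len(down)
    n_u = int(site_u.loc[down].sum()) if n else 0
    n_u1 = int(site_u1.loc[down].sum()) if n else 0
    rows.append({"group": "downregulated", "n_sites": n, "n_u": n_u,
                 "percent_u": 100.0 * n_u / n if n else np.nan,
                 "percent_u1": 100.0 * n_u1 / n if n else np.nan})
    return pd.DataFrame(rows)


def flank_logo(genome: dict[str, str], regions: pd.DataFrame, pwm: PWM,
               flank: int = 20) -> dict:
    """Best core match per region plus aggregate core/flank PFMs.

    Weak-motif mode: the best-scoring window on either strand is taken
    regardless of significance (promoter CTCF sites often carry degenerate
    cores).  Flanks are the ``flank`` bp on each side of the core on the
    match strand.  Returns per-region matches and count PFMs for the core,
    upstream and downstream flanks, for logo rendering.
    """
    dist = pwm_score_distribution(pwm)
    per_region = []
    cores, ups, downs = [], [], []
    skipped = 0
    for i, region in regions.iterrows():
        seq = genome[region["contig"]][int(region["start"]):
                                       int(region["end"])]
        if len(seq) < pwm.length:
            skipped += 1
            continue
        m = best_window(seq, pwm, dist=dist)
        if m is None:
            skipped += 1
            continue
        gs = int(region["start"])
        contig_seq = genome[region["contig"]]
        s, e = gs + m.start, gs + m.end
        if m.strand == "+":
            core = contig_seq[s:e]
            up = contig_seq[max(0, s - flank):s]
            down = contig_seq[e:e + flank]
        else:
            core = revcomp(contig_seq[s:e])
            up = revcomp(contig_seq[e:e + flank])
            down = revcomp(contig_seq[max(0, s - flank):s])
        per_region.append({"region": i, "core_start": s, "core_end": e,
                           "strand": m.strand, "score": m.score,
                           "core_seq": core})
        cores.append(core)
        if len(up) == flank:
            ups.append(up)
        if len(down) == flank:
            downs.append(down)
    if skipped:
        warnings.warn(f"{skipped} region(s) skipped (shorter than motif)")
    return {
        "matches": pd.DataFrame(per_region),
        "core_pfm": _pfm_from_seqs(cores) if cores else None,
        "upstream_pfm": _pfm_from_seqs(ups) if ups else None,
        "downstream_pfm": _pfm_from_seqs(downs) if downs else None,
    }
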