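"""Seeded synthetic data with known ground truth.

Generates the inputs the two-condition analysis expects, with a planted
registry (:class:`SyntheticTruth`) acting as the oracle for every recovery
test:

* genomes with non-overlapping planted core CTCF motifs, a seeded subset of
  which carry a 20-bp upstream (U) motif from one of several U families;
* two-condition ChIP coverage where the mutant condition loses a fixed
  multiplicative fraction ``delta`` of occupancy at U sites only, plus an
  exogenous spike-in contig whose occupancies are condition-invariant so
  that any cross-condition spike difference reflects depth alone;
* per-condition contact maps whose TAD boundary sets are related by an
  explicit edit list (deletions, insertions, replacements);
* a viewpoint-anchored 4C fragment profile with distance decay and targeted
  enhancer–promoter weakening in the mutant.

All randomness flows from a single seed through named per-stage streams, so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .chip_quant import ScaledTrack
from .insulation_tads import ContactMatrix
from .pwm import PWM, revcomp

# Planted motif models.  The core is a 19-bp CTCF-like consensus; the U
# families are 20-mers with a 12-bp informative block (flanks uniform),
# mimicking the canonical upstream motif (U1) and two noncanonical variants.
CORE_CONSENSUS = "TGGCCACCAGGGGGCGCTA"
CORE_PWM = PWM.from_consensus(CORE_CONSENSUS, dominant=0.92, name="core")
U_FAMILY_CONSENSUS = {
    "U1": "NNNCAGCAGGGGGCGCNNNN",
    "U2": "NNNTTAGCGCTAAGTCNNNN",
    "U3": "NNNGATCCATTGACGANNNN",
}
U_FAMILY_PWMS = {name: PWM.from_consensus(cons, dominant=0.92, name=name)
                 for name, cons in U_FAMILY_CONSENSUS.items()}
CANONICAL_U_PWM = U_FAMILY_PWMS["U1"]
# Upstream-context families for non-U sites.  Real CTCF-site flanks are not
# uniform random: they share degenerate repeat/promoter context.  These
# families alternate moderately conserved and fully degenerate positions, so
# they form their own Hamming clusters (keeping background flanks out of the
# U clusters) yet never show the contiguous high-information run that marks
# a U motif.
FLANK_LEN = 20
_BG_RNG = np.random.default_rng(20_240_001)


def _bg_family_pwm(i: int) -> PWM:
    cons = list("N" * FLANK_LEN)
    for pos in range(0, FLANK_LEN, 2):
        cons[pos] = "ACGT"[int(_BG_RNG.integers(4))]
    return PWM.from_consensus("".join(cons), dominant=0.85, name=f"bg{i}")


BG_FAMILY_PWMS = {f"bg{i + 1}": _bg_family_pwm(i + 1) for i in range(6)}

_STAGE_IDS = {"genome": 1, "sites": 2, "chip_ref": 3, "chip_alt": 4,
              "spike": 5, "hic_ref": 6, "hic_alt": 7, "fourc": 8,
              "boundaries": 9, "hic_vis": 10}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named per-stage random stream derived from the master seed."""
    if seed is None:
        raise ValueError("a seed is required; refusing silent nondeterminism")
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STAGE_IDS[stage],)))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``delta`` is the multiplicative occupancy loss at U sites in the mutant
    condition (0 = no effect, 1 = complete loss); ``depth_ref``/``depth_alt``
    multiply all expected read counts per condition, emulating library-size
    imbalance that spike-in normalization must absorb.
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 200_000
    n_sites: int = 400
    fraction_u: float = 0.3
    u_family_weights: dict = field(
        default_factory=lambda: {"U1": 0.6, "U2": 0.25, "U3": 0.15})
    occupancy_law: tuple = ("lognormal", 3.7, 0.85)  # mu, sigma of log reads
    isochore_block: int = 4_000       # bp; background composition block size
    isochore_alpha: float = 2.5       # Dirichlet concentration of block
    #                                   base composition (lower = skewier)
    delta: float = 0.8
    depth_ref: float = 1.0
    depth_alt: float = 1.0
    fragment_len: int = 200
    noise_rate: float = 5e-4          # background reads per bp per unit depth
    bin_size: int = 10
    # spike-in contig
    spike_contig: str = "spikein"
    spike_contig_len: int = 100_000
    n_spike_sites: int = 200
    spike_occupancy: float = 150.0
    # contact maps
    hic_bin_size: int = 50_000
    hic_n_bins: int = 240
    hic_base: float = 300.0
    hic_decay: float = 0.75           # contact distance-decay power
    tad_enrichment: float = 5.0
    hic_visibility_sigma: float = 0.2   # lognormal sd of per-bin visibility
    hic_junk_frac: float = 0.05       # unmappable-like bins (visibility ~ 0)
    hic_junk_visibility: float = 0.02
    wt_boundaries: dict | None = None     # contig -> sorted bin indices
    boundary_edits: dict | None = None    # contig -> [(op, ...), ...]
    # 4C
    n_fragments: int = 200
    fragment_size_4c: int = 2_000
    viewpoint: int = 100
    decay_exponent: float = 1.0
    fourc_amplitude: float = 20_000.0
    ep_targets: list = field(default_factory=list)  # (frag_lo, frag_hi, loss)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig requires a seed")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if not 0 <= self.fraction_u <= 1:
            raise ValueError("fraction_u must be in [0, 1]")
        for attr in ("contig_length", "n_sites", "fragment_len", "bin_size",
                     "spike_contig_len", "hic_bin_size", "hic_n_bins",
                     "n_fragments", "fragment_size_4c"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for lo, hi, loss in self.ep_targets:
            if not 0 < loss <= 1:
                raise ValueError("interaction loss factor must be in (0, 1]")

    @property
    def n_u_sites(self) -> int:
        # round half up, per the planting rule
        return int(np.floor(self.fraction_u * self.n_sites + 0.5))


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for every recovery test."""

    sites: pd.DataFrame            # contig, core_start, core_end, strand,
    #                                has_u, u_family, occ_ref, occ_alt,
    #                                upstream_seq
    spike_sites: pd.DataFrame      # position, occupancy (condition-invariant)
    true_depth_ratio: float
    boundaries_ref: dict = field(default_factory=dict)
    boundaries_alt: dict = field(default_factory=dict)


def _sample_occupancies(law: tuple, n: int, rng: np.random.Generator
                        ) -> np.ndarray:
    kind = law[0]
    if kind == "lognormal":
        _, mu, sigma = law
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if kind == "gamma":
        _, shape, scale = law
        return rng.gamma(shape, scale, size=n)
    if kind == "constant":
        return np.full(n, float(law[1]))
    raise ValueError(f"unknown occupancy law {kind!r}")


def make_genome_and_sites(cfg: SimConfig) -> tuple[dict[str, str],
                                                   SyntheticTruth]:
    """Random genome with planted, non-overlapping motif sites.

    Cores are sampled from the core PWM and written at the site position
    (reverse-complemented on '-' strand sites); each U site additionally gets
    a 20-mer sampled from its U family written immediately 5' of the core on
    the motif strand.  Exactly ``round(fraction_u * n_sites)`` sites carry a
    U motif (seeded sample without replacement).
    """
    rng_g = stage_rng(cfg.seed, "genome")
    rng_s = stage_rng(cfg.seed, "sites")
    L = CORE_PWM.length
    pad = 60
    unit = L + 2 * (FLANK_LEN + pad)
    per_contig = [cfg.n_sites // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_sites % cfg.n_contigs):
        per_contig[i] += 1
    margin = unit
    usable = cfg.contig_length - 2 * margin
    n_slots = usable // unit
    if max(per_contig) > n_slots:
        raise ValueError(
            f"contig_length {cfg.contig_length} too short for "
            f"{max(per_contig)} non-overlapping sites (capacity {n_slots})")

    genome: dict[str, str] = {}
    site_rows = []
    bases = np.array(list("ACGT"))

    def background(rng, length):
        # block-wise base composition (isochore-like heterogeneity)
        out = np.empty(length, dtype=bases.dtype)
        for s in range(0, length, cfg.isochore_block):
            e = min(s + cfg.isochore_block, length)
            comp = rng.dirichlet([cfg.isochore_alpha] * 4)
            out[s:e] = rng.choice(bases, size=e - s, p=comp)
        return out

    for c in range(cfg.n_contigs):
        name = f"chr{c + 1}"
        seq = background(rng_g, cfg.contig_length)
        slots = np.sort(rng_s.choice(n_slots, size=per_contig[c],
                                     replace=False))
        for slot in slots:
            strand = "+" if rng_s.random() < 0.5 else "-"
            core_start = margin + int(slot) * unit + FLANK_LEN + pad
            core = CORE_PWM.sample(rng_s, 1)[0]
            placed = core if strand == "+" else revcomp(core)
            seq[core_start:core_start + L] = list(placed)
            site_rows.append({"contig": name, "core_start": core_start,
                              "core_end": core_start + L, "strand": strand})
        genome[name] = "".join(seq)

    sites = pd.DataFrame(site_rows)
    n_u = cfg.n_u_sites
    u_idx = rng_s.choice(len(sites), size=n_u, replace=False)
    sites["has_u"] = False
    sites.loc[u_idx, "has_u"] = True
    families = list(cfg.u_family_weights)
    weights = np.array([cfg.u_family_weights[f] for f in families])
    weights = weights / weights.sum()
    sites["u_family"] = None
    sites["upstream_seq"] = None
    bg_families = list(BG_FAMILY_PWMS)
    mutable = {c: list(s) for c, s in genome.items()}
    for i in range(len(sites)):
        if sites.at[i, "has_u"]:
            fam = families[rng_s.choice(len(families), p=weights)]
            useq = U_FAMILY_PWMS[fam].sample(rng_s, 1)[0]
            sites.at[i, "u_family"] = fam
        else:
            # non-U sites carry a weak upstream context family, not uniform
            # random sequence (real flanks share repeat/promoter context)
            fam = bg_families[rng_s.integers(len(bg_families))]
            useq = BG_FAMILY_PWMS[fam].sample(rng_s, 1)[0]
        contig = sites.at[i, "contig"]
        seq = mutable[contig]
        s, e = sites.at[i, "core_start"], sites.at[i, "core_end"]
        if sites.at[i, "strand"] == "+":
            seq[s - FLANK_LEN:s] = list(useq)
        else:
            seq[e:e + FLANK_LEN] = list(revcomp(useq))
        sites.at[i, "upstream_seq"] = useq
    genome = {c: "".join(s) for c, s in mutable.items()}

    occ = _sample_occupancies(cfg.occupancy_law, len(sites), rng_s)
    sites["occ_ref"] = occ
    sites["occ_alt"] = np.where(sites["has_u"], occ * (1.0 - cfg.delta), occ)

    # spike contig: condition-invariant occupancies at evenly spaced sites
    rng_spike = stage_rng(cfg.seed, "spike")
    spike_margin = 2_000
    spacing = (cfg.spike_contig_len - 2 * spike_margin) // max(
        cfg.n_spike_sites - 1, 1)
    if spacing < 2 * cfg.fragment_len:
        raise ValueError("spike contig too short for requested spike sites")
    spike_pos = spike_margin + spacing * np.arange(cfg.n_spike_sites)
    spike_occ = cfg.spike_occupancy * rng_spike.lognormal(0.0, 0.2,
                                                          cfg.n_spike_sites)
    genome[cfg.spike_contig] = "".join(
        rng_spike.choice(bases, size=cfg.spike_contig_len))
    spike_sites = pd.DataFrame({"position": spike_pos,
                                "occupancy": spike_occ})

    boundaries_ref, boundaries_alt = {}, {}
    if cfg.wt_boundaries:
        for contig, bounds in cfg.wt_boundaries.items():
            ref = np.array(sorted(bounds), dtype=int)
            if np.any(ref < 0) or np.any(ref >= cfg.hic_n_bins):
                raise ValueError(f"boundary out of range on {contig}")
            edits = (cfg.boundary_edits or {}).get(contig, [])
            boundaries_ref[contig] = ref
            boundaries_alt[contig] = apply_boundary_edits(ref, edits)

    truth = SyntheticTruth(
        sites=sites, spike_sites=spike_sites,
        true_depth_ratio=cfg.depth_ref / cfg.depth_alt,
        boundaries_ref=boundaries_ref, boundaries_alt=boundaries_alt)
    return genome, truth


def apply_boundary_edits(ref: np.ndarray, edits) -> np.ndarray:
    """Apply ("del", b) / ("ins", b) / ("rep", old, new) edits to a set."""
    out = set(int(b) for b in ref)
    for edit in edits:
        op = edit[0]
        if op == "del":
            if edit[1] not in out:
                raise ValueError(f"cannot delete absent boundary {edit[1]}")
            out.remove(edit[1])
        elif op == "ins":
            if edit[1] in out:
                raise ValueError(f"cannot insert existing boundary {edit[1]}")
            out.add(edit[1])
        elif op == "rep":
            _, old, new = edit
            if old not in out or new in out:
                raise ValueError(f"bad replacement {old}->{new}")
            out.remove(old)
            out.add(new)
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return np.array(sorted(out), dtype=int)


def _deposit_fragments(cov: np.ndarray, mids: np.ndarray, flen: int,
                       bin_size: int) -> None:
    """Add fragment-overlap counts to a binned coverage vector in place."""
    starts = np.clip((mids - flen // 2).astype(int), 0,
                     len(cov) * bin_size - 1)
    ends = np.clip((mids + flen // 2).astype(int), 1, len(cov) * bin_size)
    b0 = starts // bin_size
    b1 = -(-ends // bin_size)
    diff = np.zeros(len(cov) + 1)
    np.add.at(diff, b0, 1.0)
    np.add.at(diff, b1, -1.0)
    cov += diff[:-1].cumsum()


def simulate_chip_coverage(genome: dict[str, str], truth: SyntheticTruth,
                           cfg: SimConfig) -> tuple[ScaledTrack, ScaledTrack]:
    """Raw binned two-condition ChIP coverage with spike-in.

    Per site, Poisson(occupancy x depth) fragments with midpoints from a
    truncated normal centered at the site summit (sd = fragment_len / 4,
    truncated at 2 sd), plus uniform background at ``noise_rate`` reads/bp.
    The spike contig uses the condition-invariant spike occupancies scaled
    only by condition depth.
    """
    if cfg.depth_ref <= 0 or cfg.depth_alt <= 0:
        raise ValueError("condition depths must be positive")
    tracks = []
    for cond, depth, stage in (("ref", cfg.depth_ref, "chip_ref"),
                               ("alt", cfg.depth_alt, "chip_alt")):
        rng = stage_rng(cfg.seed, stage)
        data: dict[str, np.ndarray] = {}
        for contig, seq in genome.items():
            n_bins = -(-len(seq) // cfg.bin_size)
            cov = np.zeros(n_bins)
            if contig == cfg.spike_contig:
                site_pos = truth.spike_sites["position"].values
                site_occ = truth.spike_sites["occupancy"].values
            else:
                sub = truth.sites[truth.sites["contig"] == contig]
                site_pos = ((sub["core_start"] + sub["core_end"]) // 2).values
                site_occ = sub[f"occ_{cond}"].values
            sd = cfg.fragment_len / 4.0
            for pos, occ in zip(site_pos, site_occ):
                n = rng.poisson(occ * depth)
                if n == 0:
                    continue
                mids = truncnorm.rvs(-2.0, 2.0, loc=pos, scale=sd, size=n,
                                     random_state=rng)
                _deposit_fragments(cov, mids, cfg.fragment_len, cfg.bin_size)
            n_bg = rng.poisson(cfg.noise_rate * len(seq) * depth)
            if n_bg:
                mids = rng.uniform(0, len(seq), size=n_bg)
                _deposit_fragments(cov, mids, cfg.fragment_len, cfg.bin_size)
            data[contig] = cov
        tracks.append(ScaledTrack(data, bin_size=cfg.bin_size,
                                  norm_state="raw"))
    return tracks[0], tracks[1]


def expected_contact_matrix(boundaries: np.ndarray, cfg: SimConfig
                            ) -> np.ndarray:
    """Noise-free expected contact matrix for a boundary set.

    E[i, j] = base * (|i-j| + 1)^(-decay), multiplied by the within-TAD
    enrichment factor when i and j fall in the same TAD (contig ends act as
    implicit boundaries).
    """
    n = cfg.hic_n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = cfg.hic_base * (dist + 1.0) ** (-cfg.hic_decay)
    tad_id = np.searchsorted(np.asarray(boundaries, dtype=int), idx,
                             side="right")
    same = tad_id[:, None] == tad_id[None, :]
    expected[same] *= cfg.tad_enrichment
    return expected


def _bin_visibility(cfg: SimConfig, protected: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-bin visibility factors (mappability/GC-like multiplicative bias).

    A ``hic_junk_frac`` fraction of bins is nearly invisible (unmappable
    regions, the low-coverage mask's intended target); junk bins are kept
    away from planted boundaries so ground-truth recovery stays defined.
    """
    n = cfg.hic_n_bins
    v = rng.lognormal(0.0, cfg.hic_visibility_sigma, n)
    n_junk = int(round(cfg.hic_junk_frac * n))
    allowed = np.ones(n, dtype=bool)
    for b in protected:
        allowed[max(0, b - 4):b + 5] = False
    candidates = rng.permutation(np.flatnonzero(allowed))
    # keep junk bins isolated: a run of masked bins near a boundary would
    # blank out its insulation square entirely
    junk: list[int] = []
    for c in candidates:
        if len(junk) >= n_junk:
            break
        if all(abs(int(c) - j) >= 6 for j in junk):
            junk.append(int(c))
    v[junk] = cfg.hic_junk_visibility
    return v


def simulate_contact_maps(truth: SyntheticTruth, cfg: SimConfig
                          ) -> tuple[dict[str, ContactMatrix],
                                     dict[str, ContactMatrix]]:
    """Poisson-sampled symmetric contact maps for both conditions.

    Both conditions share per-bin visibility biases (same genome), which
    balancing must remove; the expected contact structure differs only
    through the boundary sets.
    """
    rng_vis = stage_rng(cfg.seed, "hic_vis")
    visibility = {}
    for contig in truth.boundaries_ref:
        protected = np.union1d(truth.boundaries_ref[contig],
                               truth.boundaries_alt[contig])
        visibility[contig] = _bin_visibility(cfg, protected, rng_vis)
    out: list[dict[str, ContactMatrix]] = []
    for bounds, stage in ((truth.boundaries_ref, "hic_ref"),
                          (truth.boundaries_alt, "hic_alt")):
        rng = stage_rng(cfg.seed, stage)
        maps = {}
        for contig, b in bounds.items():
            v = visibility[contig]
            expected = expected_contact_matrix(b, cfg) * np.outer(v, v)
            upper = rng.poisson(np.triu(expected))
            m = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(
                np.diag(upper))
            maps[contig] = ContactMatrix(m.astype(float),
                                         bin_size=cfg.hic_bin_size)
        out.append(maps)
    return out[0], out[1]


def simulate_4c_profile(truth: SyntheticTruth, cfg: SimConfig
                        ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Viewpoint-anchored fragment counts for both conditions.

    Expected counts decay as (fragment distance + 1)^(-decay_exponent);
    mutant expected counts on each enhancer–promoter target interval are
    multiplied by the planted loss factor.
    """
    if not 0 <= cfg.viewpoint < cfg.n_fragments:
        raise ValueError("viewpoint fragment out of range")
    rng = stage_rng(cfg.seed, "fourc")
    idx = np.arange(cfg.n_fragments)
    expected = cfg.fourc_amplitude * (
        np.abs(idx - cfg.viewpoint) + 1.0) ** (-cfg.decay_exponent)
    expected_alt = expected.copy()
    for lo, hi, loss in cfg.ep_targets:
        if not 0 <= lo < hi <= cfg.n_fragments:
            raise ValueError("ep target out of fragment range")
        expected_alt[lo:hi] *= loss
    counts_ref = rng.poisson(expected).astype(float)
    counts_alt = rng.poisson(expected_alt).astype(float)
    fragments = pd.DataFrame({
        "contig": "chr4c",
        "start": idx * cfg.fragment_size_4c,
        "end": (idx + 1) * cfg.fragment_size_4c,
    })
    return fragments, counts_ref, counts_alt


def truth_peaks(truth: SyntheticTruth, half_width: int = 50) -> pd.DataFrame:
    """Consensus peak intervals centered on planted site summits."""
    sites = truth.sites
    summit = (sites["core_start"] + sites["core_end"]) // 2
    return pd.DataFrame({
        "contig": sites["contig"],
        "start": (summit - half_width).astype(int),
        "end": (summit + half_width).astype(int),
        "strand": sites["strand"],
    })


def spike_peak_intervals(truth: SyntheticTruth,
                         half_width: int = 100) -> list[tuple[int, int]]:
    """Peak intervals around spike-in site positions."""
    return [(int(p - half_width), int(p + half_width))
            for p in truth.spike_sites["position"]]


def random_boundary_plan(seed: int, n_contigs: int, n_bins: int = 240,
                         spacing: int = 20, tol_guard: int = 3,
                         edits_per_contig: int = 5
                         ) -> tuple[dict, dict]:
    """A seeded boundary layout plus deletion/insertion/replacement edits.

    Boundaries are laid out every ``spacing`` bins.  Edits touch only
    alternating interior boundaries (never the outermost ones), so each edit
    sits alone in a region between two boundaries that remain shared across
    conditions and its change class is unambiguous: deletion -> fusion,
    insertion (mid-TAD) -> separation, replacement (a boundary moved by
    ``tol_guard`` bins, beyond the matching tolerance) -> confusion.
    """
    rng = stage_rng(seed, "boundaries")
    wt, edits = {}, {}
    ops = ["del", "ins", "rep"]
    for c in range(n_contigs):
        name = f"hic{c + 1}"
        bounds = list(range(spacing, n_bins - spacing + 1, spacing))
        editable_idx = list(range(1, len(bounds) - 1, 2))
        if len(editable_idx) < edits_per_contig:
            raise ValueError("not enough editable boundaries; increase "
                             "n_bins or reduce edits_per_contig")
        rng.shuffle(editable_idx)
        contig_edits = []
        rot = int(rng.integers(3))
        for k, i in enumerate(sorted(editable_idx[:edits_per_contig])):
            op = ops[(k + rot) % 3]
            b = bounds[i]
            if op == "del":
                contig_edits.append(("del", b))
            elif op == "ins":
                contig_edits.append(("ins", b + spacing // 2))
            else:
                contig_edits.append(("rep", b, b + tol_guard))
        wt[name] = bounds
        edits[name] = contig_edits
    return wt, edits
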