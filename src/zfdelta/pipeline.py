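"""End-to-end orchestration of the two-condition analysis.

Runs the stages in dependency order on simulated (or user-supplied) data:
simulate -> spike-in ChIP normalization -> fold-change grouping -> core
motif scan -> upstream extraction -> Hamming subclustering -> U typing ->
per-group U proportions -> contact-map masking/balancing -> insulation ->
boundaries -> TAD change classes -> 4C profile ratios, and assembles a
reproducible report.  Identical config + seed gives identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip_quant, insulation_tads, motif_u, simgen, viewpoint_4c


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (defaults follow the study settings)."""

    seed: int = 7
    alpha: float = 1e-4               # core-motif scan p-value threshold
    flank_len: int = 20               # upstream flank length (bp)
    k_subclusters: int = 10           # Hamming subclusters
    downreg_cutoff: float = 1.0       # log2(ref/alt) above which a site
    #                                   counts as downregulated
    insulation_window: int = 400_000  # bp (300 kb preset for other tissues)
    resolution: int = 50_000          # contact-map bin size (bp)
    boundary_strength: float = 0.7    # insulation-drop cutoff
    low_cov_pct: float = 5.0          # masked percentile of nonzero bins
    tol_bins: int = 1                 # boundary matching tolerance
    epsilon_frac: float = 0.01        # log2fc pseudocount, fraction of mean
    group_mode: str = "quartile"
    outdir: str | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.flank_len < 1 or self.k_subclusters < 1:
            raise ValueError("flank_len and k_subclusters must be positive")
        if self.insulation_window % self.resolution != 0:
            raise ValueError("insulation window must be a multiple of the "
                             "resolution")
        if not 0 <= self.low_cov_pct < 100:
            raise ValueError("low_cov_pct must be in [0, 100)")
        if self.tol_bins < 0:
            raise ValueError("tol_bins must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    config: dict
    scale_factor: float
    group_counts: dict
    u_table: pd.DataFrame
    tad_proportions: dict
    tad_agreement: float | None
    fourc: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    stage_status: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "config": self.config,
            "scale_factor": self.scale_factor,
            "group_counts": {str(k): int(v)
                             for k, v in self.group_counts.items()},
            "u_table": self.u_table.to_dict(orient="records"),
            "tad_proportions": {k: float(v)
                                for k, v in self.tad_proportions.items()},
            "tad_agreement": self.tad_agreement,
            "fourc": self.fourc.to_dict(orient="records"),
            "n_warnings": len(self.warnings),
            "warnings": self.warnings,
            "stage_status": self.stage_status,
            "files": self.files,
        }


def _simulation_config(config: PipelineConfig) -> simgen.SimConfig:
    """The simulated study conditions for a full-pipeline run."""
    wt, edits = simgen.random_boundary_plan(config.seed, n_contigs=2)
    # the planted interaction loss covers the annotated element plus a
    # 2-fragment shoulder on each side (perturbations do not stop exactly at
    # annotation edges); the measured target below is the element itself
    return simgen.SimConfig(
        seed=config.seed,
        hic_bin_size=config.resolution,
        wt_boundaries=wt, boundary_edits=edits,
        ep_targets=[(138, 167, 0.5)],
    )


def run_pipeline(config: PipelineConfig,
                 sim_cfg: simgen.SimConfig | None = None) -> RunReport:
    """Execute all stages on simulated data and assemble a report."""
    config.validate()
    status: dict[str, str] = {}
    caught: list[str] = []
    if sim_cfg is None:
        sim_cfg = _simulation_config(config)

    def run_stage(name, fn):
        try:
            with warnings.catch_warnings(record=True) as ws:
                warnings.simplefilter("always")
                out = fn()
            caught.extend(f"{name}: {w.message}" for w in ws)
            status[name] = "ok"
            return out
        except Exception as exc:
            status[name] = f"failed: {exc}"
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    genome, truth = run_stage(
        "simulate", lambda: simgen.make_genome_and_sites(sim_cfg))
    track_ref, track_alt = run_stage(
        "chip_coverage",
        lambda: simgen.simulate_chip_coverage(genome, truth, sim_cfg))

    egs = sum(len(s) for c, s in genome.items() if c != sim_cfg.spike_contig)

    def chip():
        rpgc_ref = chip_quant.normalize_rpgc(track_ref, egs)
        rpgc_alt = chip_quant.normalize_rpgc(track_alt, egs)
        spike_peaks = simgen.spike_peak_intervals(truth)
        prof_ref = chip_quant.spikein_meta_profile(
            rpgc_ref, sim_cfg.spike_contig, spike_peaks, half_width=500)
        prof_alt = chip_quant.spikein_meta_profile(
            rpgc_alt, sim_cfg.spike_contig, spike_peaks, half_width=500)
        factors = chip_quant.compute_scale_factor(prof_ref, prof_alt)
        scaled_ref = chip_quant.apply_scale(rpgc_ref, factors, "ref")
        scaled_alt = chip_quant.apply_scale(rpgc_alt, factors, "alt")
        peaks = simgen.truth_peaks(truth)
        table = chip_quant.quantify_site_strength(
            scaled_ref, scaled_alt, peaks, epsilon_frac=config.epsilon_frac)
        table = chip_quant.classify_fc_groups(
            table, mode=config.group_mode,
            downreg_cutoff=config.downreg_cutoff)
        return factors, table

    factors, site_table = run_stage("chip_quant", chip)

    def motif():
        peaks = simgen.truth_peaks(truth)
        matches = motif_u.scan_core_motif(genome, peaks, simgen.CORE_PWM,
                                          alpha=config.alpha)
        upstream = motif_u.extract_upstream(genome, matches,
                                            flank_len=config.flank_len)
        clusters = motif_u.hamming_cluster(upstream, k=config.k_subclusters,
                                           seed=config.seed)
        clusters = motif_u.assign_u_types(clusters, simgen.CANONICAL_U_PWM)
        table = motif_u.u_proportions(site_table, clusters)
        return clusters, table

    clusters, u_table = run_stage("motif_u", motif)

    def tads():
        cm_ref, cm_alt = simgen.simulate_contact_maps(truth, sim_cfg)
        all_calls = []
        agree_n = agree_total = 0
        for contig in cm_ref:
            bs = {}
            for cond, cm in (("ref", cm_ref[contig]),
                             ("alt", cm_alt[contig])):
                cm = insulation_tads.mask_low_coverage(
                    cm, pct=config.low_cov_pct)
                cm = insulation_tads.balance_matrix(cm, name=contig)
                ins = insulation_tads.insulation_score(
                    cm, window=config.insulation_window)
                bs[cond] = insulation_tads.call_boundaries(
                    ins, strength_cutoff=config.boundary_strength)
            calls = insulation_tads.classify_tad_changes(
                bs["ref"], bs["alt"], tol_bins=config.tol_bins)
            all_calls.extend(calls)
            expected = expected_region_classes(
                truth.boundaries_ref[contig],
                (sim_cfg.boundary_edits or {}).get(contig, []))
            a, m = match_region_classes(expected, calls, config.tol_bins)
            agree_n += a
            agree_total += m
        props = insulation_tads.tad_change_proportions(all_calls)
        agreement = (100.0 * agree_n / agree_total) if agree_total else None
        return props.to_dict(), agreement

    tad_props, tad_agreement = run_stage("tads", tads)

    def fourc():
        frags, counts_ref, counts_alt = simgen.simulate_4c_profile(truth,
                                                                   sim_cfg)
        p_ref = viewpoint_4c.normalize_viewpoint_profile(
            frags, counts_ref, sim_cfg.viewpoint)
        p_alt = viewpoint_4c.normalize_viewpoint_profile(
            frags, counts_alt, sim_cfg.viewpoint)
        fs = sim_cfg.fragment_size_4c
        inset = 2  # annotated element = planted loss region minus shoulders
        targets = pd.DataFrame(
            [{"contig": "chr4c", "start": (lo + inset) * fs,
              "end": (hi - inset) * fs, "planted_loss": loss}
             for lo, hi, loss in sim_cfg.ep_targets])
        delta = viewpoint_4c.interaction_delta(p_ref, p_alt, targets)
        delta["planted_loss"] = targets["planted_loss"].values
        return delta

    fourc_table = run_stage("fourc", fourc)

    group_counts = site_table["group"].value_counts().sort_index().to_dict()
    report = RunReport(
        config=asdict(config),
        scale_factor=float(factors.factors["alt"]),
        group_counts=group_counts,
        u_table=u_table,
        tad_proportions=tad_props,
        tad_agreement=tad_agreement,
        fourc=fourc_table,
        warnings=caught,
        stage_status=status,
    )
    if config.outdir:
        write_report(report, config.outdir, site_table=site_table)
    return report


def expected_region_classes(boundaries_ref, edits) -> dict:
    """Map each edited region (ref-boundary pair) to its expected class.

    Regions are keyed by the flanking unedited reference boundaries; edits
    are assumed non-adjacent (the layout :func:`simgen.random_boundary_plan`
    produces).  Unedited regions between consecutive reference boundaries
    are stable.
    """
    ref = sorted(int(b) for b in boundaries_ref)
    edited: dict[tuple[int, int], str] = {}
    removed = set()
    for edit in edits:
        if edit[0] == "del":
            removed.add(edit[1])
        elif edit[0] == "rep":
            removed.add(edit[1])
    for edit in edits:
        if edit[0] == "del":
            b = edit[1]
            i = ref.index(b)
            edited[(ref[i - 1], ref[i + 1])] = "fusion"
        elif edit[0] == "ins":
            b = edit[1]
            left = max(x for x in ref if x < b and x not in removed)
            right = min(x for x in ref if x > b and x not in removed)
            edited[(left, right)] = "separation"
        elif edit[0] == "rep":
            old = edit[1]
            i = ref.index(old)
            edited[(ref[i - 1], ref[i + 1])] = "confusion"
    expected = dict(edited)
    for a, b in zip(ref[:-1], ref[1:]):
        spans = [key for key in edited if key[0] <= a and b <= key[1]]
        if not spans and a not in removed and b not in removed:
            expected[(a, b)] = "stable"
    return expected


def match_region_classes(expected: dict, calls, tol_bins: int = 1):
    """Pair called regions with expected regions, allowing boundary jitter.

    Called boundary positions wobble by up to the matching tolerance, so a
    called region (a, b) corresponds to an expected region (a', b') when
    both endpoints agree within ``tol_bins``.  Returns (n_agree, n_matched).
    """
    agree = matched = 0
    for call in calls:
        hits = [cls for (a, b), cls in expected.items()
                if abs(a - call.start_bin) <= tol_bins
                and abs(b - call.end_bin) <= tol_bins]
        if hits:
            matched += 1
            agree += hits[0] == call.change
    return agree, matched


def jaccard_matrix(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise Jaccard similarity |A n B| / |A u B| of named gene sets.

    Duplicates are dropped; the union of two empty sets is undefined and
    reported as NaN, not 0.
    """
    names = list(sets)
    clean = {k: set(v) for k, v in sets.items()}
    mat = np.ones((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            union = clean[a] | clean[b]
            if not union:
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = len(clean[a] & clean[b]) / len(union)
        if not clean[a]:
            mat[i, i] = np.nan
    return pd.DataFrame(mat, index=names, columns=names)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: RunReport, outdir,
                 site_table: pd.DataFrame | None = None) -> dict:
    """Write the report as JSON + TSV tables + a human-readable log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    u_path = out / "u_proportions.tsv"
    report.u_table.to_csv(u_path, sep="\t", index=False)
    files["u_proportions.tsv"] = _sha256(u_path)

    fourc_path = out / "fourc_ratios.tsv"
    report.fourc.to_csv(fourc_path, sep="\t", index=False)
    files["fourc_ratios.tsv"] = _sha256(fourc_path)

    if site_table is not None:
        site_path = out / "site_table.tsv"
        site_table.to_csv(site_path, sep="\t", index=False)
        files["site_table.tsv"] = _sha256(site_path)

    report.files = files
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True,
                  default=float)
        fh.write("\n")

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write("zfdelta pipeline report\n")
        for stage, st in report.stage_status.items():
            fh.write(f"stage {stage}: {st}\n")
        fh.write(f"scale factor (alt): {report.scale_factor:.4f}\n")
        fh.write(f"group counts: {report.group_counts}\n")
        fh.write(f"TAD proportions: {report.tad_proportions}\n")
        if report.tad_agreement is not None:
            fh.write(f"TAD edit agreement: {report.tad_agreement:.1f}%\n")
        fh.write(f"warnings ({len(report.warnings)}):\n")
        for w in report.warnings:
            fh.write(f"  - {w}\n")
    return files
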