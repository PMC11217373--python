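"""Shared fixtures: small seeded simulations reused across test modules."""

import warnings

import pytest

from zfdelta import chip_quant, motif_u, simgen


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation (seed 7): genome, truth, raw tracks."""
    cfg = simgen.SimConfig(seed=7)
    genome, truth = simgen.make_genome_and_sites(cfg)
    track_ref, track_alt = simgen.simulate_chip_coverage(genome, truth, cfg)
    return {"cfg": cfg, "genome": genome, "truth": truth,
            "track_ref": track_ref, "track_alt": track_alt}


@pytest.fixture(scope="session")
def chip_chain(default_sim):
    """Spike-in normalized site table for the default simulation."""
    cfg = default_sim["cfg"]
    genome = default_sim["genome"]
    truth = default_sim["truth"]
    egs = sum(len(s) for c, s in genome.items() if c != cfg.spike_contig)
    rpgc_ref = chip_quant.normalize_rpgc(default_sim["track_ref"], egs)
    rpgc_alt = chip_quant.normalize_rpgc(default_sim["track_alt"], egs)
    spikes = simgen.spike_peak_intervals(truth)
    prof_ref = chip_quant.spikein_meta_profile(rpgc_ref, cfg.spike_contig,
                                               spikes, 500)
    prof_alt = chip_quant.spikein_meta_profile(rpgc_alt, cfg.spike_contig,
                                               spikes, 500)
    factors = chip_quant.compute_scale_factor(prof_ref, prof_alt)
    scaled_ref = chip_quant.apply_scale(rpgc_ref, factors, "ref")
    scaled_alt = chip_quant.apply_scale(rpgc_alt, factors, "alt")
    peaks = simgen.truth_peaks(truth)
    table = chip_quant.quantify_site_strength(scaled_ref, scaled_alt, peaks)
    table = chip_quant.classify_fc_groups(table)
    return {"factors": factors, "table": table, "peaks": peaks,
            "scaled_ref": scaled_ref, "scaled_alt": scaled_alt}


@pytest.fixture(scope="session")
def motif_chain(default_sim, chip_chain):
    """Core scan -> upstream -> clusters -> U types for the default sim."""
    genome = default_sim["genome"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matches = motif_u.scan_core_motif(genome, chip_chain["peaks"],
                                          simgen.CORE_PWM, alpha=1e-4)
        upstream = motif_u.extract_upstream(genome, matches, flank_len=20)
        clusters = motif_u.hamming_cluster(upstream, k=10, seed=7)
        clusters = motif_u.assign_u_types(clusters, simgen.CANONICAL_U_PWM)
    return {"matches": matches, "upstream": upstream, "clusters": clusters}
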