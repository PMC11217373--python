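"""Upstream extraction, Hamming clustering, U typing and proportions."""

import numpy as np
import pandas as pd
import pytest

from zfdelta import motif_u, simgen
from zfdelta.motif_u import UpstreamSet
from zfdelta.pwm import PWM, revcomp


def upstream_set(seqs):
    return UpstreamSet(pd.Series(seqs, index=range(len(seqs))),
                       flank_len=len(seqs[0]))


class TestExtractUpstream:
    GENOME = {"c": "".join(
        np.random.default_rng(3).choice(list("ACGT"), size=400))}

    def match_frame(self, start, end, strand):
        return pd.DataFrame([{"contig": "c", "core_start": float(start),
                              "core_end": float(end), "strand": strand}],
                            index=pd.Index([0], name="site_id"))

    def test_plus_strand_coordinates(self):
        out = motif_u.extract_upstream(self.GENOME,
                                       self.match_frame(100, 119, "+"))
        assert out.sequences[0] == self.GENOME["c"][80:100]

    def test_minus_strand_coordinates(self):
        out = motif_u.extract_upstream(self.GENOME,
                                       self.match_frame(100, 119, "-"))
        assert out.sequences[0] == revcomp(self.GENOME["c"][119:139])

    def test_off_contig_flank_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = motif_u.extract_upstream(self.GENOME,
                                           self.match_frame(5, 24, "+"))
        assert len(out.sequences) == 0 and out.n_excluded == 1

    def test_revcomp_involution(self):
        """Reverse-complementing the genome and flipping strands/coords
        reproduces every upstream sequence exactly."""
        rng = np.random.default_rng(8)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=500))}
        rows = []
        for i, (s, strand) in enumerate([(60, "+"), (150, "-"), (300, "+"),
                                         (420, "-")]):
            rows.append({"contig": "c", "core_start": float(s),
                         "core_end": float(s + 19), "strand": strand})
        matches = pd.DataFrame(rows, index=pd.Index(range(4),
                                                    name="site_id"))
        fwd = motif_u.extract_upstream(genome, matches)
        n = len(genome["c"])
        flipped = matches.copy()
        flipped["core_start"] = n - matches["core_end"]
        flipped["core_end"] = n - matches["core_start"]
        flipped["strand"] = matches["strand"].map({"+": "-", "-": "+"})
        rev = motif_u.extract_upstream({"c": revcomp(genome["c"])}, flipped)
        for i in fwd.sequences.index:
            assert fwd.sequences[i] == rev.sequences[i]


class TestHammingDistance:
    def test_basic_counts_and_n_weight(self):
        d = motif_u.hamming_distance_matrix(["ACGT", "ACGA", "NCGT"])
        assert d[0, 1] == 1.0
        assert d[0, 2] == 0.5       # N vs A counts 1/2
        assert d[1, 2] == 1.5
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            motif_u.hamming_distance_matrix(["ACGT", "ACG"])


class TestHammingCluster:
    def planted_families(self, rng, n_per=20, length=20):
        """Two families: within-family radius <= 2, separation >= 12."""
        fam_a = "A" * length
        fam_b = "C" * 14 + "G" * 6
        seqs, labels = [], []
        for fam, consensus in (("a", fam_a), ("b", fam_b)):
            for _ in range(n_per):
                s = list(consensus)
                for pos in rng.choice(length, size=rng.integers(0, 3),
                                      replace=False):
                    s[pos] = "ACGT"[rng.integers(4)]
                seqs.append("".join(s))
                labels.append(fam)
        return seqs, labels

    def test_two_planted_families_partition_exactly(self):
        rng = np.random.default_rng(42)
        seqs, labels = self.planted_families(rng)
        # brute-force verification of the planted geometry
        d = motif_u.hamming_distance_matrix(seqs)
        same = np.equal.outer(labels, labels)
        assert d[same].max() <= 4          # within-family diameter
        assert d[~same].min() >= 12        # between-family separation
        res = motif_u.hamming_cluster(upstream_set(seqs), k=2, seed=0)
        assert res.k == 2
        by_cluster = {}
        for i, lab in zip(res.assignment.index, labels):
            by_cluster.setdefault(res.assignment[i], set()).add(lab)
        assert all(len(v) == 1 for v in by_cluster.values())

    def test_order_invariance_under_fixed_seed(self):
        rng = np.random.default_rng(42)
        seqs, _ = self.planted_families(rng)
        res1 = motif_u.hamming_cluster(upstream_set(seqs), k=2, seed=5)
        perm = rng.permutation(len(seqs))
        permuted = UpstreamSet(
            pd.Series([seqs[i] for i in perm], index=perm), flank_len=20)
        res2 = motif_u.hamming_cluster(permuted, k=2, seed=5)
        for i in range(len(seqs)):
            assert res1.assignment[i] == res2.assignment[i]

    def test_identical_sequences_collapse_k(self):
        with pytest.warns(UserWarning, match="k reduced"):
            res = motif_u.hamming_cluster(upstream_set(["ACGTACGT"] * 10),
                                          k=3, seed=0)
        assert res.k == 1
        pfm = res.pfms[0]
        assert pfm.max(axis=1).sum() == pfm.sum()  # point mass

    def test_cluster_pfm_column_sums_equal_cluster_size(self):
        rng = np.random.default_rng(1)
        seqs, _ = self.planted_families(rng)
        res = motif_u.hamming_cluster(upstream_set(seqs), k=2, seed=0)
        for j in range(res.k):
            assert np.allclose(res.pfms[j].sum(axis=1), res.sizes[j])

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            motif_u.hamming_cluster(upstream_set(["ACGT", "AAAA"]), k=0)


class TestAssignUTypes:
    def cluster_result(self, pfms, sizes):
        k = len(pfms)
        return motif_u.SubclusterResult(
            k=k, assignment=pd.Series(range(k)), medoids=[""] * k,
            pfms=pfms,
            consensus=["".join("ACGT"[b] for b in p.argmax(axis=1))
                       for p in pfms],
            information=[motif_u._information_content(p) for p in pfms],
            sizes=sizes, u_labels=[None] * k)

    def test_canonical_cluster_labeled_u1(self):
        pfm = simgen.CANONICAL_U_PWM.probs * 50
        res = self.cluster_result([pfm], [50])
        out = motif_u.assign_u_types(res, simgen.CANONICAL_U_PWM)
        assert out.u_labels == ["U1"]

    def test_flat_cluster_labeled_none(self):
        flat = np.full((20, 4), 12.5)
        res = self.cluster_result([flat], [50])
        out = motif_u.assign_u_types(res, simgen.CANONICAL_U_PWM)
        assert out.u_labels == [None]

    def test_noncanonical_family_gets_non_u1_label(self):
        pfm = simgen.U_FAMILY_PWMS["U2"].probs * 40
        res = self.cluster_result([pfm], [40])
        out = motif_u.assign_u_types(res, simgen.CANONICAL_U_PWM)
        assert out.u_labels[0] is not None and out.u_labels[0] != "U1"

    def test_composition_skew_is_not_a_motif(self):
        """An AT-rich but position-uniform cluster never gets a U label."""
        skew = np.tile(np.array([0.4, 0.1, 0.1, 0.4]), (20, 1)) * 60
        res = self.cluster_result([skew], [60])
        out = motif_u.assign_u_types(res, simgen.CANONICAL_U_PWM)
        assert out.u_labels == [None]

    def test_canonical_longer_than_flank_rejected(self):
        long_u = PWM.from_consensus("A" * 25, dominant=0.9)
        pfm = np.full((20, 4), 10.0)
        res = self.cluster_result([pfm], [40])
        with pytest.raises(ValueError):
            motif_u.assign_u_types(res, long_u, ic_min=0.0, min_run=1)


class TestUProportions:
    def site_table(self, n, groups, down):
        return pd.DataFrame({"group": groups, "downregulated": down},
                            index=range(n))

    def proportions(self, labels, assignment, sites):
        k = len(labels)
        res = motif_u.SubclusterResult(
            k=k, assignment=pd.Series(assignment), medoids=[""] * k,
            pfms=[np.ones((20, 4))] * k, consensus=["A" * 20] * k,
            information=[np.zeros(20)] * k,
            sizes=[int(np.sum(np.array(assignment) == j)) for j in range(k)],
            u_labels=labels)
        return motif_u.u_proportions(sites, res)

    def test_all_u_labeled_gives_100_percent(self):
        sites = self.site_table(4, [1, 2, 3, 4], [False] * 4)
        out = self.proportions(["U1"], [0, 0, 0, 0], sites).set_index("group")
        assert (out.loc[["1", "2", "3", "4"], "percent_u"] == 100).all()

    def test_no_u_clusters_gives_zero_percent(self):
        sites = self.site_table(4, [1, 2, 3, 4], [True] * 4)
        out = self.proportions([None], [0, 0, 0, 0], sites).set_index("group")
        assert (out["percent_u"].loc[["1", "2", "3", "4"]] == 0).all()

    def test_empty_group_reports_nan_not_zero(self):
        sites = self.site_table(4, [1, 1, 2, 2], [False] * 4)
        res = self.proportions(["U1", None], [0, 0, 1, 1], sites)
        down_row = res[res["group"] == "downregulated"].iloc[0]
        assert np.isnan(down_row["percent_u"])


class TestFlankLogo:
    def test_exact_consensus_region(self):
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("ACGT"), size=100))
        core = simgen.CORE_CONSENSUS
        genome = {"c": bg[:40] + core + bg[40:]}
        regions = pd.DataFrame([{"contig": "c", "start": 10, "end": 90}])
        out = motif_u.flank_logo(genome, regions, simgen.CORE_PWM)
        assert out["matches"].loc[0, "core_start"] == 40
        assert out["matches"].loc[0, "core_seq"] == core

    def test_identical_regions_identical_output(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        genome = {"a": seq, "b": seq}
        regions = pd.DataFrame([
            {"contig": "a", "start": 20, "end": 110},
            {"contig": "b", "start": 20, "end": 110}])
        out = motif_u.flank_logo(genome, regions, simgen.CORE_PWM)
        m = out["matches"]
        assert m.loc[0, "core_seq"] == m.loc[1, "core_seq"]
        assert m.loc[0, "strand"] == m.loc[1, "strand"]

    def test_aggregate_pfm_counts_regions(self):
        rng = np.random.default_rng(6)
        genome = {}
        rows = []
        for i in range(5):
            genome[f"r{i}"] = "".join(rng.choice(list("ACGT"), size=120))
            rows.append({"contig": f"r{i}", "start": 0, "end": 120})
        out = motif_u.flank_logo(genome, pd.DataFrame(rows), simgen.CORE_PWM)
        assert np.allclose(out["core_pfm"].sum(axis=1), 5)

    def test_short_region_skipped_with_warning(self):
        genome = {"c": "ACGTACGTAC"}
        regions = pd.DataFrame([{"contig": "c", "start": 0, "end": 10}])
        with pytest.warns(UserWarning, match="skipped"):
            out = motif_u.flank_logo(genome, regions, simgen.CORE_PWM)
        assert out["core_pfm"] is None


def test_end_to_end_u_enrichment_monotone_top_groups(default_sim, chip_chain,
                                                     motif_chain):
    """The full chain reports far higher U-motif percentages in the
    strong-loss groups than in the weak-loss groups on planted data."""
    table = motif_u.u_proportions(chip_chain["table"],
                                  motif_chain["clusters"]).set_index("group")
    g = table.loc[["1", "2", "3", "4"], "percent_u"].astype(float)
    assert g["4"] > g["3"] > max(g["1"], g["2"])
    assert g["4"] >= 5 * g["1"]
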