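"""Consensus-network merging, CAG partitioning and functional profiling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from guildflow import guilds, simulate, sparcc
from guildflow.stats import permanova


def _net(participant, edges):
    """edges: list of (i, j, rho, p)."""
    df = pd.DataFrame(edges, columns=["taxon_i", "taxon_j", "rho", "p"])
    df["sign"] = np.sign(df["rho"]).astype(int)
    return sparcc.ParticipantNetwork(participant, df, 28)


class TestConsensus:
    def test_support_threshold_five_rejected_six_retained(self):
        nets = []
        for k in range(10):
            edges = []
            if k < 6:
                edges.append(("a", "b", 0.8, 0.01))
            if k < 5:
                edges.append(("c", "d", 0.7, 0.01))
            nets.append(_net(f"p{k}", edges))
        cons = guilds.build_consensus(nets, min_support=6)
        assert len(cons.edges) == 1
        e = cons.edges.iloc[0]
        assert (e["taxon_i"], e["taxon_j"]) == ("a", "b")
        assert e["support"] == 6
        assert e["mean_rho"] == pytest.approx(0.8)

    def test_mixed_sign_support_never_retained(self):
        nets = [
            _net(f"p{k}", [("a", "b", 0.8 if k < 3 else -0.8, 0.01)])
            for k in range(6)
        ]
        cons = guilds.build_consensus(nets, min_support=6)
        assert cons.edges.empty
        # without sign consistency the 6 significant results do count
        cons2 = guilds.build_consensus(nets, min_support=6,
                                       require_sign_consistency=False)
        assert len(cons2.edges) == 1

    def test_mean_rho_averages_only_supporting_participants(self):
        nets = [_net(f"p{k}", [("a", "b", 0.6 + 0.05 * k, 0.01)]) for k in range(7)]
        cons = guilds.build_consensus(nets, min_support=6)
        expected = np.mean([0.6 + 0.05 * k for k in range(7)])
        assert cons.edges.iloc[0]["mean_rho"] == pytest.approx(expected)

    def test_planted_consensus_edges_recovered_exactly(self, ten_design):
        """With stable (trend-free) guilds, consensus edges = planted pairs."""
        mismatches = 0
        for seed in range(3):
            ab, truth = simulate.generate_abundance(
                ten_design, 30, 6, seed=seed, amplitude=0.0)
            nets = []
            for p in ten_design.participants("overweight"):
                mat = sparcc.prevalence_filter(ab.participant_matrix(p), 0.45)
                corr = sparcc.sparcc_correlation(mat, n_inner=20, seed=seed)
                pv = sparcc.permutation_pvalues(mat, corr, n_perm=200,
                                                seed=seed + 1)
                nets.append(sparcc.build_participant_network(
                    corr, pv, p, mat.shape[0]))
            cons = guilds.build_consensus(nets, min_support=6)
            planted = set()
            for g in truth.guilds:
                m = sorted(truth.members(g))
                planted |= {(m[i], m[j]) for i in range(len(m))
                            for j in range(i + 1, len(m))}
            got = set(zip(cons.edges["taxon_i"], cons.edges["taxon_j"]))
            mismatches += len(got.symmetric_difference(planted))
        assert mismatches <= 2   # allow a rare borderline pair over 3 seeds

    def test_duplicate_participant_rejected(self):
        nets = [_net("p0", [("a", "b", 0.5, 0.01)])] * 2
        with pytest.raises(ValueError):
            guilds.build_consensus(nets)


def _block_network(n_blocks=3, size=10, rho_within=0.7):
    """Consensus network with planted blocks: within mean_rho, between absent."""
    taxa = [f"t{b}{i:02d}" for b in range(n_blocks) for i in range(size)]
    rows = []
    for b in range(n_blocks):
        block = taxa[b * size:(b + 1) * size]
        for i in range(size):
            for j in range(i + 1, size):
                rows.append({"taxon_i": block[i], "taxon_j": block[j],
                             "support": 8, "sign": 1, "mean_rho": rho_within})
    edges = pd.DataFrame(rows)
    return guilds.ConsensusNetwork("g", edges, taxa, 6), {
        t: f"block{b}" for b in range(n_blocks)
        for t in taxa[b * size:(b + 1) * size]
    }


class TestPartition:
    def test_three_planted_blocks_recovered_perfectly(self):
        net, truth_labels = _block_network()
        gs = guilds.partition_cags(net, min_size=5, alpha=0.001,
                                   n_perm=1999, seed=0)
        pred = gs.labels(net.nodes)
        true = [truth_labels[t] for t in net.nodes]
        assert adjusted_rand_score(true, pred) == 1.0
        assert len(gs.cag_members) == 3

    def test_equal_distances_give_single_cag(self):
        taxa = [f"t{i}" for i in range(20)]
        edges = pd.DataFrame(
            [{"taxon_i": taxa[i], "taxon_j": taxa[j], "support": 8,
              "sign": 1, "mean_rho": 0.5}
             for i in range(20) for j in range(i + 1, 20)]
        )
        net = guilds.ConsensusNetwork("g", edges, taxa, 6)
        gs = guilds.partition_cags(net, n_perm=499, seed=1)
        assert len(gs.cag_members) == 1
        assert set(gs.assignment.values()) == {"cag001"}

    def test_small_child_clusters_become_unassigned(self):
        # two blocks of 10 plus an outlier block of 4 -> unassigned
        net, _ = _block_network(n_blocks=2, size=10)
        extra = [f"x{i}" for i in range(4)]
        rows = [{"taxon_i": extra[i], "taxon_j": extra[j], "support": 8,
                 "sign": 1, "mean_rho": 0.9}
                for i in range(4) for j in range(i + 1, 4)]
        edges = pd.concat([net.edges, pd.DataFrame(rows)], ignore_index=True)
        net2 = guilds.ConsensusNetwork("g", edges, net.nodes + extra, 6)
        gs = guilds.partition_cags(net2, min_size=5, n_perm=1999, seed=2)
        assert all(gs.assignment[t] == guilds.UNASSIGNED for t in extra)
        assert len(gs.cag_members) == 2

    def test_partition_deterministic_for_fixed_seed(self):
        net, _ = _block_network()
        g1 = guilds.partition_cags(net, n_perm=999, seed=7)
        g2 = guilds.partition_cags(net, n_perm=999, seed=7)
        assert g1.assignment == g2.assignment

    def test_cag_abundance_conserves_member_sums(self, ten_design):
        ab, truth = simulate.generate_abundance(ten_design, 30, 6, seed=0)
        net, _ = _block_network(n_blocks=2, size=10)
        # use real taxa names so abundance lookup works
        taxa = ab.taxa[:20]
        rename = dict(zip(net.nodes, taxa))
        net.edges["taxon_i"] = net.edges["taxon_i"].map(rename)
        net.edges["taxon_j"] = net.edges["taxon_j"].map(rename)
        net.nodes = taxa
        gs = guilds.partition_cags(net, abundance=ab, n_perm=999, seed=0)
        total_assigned = sum(
            ab.values[m].sum(axis=1) for m in gs.cag_members.values()
        )
        assert np.allclose(gs.cag_abundance.sum(axis=1), total_assigned)


class TestFunctionalProfiles:
    def test_proportions_are_member_sums_over_totals(self):
        ann = pd.DataFrame(
            {"cazy_starch": [2, 0], "cazy_inulin": [1, 3],
             "cazy_total": [10, 10], "ko_pts": [1, 1], "ko_total": [5, 5]},
            index=["t1", "t2"],
        )
        gs = guilds.GuildSet({"t1": "cag001", "t2": "cag001"},
                             {"cag001": ["t1", "t2"]}, None)
        prof = guilds.profile_functions(gs, ann)
        assert prof.loc["cag001", "cazy_starch"] == pytest.approx(0.1)
        assert prof.loc["cag001", "cazy_inulin"] == pytest.approx(0.2)

    def test_zero_total_genes_reported_missing_not_zero(self):
        ann = pd.DataFrame({"cazy_starch": [0], "cazy_total": [0],
                            "ko_pts": [0], "ko_total": [0]}, index=["t1"])
        gs = guilds.GuildSet({"t1": "cag001"}, {"cag001": ["t1"]}, None)
        prof = guilds.profile_functions(gs, ann)
        assert np.isnan(prof.loc["cag001", "cazy_starch"])

    def test_enriched_guilds_show_higher_fiber_proportions(self, ten_design):
        ab, truth = simulate.generate_abundance(ten_design, 60, 10, seed=4)
        ann = simulate.generate_annotations(truth, seed=4, enrichment=3.0)
        members = {g: truth.members(g) for g in truth.guilds}
        gs = guilds.GuildSet(
            {t: g for t, g in truth.guild_of_taxon.items()}, members, None)
        prof = guilds.profile_functions(gs, ann)
        cat = {g: ("increased" if truth.archetype_of_guild[g]
                   in simulate.INCREASE_ARCHETYPES else "other")
               for g in truth.guilds}
        res = guilds.compare_categories(prof, cat)
        row = res["pairwise"].query("feature == 'cazy_inulin'").iloc[0]
        assert row["p"] < 0.05


class TestCompareCategories:
    def test_complete_separation_exact_p(self):
        prof = pd.DataFrame({"cazy_starch": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]},
                            index=[f"c{i}" for i in range(6)])
        cat = {f"c{i}": ("lo" if i < 3 else "hi") for i in range(6)}
        res = guilds.compare_categories(prof, cat)
        assert res["pairwise"].iloc[0]["p"] == pytest.approx(0.1)

    def test_identical_categories_not_significant(self):
        prof = pd.DataFrame({"cazy_starch": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]},
                            index=[f"c{i}" for i in range(6)])
        cat = {f"c{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = guilds.compare_categories(prof, cat)
        assert res["pairwise"].iloc[0]["p"] > 0.9

    def test_singleton_category_skipped_with_warning(self):
        prof = pd.DataFrame({"cazy_starch": [0.1, 0.2, 0.3, 0.4, 0.9]},
                            index=[f"c{i}" for i in range(5)])
        cat = {"c0": "a", "c1": "a", "c2": "b", "c3": "b", "c4": "lonely"}
        with pytest.warns(UserWarning, match="singleton"):
            res = guilds.compare_categories(prof, cat)
        cats = set(res["pairwise"]["category_a"]) | set(res["pairwise"]["category_b"])
        assert "lonely" not in cats


def test_fast_permanova_matches_scikit_bio(rng):
    """The vectorised two-group PERMANOVA agrees with the reference
    implementation on pseudo-F (identical partitioning of sums of squares)."""
    pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix as SkbioDM
    from skbio.stats.distance import permanova as skbio_permanova

    x = rng.standard_normal((14, 3))
    x[7:] += 1.0
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(x))
    labels = np.array(["a"] * 7 + ["b"] * 7)
    f_mine, _, _ = permanova(d, labels, n_perm=99, seed=0)
    res = skbio_permanova(SkbioDM(d), labels, permutations=99)
    assert f_mine == pytest.approx(res["test statistic"], rel=1e-10)
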