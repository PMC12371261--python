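"""Consensus co-abundance networks, guild (CAG) partitioning, and
functional-gene profiling of guilds.

Per-participant networks are merged by keeping only taxon pairs that are
significantly correlated with a consistent sign in at least ``min_support``
participants of a group; the mean correlation over exactly the supporting
participants weights the consensus edge.  Taxa are then partitioned into
co-abundance groups by Ward.D2 clustering of the 1 - correlation distance,
descending the dendrogram and accepting a split only when a free-permutation
PERMANOVA on the child labels is significant and both children meet the
minimum guild size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .simulate import AbundanceTable
from .sparcc import ParticipantNetwork
from .stats import bh_adjust, dunn_test, permanova_two_group_fast

UNASSIGNED = "unassigned"


@dataclass
class ConsensusNetwork:
    """Group-level consensus edges with per-participant support."""

    group: str
    edges: pd.DataFrame    # taxon_i, taxon_j, support, sign, mean_rho
    nodes: list[str]
    min_support: int


@dataclass
class GuildSet:
    """A partition of taxa into co-abundance groups (CAGs)."""

    assignment: dict[str, str]              # taxon -> cag id (or "unassigned")
    cag_members: dict[str, list[str]]
    cag_abundance: pd.DataFrame | None      # (participant, day) x cag, member sums
    linkage: np.ndarray | None = None       # Ward tree retained for audit
    split_log: list[dict] = field(default_factory=list)

    @property
    def cags(self) -> list[str]:
        return sorted(self.cag_members)

    def labels(self, taxa: list[str]) -> np.ndarray:
        return np.array([self.assignment.get(t, UNASSIGNED) for t in taxa])


def build_consensus(
    networks: list[ParticipantNetwork],
    min_support: int = 6,
    require_sign_consistency: bool = True,
    group: str = "",
) -> ConsensusNetwork:
    """Merge one group's participant networks into a consensus network.

    An edge is retained iff at least ``min_support`` participants carry a
    significant edge for the pair — of the same sign when
    ``require_sign_consistency`` (the default reading of "consistently
    significant positive or negative").  ``mean_rho`` averages the
    correlation over exactly the supporting participants.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not networks:
        raise ValueError("no participant networks given")
    seen = [n.participant for n in networks]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate participant networks")

    frames = []
    for net in networks:
        e = net.edges.copy()
        pair = np.where(
            e["taxon_i"] < e["taxon_j"],
            e["taxon_i"] + "\t" + e["taxon_j"],
            e["taxon_j"] + "\t" + e["taxon_i"],
        )
        e = e.assign(pair=pair, participant=net.participant)
        frames.append(e[["pair", "participant", "rho", "sign"]])
    frames = [f for f in frames if len(f)]
    if not frames:
        return ConsensusNetwork(group, pd.DataFrame(
            columns=["taxon_i", "taxon_j", "support", "sign", "mean_rho"]),
            [], min_support)
    all_edges = pd.concat(frames, ignore_index=True)

    rows = []
    for pair, sub in all_edges.groupby("pair", sort=True):
        if require_sign_consistency:
            for sign in (1, -1):
                s = sub[sub["sign"] == sign]
                if len(s) >= min_support:
                    ti, tj = pair.split("\t")
                    rows.append(
                        {"taxon_i": ti, "taxon_j": tj, "support": len(s),
                         "sign": sign, "mean_rho": s["rho"].mean()}
                    )
        else:
            if len(sub) >= min_support:
                ti, tj = pair.split("\t")
                mean_rho = sub["rho"].mean()
                rows.append(
                    {"taxon_i": ti, "taxon_j": tj, "support": len(sub),
                     "sign": int(np.sign(mean_rho)) or 1, "mean_rho": mean_rho}
                )
    edges = pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "support", "sign", "mean_rho"])
    nodes = sorted(set(edges["taxon_i"]) | set(edges["taxon_j"]))
    return ConsensusNetwork(group, edges, nodes, min_support)


def consensus_distance(network: ConsensusNetwork) -> pd.DataFrame:
    """1 - mean_rho distance over consensus nodes; missing pairs get 1."""
    nodes = network.nodes
    idx = {t: i for i, t in enumerate(nodes)}
    d = np.ones((len(nodes), len(nodes)))
    np.fill_diagonal(d, 0.0)
    for _, e in network.edges.iterrows():
        i, j = idx[e["taxon_i"]], idx[e["taxon_j"]]
        d[i, j] = d[j, i] = np.clip(1.0 - e["mean_rho"], 0.0, 2.0)
    return pd.DataFrame(d, index=nodes, columns=nodes)


def partition_cags(
    network: ConsensusNetwork,
    abundance: AbundanceTable | None = None,
    min_size: int = 5,
    alpha: float = 0.001,
    n_perm: int = 9999,
    seed: int | None = None,
) -> GuildSet:
    """Partition consensus-network taxa into CAGs.

    Ward.D2 agglomeration on the 1 - correlation distance, then a top-down
    descent of the dendrogram: a binary split is kept only when a
    PERMANOVA of the two child groups on the sub-distance-matrix rejects
    at ``alpha``; a significant child smaller than ``min_size`` can never
    form a guild and is peeled off (ending up unassigned) while the
    descent continues in the larger child.  Terminal clusters smaller than
    ``min_size`` are labelled unassigned.  When an
    abundance table is supplied, per-CAG abundance series are computed as
    member sums.
    """
    nodes = network.nodes
    dist = consensus_distance(network).to_numpy()
    n = len(nodes)
    rng = np.random.default_rng(seed)
    split_log: list[dict] = []

    if n < 2 * min_size:
        clusters = [list(range(n))]
        linkage = None
    else:
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")
        tree = hierarchy.to_tree(linkage)
        clusters = []

        def descend(node) -> None:
            members = node.pre_order(lambda leaf: leaf.id)
            if node.is_leaf() or len(members) < 2 * min_size:
                clusters.append(members)
                return
            left = node.get_left().pre_order(lambda leaf: leaf.id)
            right = node.get_right().pre_order(lambda leaf: leaf.id)
            sub = dist[np.ix_(members, members)]
            indicator = np.isin(members, left)
            _, p = permanova_two_group_fast(sub, indicator, n_perm, rng)
            significant = p < alpha
            small_child = min(len(left), len(right)) < min_size
            split_log.append(
                {"size": len(members), "child_sizes": (len(left), len(right)),
                 "p": p, "accepted": significant and not small_child,
                 "reason": "child below min_size" if small_child else "permanova"}
            )
            if not significant:
                clusters.append(members)
            elif small_child:
                # a significant but undersized child cannot form a guild: it
                # is peeled off (-> unassigned) and the descent continues in
                # the larger child
                small, large = ((node.get_left(), node.get_right())
                                if len(left) < len(right)
                                else (node.get_right(), node.get_left()))
                clusters.append(small.pre_order(lambda leaf: leaf.id))
                descend(large)
            else:
                descend(node.get_left())
                descend(node.get_right())

        descend(tree)

    assignment: dict[str, str] = {}
    cag_members: dict[str, list[str]] = {}
    k = 0
    for members in sorted(clusters, key=lambda m: (-len(m), m)):
        taxa = [nodes[i] for i in members]
        if len(taxa) < min_size:
            for t in taxa:
                assignment[t] = UNASSIGNED
            continue
        k += 1
        cag = f"cag{k:03d}"
        cag_members[cag] = sorted(taxa)
        for t in taxa:
            assignment[t] = cag

    cag_abundance = None
    if abundance is not None and cag_members:
        cag_abundance = pd.DataFrame(
            {cag: abundance.values[members].sum(axis=1)
             for cag, members in cag_members.items()}
        )
    return GuildSet(assignment, cag_members, cag_abundance, linkage, split_log)


# ---------------------------------------------------------------------------
# functional profiling


def profile_functions(guilds: GuildSet, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-CAG functional-gene proportions.

    CAZy substrate proportions divide the summed substrate counts of a
    CAG's members by the CAG's total CAZy genes; KO transport-group
    proportions likewise over total KOs.  A CAG with zero total genes gets
    missing (NaN) proportions, not zero.
    """
    cazy_cols = [c for c in annotations.columns
                 if c.startswith("cazy_") and c != "cazy_total"]
    ko_cols = [c for c in annotations.columns
               if c.startswith("ko_") and c != "ko_total"]
    rows = {}
    for cag, members in guilds.cag_members.items():
        missing = [m for m in members if m not in annotations.index]
        if missing:
            warnings.warn(f"{cag}: {len(missing)} members without annotations; "
                          "treated as zero counts")
        present = [m for m in members if m in annotations.index]
        sums = annotations.loc[present].sum(axis=0) if present else annotations.iloc[:0].sum()
        row = {}
        cazy_total = float(sums.get("cazy_total", 0))
        ko_total = float(sums.get("ko_total", 0))
        for c in cazy_cols:
            row[c] = float(sums.get(c, 0)) / cazy_total if cazy_total > 0 else np.nan
        for c in ko_cols:
            row[c] = float(sums.get(c, 0)) / ko_total if ko_total > 0 else np.nan
        rows[cag] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cag"
    return out


def compare_categories(
    profiles: pd.DataFrame,
    category_of_cag: dict[str, str],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Compare functional proportions across CAG response categories.

    For every functional column: pairwise two-sided Mann-Whitney U tests
    between categories, plus a Kruskal-Wallis test with Dunn's post hoc
    across all categories.  Categories with fewer than 2 CAGs are skipped.
    """
    cats: dict[str, list[str]] = {}
    for cag, cat in category_of_cag.items():
        if cag in profiles.index:
            cats.setdefault(cat, []).append(cag)
    usable = {c: m for c, m in cats.items() if len(m) >= 2}
    skipped = sorted(set(cats) - set(usable))
    if skipped:
        warnings.warn(f"singleton categories skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("need at least two categories with >= 2 CAGs")

    pairwise_rows, kw_rows, dunn_frames = [], [], []
    for col in profiles.columns:
        series = {c: profiles.loc[m, col].dropna().to_numpy() for c, m in usable.items()}
        series = {c: v for c, v in series.items() if v.size >= 2}
        if len(series) < 2:
            continue
        names = sorted(series)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ca, cb = names[a], names[b]
                try:
                    u, p = sps.mannwhitneyu(series[ca], series[cb],
                                            alternative="two-sided")
                except ValueError:      # all values identical
                    u, p = np.nan, 1.0
                pairwise_rows.append(
                    {"feature": col, "category_a": ca, "category_b": cb,
                     "U": u, "p": p, "significant": p < alpha}
                )
        if len(series) >= 2:
            try:
                h, kw_p = sps.kruskal(*[series[c] for c in names])
            except ValueError:
                h, kw_p = np.nan, 1.0
            kw_rows.append({"feature": col, "H": h, "p": kw_p,
                            "significant": kw_p < alpha})
            d = dunn_test({c: series[c] for c in names})
            d.insert(0, "feature", col)
            dunn_frames.append(d)

    pairwise = pd.DataFrame(pairwise_rows)
    if len(pairwise):
        pairwise["q"] = bh_adjust(pairwise["p"].to_numpy())
    kruskal = pd.DataFrame(kw_rows)
    dunn = pd.concat(dunn_frames, ignore_index=True) if dunn_frames else pd.DataFrame()
    return {"pairwise": pairwise, "kruskal": kruskal, "dunn": dunn}
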