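"""Planted-truth recovery benchmarks and null calibrations.

Self-validation utilities that exercise whole pipeline stages against the
synthetic generator's plantings: SparCC basis-correlation recovery, the
full network -> consensus -> CAG chain, trajectory-LMM parameter recovery,
the delay-limited association screen, mediation recovery, and type-I-error
calibration of the permutation tests.  Both the acceptance test-suite and
``scripts/acceptance.py`` are thin wrappers around these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from . import dynamics, guilds, integrate, lsa, simulate, sparcc
from .design import StudyDesign
from .stats import permanova


def _derive(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# SparCC planted-pair benchmark


def sparcc_planted_benchmark(
    seed: int,
    n_samples: int = 200,
    n_taxa: int = 20,
    rho: float = 0.8,
    n_perm: int = 1000,
) -> dict:
    """One planted basis pair among nulls; estimator vs basis-correlation oracle."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_taxa))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_samples)
    log_basis = z + rng.normal(0.0, 1.0, n_taxa)[None, :]
    x = np.exp(log_basis)
    x /= x.sum(axis=1, keepdims=True)
    mat = pd.DataFrame(x, columns=[f"t{i:02d}" for i in range(n_taxa)])

    corr = sparcc.sparcc_correlation(mat, seed=_derive(seed, 1))
    pv = sparcc.permutation_pvalues(mat, corr, n_perm=n_perm,
                                    seed=_derive(seed, 2))
    r_basis = np.corrcoef(log_basis, rowvar=False)
    iu = np.triu_indices(n_taxa, 1)
    null_mask = ~((iu[0] == 0) & (iu[1] == 1))
    dev = np.abs(corr.rho - r_basis)[iu]
    return {
        "planted_rho_est": float(corr.rho[0, 1]),
        "max_null_oracle_dev": float(dev[null_mask].max()),
        "max_null_abs_rho": float(np.abs(corr.rho[iu][null_mask]).max()),
        "planted_p": float(pv.iloc[0, 1]),
        "min_p_bound": 1.0 / (n_perm + 1.0),
        "min_p_observed": float(pv.to_numpy()[iu].min()),
    }


# ---------------------------------------------------------------------------
# full guild-recovery chain


def guild_recovery_run(
    seed: int,
    n_taxa: int = 200,
    n_guilds: int = 20,
    participants: int = 10,
    network_permutations: int = 250,
    cag_permutations: int = 9999,
    min_support: int = 6,
    alpha: float = 0.001,
    min_size: int = 5,
) -> dict:
    """Generator -> per-participant networks -> consensus -> CAG partition.

    Returns the adjusted Rand index of the recovered partition against the
    planted guilds, plus within-guild edge recall of the consensus network.
    """
    design = StudyDesign(groups=("overweight",),
                         participants_per_group=participants)
    ab, truth = simulate.generate_abundance(design, n_taxa, n_guilds, seed=seed)
    nets = []
    for i, p in enumerate(design.participants("overweight")):
        mat = sparcc.prevalence_filter(ab.participant_matrix(p), 0.45)
        corr = sparcc.sparcc_correlation(mat, seed=_derive(seed, 10 + i))
        pv = sparcc.permutation_pvalues(mat, corr, n_perm=network_permutations,
                                        seed=_derive(seed, 100 + i))
        nets.append(sparcc.build_participant_network(corr, pv, p, mat.shape[0]))
    cons = guilds.build_consensus(nets, min_support=min_support)
    gset = guilds.partition_cags(cons, ab, min_size=min_size, alpha=alpha,
                                 n_perm=cag_permutations, seed=_derive(seed, 3))
    taxa = cons.nodes
    true_labels = [truth.guild_of_taxon[t] for t in taxa]
    ari = adjusted_rand_score(true_labels, gset.labels(taxa))

    planted = set()
    for g in truth.guilds:
        m = sorted(truth.members(g))
        planted |= {(m[i], m[j]) for i in range(len(m)) for j in range(i + 1, len(m))}
    got = set(zip(cons.edges["taxon_i"], cons.edges["taxon_j"]))
    recall = len(got & planted) / len(planted)
    return {"ari": float(ari), "edge_recall": float(recall),
            "n_cags": len(gset.cag_members), "n_nodes": len(taxa)}


# ---------------------------------------------------------------------------
# trajectory LMM recovery


def trajectory_recovery_run(
    seed: int,
    sigma_b: float = 1.0,
    sigma: float = 0.5,
    n_participants: int = 10,
) -> float:
    """RMSE of recovered day effects when simulating from the LMM itself."""
    design = StudyDesign(groups=("overweight",),
                         participants_per_group=n_participants)
    rng = np.random.default_rng(seed)
    effects = {d: (0.8 if d >= 21 else 0.4 if d >= 14 else 0.0)
               for d in design.days}
    rows, idx = [], []
    for p in design.participants("overweight"):
        b = rng.normal(0.0, sigma_b)
        for d in design.days:
            rows.append(np.exp(-2.0 + effects[d] + b + rng.normal(0.0, sigma)))
            idx.append((p, d))
    series = pd.Series(rows, index=pd.MultiIndex.from_tuples(
        idx, names=["participant", "day"]))
    fit = dynamics.fit_trajectory(series, design, reference="normal")
    err = [fit.day_effects[d] - effects[d] for d in fit.day_effects.index]
    return float(np.sqrt(np.mean(np.square(err))))


# ---------------------------------------------------------------------------
# end-to-end association recovery


def lsa_recovery_run(seed: int, n_taxa: int = 200, n_guilds: int = 20,
                     n_metabolites: int = 20, max_delay: int = 3) -> dict:
    """Generator -> LMM daily series -> association screen; did the planted
    positive delay-3 link come back with the right delay at q < 0.05?"""
    design = StudyDesign(groups=("overweight",), participants_per_group=10)
    ab, truth = simulate.generate_abundance(design, n_taxa, n_guilds, seed=seed)
    mets = simulate.generate_metabolites(ab, truth, n_metabolites,
                                         seed=_derive(seed, 4))
    gab = truth.guild_abundance(ab)
    traj = dynamics.daily_series(gab, design, reference="day0")
    met_traj = dynamics.daily_series(mets.values, design, reference="day0")
    screen = lsa.lsa_screen(traj, met_traj, max_delay=max_delay,
                            seed=_derive(seed, 5))
    link = [l for l in truth.planted_links if l.delay == 3 and l.sign > 0][0]
    row = screen[(screen["x"] == link.guild)
                 & (screen["y"] == link.metabolite)].iloc[0]
    return {
        "recovered": bool(row["hit"]) and int(row["delay"]) == link.delay,
        "score": float(row["score"]),
        "delay": int(row["delay"]),
        "q": float(row["q"]),
        "n_pairs": len(screen),
    }


# ---------------------------------------------------------------------------
# mediation recovery


def mediation_recovery_run(seed: int, a: float = 1.0, b: float = 0.5,
                           c: float = 0.3, n_participants: int = 10,
                           n_obs: int = 14) -> dict:
    truth = simulate.GroundTruth(guild_of_taxon={"t0": "g0"},
                                 archetype_of_guild={"g0": "stable"})
    df = simulate.generate_mediation_dataset(
        truth, a=a, b=b, c_prime=c, n_participants=n_participants,
        n_obs=n_obs, seed=seed)
    res = integrate.mediate(df["treatment"], df["mediator"], df["outcome"],
                            df["participant"], n_sims=1000,
                            seed=_derive(seed, 6))
    lo, hi = res.ci_acme
    return {"acme": res.acme, "covered": lo <= a * b <= hi,
            "covers_zero": lo <= 0.0 <= hi, "p_acme": res.p_acme}


# ---------------------------------------------------------------------------
# null calibrations (type-I error at alpha = 0.05)


def permanova_strata_null_rejection(n_sims: int = 1000, seed: int = 0,
                                    n_perm: int = 99) -> float:
    rng = np.random.default_rng(seed)
    rej = 0
    strata = np.repeat([f"p{i}" for i in range(4)], 4)
    labels = np.tile(["a", "a", "b", "b"], 4)
    for s in range(n_sims):
        x = rng.standard_normal((16, 3))
        d = squareform(pdist(x))
        _, _, p = permanova(d, labels, strata=strata, n_perm=n_perm,
                            seed=_derive(seed, s))
        rej += p <= 0.05
    return rej / n_sims


def kruskal_null_rejection(n_sims: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_sims):
        g = [rng.standard_normal(8) for _ in range(3)]
        rej += sps.kruskal(*g).pvalue <= 0.05
    return rej / n_sims


def changepoint_null_rejection(n_sims: int = 1000, seed: int = 0,
                               n_perm: int = 199) -> float:
    rej = 0
    rng = np.random.default_rng(seed)
    for s in range(n_sims):
        x = rng.standard_normal(28)
        cp = dynamics.detect_changepoint(x, n_perm=n_perm, seed=_derive(seed, s))
        rej += cp.p <= 0.05
    return rej / n_sims


def procrustes_null_rejection(n_sims: int = 1000, seed: int = 0,
                              n_perm: int = 99) -> float:
    rng = np.random.default_rng(seed)
    rej = 0
    for s in range(n_sims):
        x = rng.standard_normal((10, 2))
        y = rng.standard_normal((10, 2))
        _, p = integrate.procrustes_test(x, y, n_perm=n_perm,
                                         seed=_derive(seed, s))
        rej += p <= 0.05
    return rej / n_sims
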