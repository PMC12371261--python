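"""End-to-end orchestration: simulate -> per-participant networks ->
consensus guilds -> trajectories -> temporal clusters -> time-delayed
associations -> CGM metrics -> integration, from one seeded config."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cgm, dynamics, guilds, integrate, io, lsa, simulate, sparcc
from .design import StudyDesign


@dataclass
class PipelineConfig:
    """All stage parameters of one run; defaults mirror the study protocol."""

    outdir: str = "guildflow_out"
    seed: int = 0
    # synthetic-data scale
    simulate_data: bool = True
    groups: list[str] = field(default_factory=lambda: ["overweight"])
    participants_per_group: int = 10
    n_taxa: int = 200
    n_guilds: int = 20
    n_metabolites: int = 20
    intervention_effect: float = 0.35
    # network stage
    prevalence_threshold: float = 0.45
    network_permutations: int = 1000
    edge_alpha: float = 0.05
    sparcc_inner: int = 50
    # consensus / guild stage
    min_support: int = 6
    cag_alpha: float = 0.001
    cag_permutations: int = 9999
    min_size: int = 5
    # dynamics / association stage
    max_delay: int = 3
    fdr_alpha: float = 0.05
    lsa_method: str = "theoretical"
    # CGM
    cgm_low: float = 70.0
    cgm_high: float = 180.0
    # optional external inputs (used when simulate_data is false)
    abundance_path: str | None = None
    metabolite_path: str | None = None
    glucose_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = StudyDesign(
        groups=tuple(config.groups),
        participants_per_group=config.participants_per_group,
    )
    manifest: dict = {
        "guildflow_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in asdict(config).items() if k != "outdir"},
                       sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "stages": {},
    }

    # --- data ------------------------------------------------------------
    if config.simulate_data:
        abundance, truth = simulate.generate_abundance(
            design, n_taxa=config.n_taxa, n_guilds=config.n_guilds,
            seed=stage_seed(config.seed, "abundance"),
        )
        metabolites = simulate.generate_metabolites(
            abundance, truth, n_metabolites=config.n_metabolites,
            seed=stage_seed(config.seed, "metabolites"),
        )
        glucose = simulate.generate_glucose(
            design, intervention_effect=config.intervention_effect,
            seed=stage_seed(config.seed, "glucose"),
        )
        annotations = simulate.generate_annotations(
            truth, seed=stage_seed(config.seed, "annotations")
        )
        io.write_long_tsv(abundance, outdir / "abundance.tsv")
        io.write_long_tsv(metabolites, outdir / "metabolites.tsv")
        io.write_glucose_tsv(glucose, outdir / "glucose.tsv")
        truth.to_json(outdir / "ground_truth.json")
    else:
        if not (config.abundance_path and config.metabolite_path):
            raise ValueError("need abundance_path and metabolite_path when not simulating")
        abundance = io.read_abundance_tsv(config.abundance_path)
        metabolites = io.read_metabolite_tsv(config.metabolite_path)
        glucose = (io.read_glucose_tsv(config.glucose_path)
                   if config.glucose_path else None)
        annotations, truth = None, None
    manifest["stages"]["data"] = {
        "participants": len(abundance.participants),
        "taxa": len(abundance.taxa),
        "days": len(abundance.days),
    }

    # --- per-participant networks ----------------------------------------
    networks_by_group: dict[str, list[sparcc.ParticipantNetwork]] = {}
    for group in design.groups:
        nets = []
        for participant in design.participants(group):
            mat = sparcc.prevalence_filter(
                abundance.participant_matrix(participant),
                config.prevalence_threshold,
            )
            corr = sparcc.sparcc_correlation(
                mat, n_inner=config.sparcc_inner,
                seed=stage_seed(config.seed, f"sparcc:{participant}"),
            )
            pvals = sparcc.permutation_pvalues(
                mat, corr, n_perm=config.network_permutations,
                seed=stage_seed(config.seed, f"perm:{participant}"),
            )
            net = sparcc.build_participant_network(
                corr, pvals, participant, mat.shape[0], alpha=config.edge_alpha
            )
            io.write_edges_tsv(net.edges, outdir / f"network_{participant}.tsv")
            nets.append(net)
        networks_by_group[group] = nets
    manifest["stages"]["networks"] = {
        g: {n.participant: len(n.edges) for n in nets}
        for g, nets in networks_by_group.items()
    }

    # --- consensus + guild partitioning -----------------------------------
    guildsets: dict[str, guilds.GuildSet] = {}
    for group, nets in networks_by_group.items():
        consensus = guilds.build_consensus(
            nets, min_support=config.min_support, group=group
        )
        io.write_edges_tsv(consensus.edges, outdir / f"consensus_{group}.tsv")
        io.consensus_to_graphml(consensus, outdir / f"consensus_{group}.graphml")
        gset = guilds.partition_cags(
            consensus, abundance,
            min_size=config.min_size, alpha=config.cag_alpha,
            n_perm=config.cag_permutations,
            seed=stage_seed(config.seed, f"cags:{group}"),
        )
        io.write_guilds_tsv(gset, outdir / f"cags_{group}.tsv")
        guildsets[group] = gset
        unassigned = [t for t, c in gset.assignment.items() if c == guilds.UNASSIGNED]
        manifest["stages"].setdefault("guilds", {})[group] = {
            "consensus_edges": len(consensus.edges),
            "consensus_nodes": len(consensus.nodes),
            "n_cags": len(gset.cag_members),
            "unassigned_taxa": sorted(unassigned),
        }

    # --- trajectories, clusters, associations ------------------------------
    for group, gset in guildsets.items():
        if not gset.cag_members:
            continue
        participants = set(design.participants(group))
        mask = gset.cag_abundance.index.get_level_values(0).isin(participants)
        cag_ab = gset.cag_abundance[mask]
        traj28 = dynamics.daily_series(cag_ab, design, reference="day0")
        io.write_matrix_tsv(traj28, outdir / f"trajectories_{group}.tsv")

        fits = {
            cag: dynamics.fit_trajectory(cag_ab[cag], design, reference="normal",
                                         feature=cag)
            for cag in cag_ab.columns
        }
        rel = pd.DataFrame({c: f.day_effects for c, f in fits.items()})
        if rel.shape[1] >= 3:
            clusters = dynamics.cluster_trajectories(rel, design=design)
            io.write_matrix_tsv(clusters.dtw, outdir / f"dtw_{group}.tsv")
            pd.Series(clusters.cluster_of_cag).rename("cluster").to_csv(
                outdir / f"clusters_{group}.tsv", sep="\t"
            )
            manifest["stages"].setdefault("clusters", {})[group] = {
                "k": clusters.chosen_k,
            }
        diff = dynamics.differential_abundance(cag_ab, design, contrast="endpoint",
                                               fdr_alpha=config.fdr_alpha)
        io.write_matrix_tsv(diff, outdir / f"differential_{group}.tsv")

        met_vals = metabolites.values[
            metabolites.values.index.get_level_values(0).isin(participants)
        ]
        met28 = dynamics.daily_series(met_vals, design, reference="day0")
        hits = lsa.lsa_screen(
            traj28, met28, max_delay=config.max_delay,
            fdr_alpha=config.fdr_alpha, method=config.lsa_method,
            seed=stage_seed(config.seed, f"lsa:{group}"),
        )
        io.write_edges_tsv(hits, outdir / f"lsa_{group}.tsv")
        io.hits_to_graphml(hits, outdir / f"lsa_{group}.graphml")
        manifest["stages"].setdefault("lsa", {})[group] = {
            "pairs": len(hits), "hits": int(hits["hit"].sum()),
        }

    # --- CGM ---------------------------------------------------------------
    if glucose is not None:
        daily = cgm.compute_daily_metrics(glucose, low=config.cgm_low,
                                          high=config.cgm_high)
        io.write_edges_tsv(daily, outdir / "cgm_daily.tsv")
        phase = cgm.summarize_phases(daily, design)
        io.write_edges_tsv(phase["summary"], outdir / "cgm_phase_summary.tsv")
        manifest["stages"]["cgm"] = {"participant_days": len(daily)}

    # --- sample-level integration ------------------------------------------
    group0 = design.groups[0]
    sub = abundance.values[
        abundance.values.index.get_level_values(0).isin(design.participants(group0))
    ]
    dm = integrate.bray_curtis(sub)
    phase_labels = np.array(
        ["normal" if design.phase_of_day[d] == "normal" else "fiber"
         for d in sub.index.get_level_values(1)]
    )
    strata = sub.index.get_level_values(0).to_numpy()
    f_stat, r2, p = integrate.permanova(
        dm.to_numpy(), phase_labels, strata=strata, n_perm=999,
        seed=stage_seed(config.seed, "permanova"),
    )
    coords, _ = integrate.adjusted_pcoa(dm, pd.Series(strata, index=dm.index))
    manifest["stages"]["integration"] = {
        "permanova": {"pseudo_F": f_stat, "R2": r2, "p": p},
        "apcoa_axes": int(coords.shape[1]),
    }

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
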