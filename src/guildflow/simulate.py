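"""Synthetic multi-omics generator with planted ground truth.

Emulates the *derived* tables of a daily-sampling fiber-intervention study —
relative-abundance matrices with guild block-correlation and temporal
response archetypes, lag-coupled fecal metabolites, intervention-responsive
glucose traces and per-taxon carbohydrate-gene annotation counts — so that
every downstream stage (network inference, guild partitioning, trajectory
modelling, time-delayed association, CGM metrics, mediation) can be tested
against known plantings without any sequencing data.

The abundance model is a log-normal basis closed to the simplex: for taxon
``t`` of guild ``g``, participant ``p`` and day ``d``,

    log basis = mu_t + b_{p,t} + A_g(d) + sigma * (sqrt(rho_w) u_{p,d,g}
                + sqrt(1 - rho_w) e_{p,d,t})

where ``A_g`` is the guild's piecewise-linear archetype curve (onset at the
first intervention day), ``u`` a guild-shared latent factor giving a
within-guild log-scale correlation target ``rho_w``, ``b`` a participant
offset and ``e`` idiosyncratic noise.  A Dirichlet-multinomial resampling
switch is available for robustness checks of downstream estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import NORMAL, StudyDesign

ARCHETYPES = (
    "sustained-increase",
    "transient-increase",
    "late-increase",
    "rapid-decline",
    "late-decline",
    "stable",
)

INCREASE_ARCHETYPES = {"sustained-increase", "transient-increase", "late-increase"}
DECLINE_ARCHETYPES = {"rapid-decline", "late-decline"}


# ---------------------------------------------------------------------------
# containers


@dataclass
class AbundanceTable:
    """Participant x day x taxon relative abundances.

    ``values`` is a wide DataFrame indexed by (participant, day) with one
    column per taxon; every row lies on the unit simplex.
    """

    values: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participants(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def days(self) -> list[int]:
        return sorted(self.values.index.get_level_values(1).unique())

    def participant_matrix(self, participant: str) -> pd.DataFrame:
        """Day x taxon abundance matrix of one participant."""
        out = self.values.xs(participant, level=0)
        return out.sort_index()

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["participant", "day", "feature", "value"]
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "AbundanceTable":
        wide = long.pivot_table(
            index=["participant", "day"], columns="feature", values="value", sort=False
        )
        wide.columns.name = None
        return cls(wide)


@dataclass
class MetaboliteTable:
    """Participant x day x metabolite concentrations (arbitrary units)."""

    values: pd.DataFrame

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def participant_matrix(self, participant: str) -> pd.DataFrame:
        return self.values.xs(participant, level=0).sort_index()

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["participant", "day", "feature", "value"]
        return long


@dataclass(frozen=True)
class PlantedLink:
    """A planted guild -> metabolite coupling: m(t) tracks g(t - delay)."""

    guild: str
    metabolite: str
    delay: int
    sign: int
    effect: float


@dataclass(frozen=True)
class PlantedMediation:
    """Planted treatment -> mediator -> outcome coefficients."""

    guild: str
    metabolite: str
    outcome: str
    a: float
    b: float


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    guild_of_taxon: dict[str, str]
    archetype_of_guild: dict[str, str]
    planted_links: list[PlantedLink] = field(default_factory=list)
    planted_mediation: PlantedMediation | None = None
    seeds: dict[str, int] = field(default_factory=dict)
    rho_w: float = 0.7
    log_basis: pd.DataFrame | None = None

    def members(self, guild: str) -> list[str]:
        return [t for t, g in self.guild_of_taxon.items() if g == guild]

    @property
    def guilds(self) -> list[str]:
        return sorted(set(self.guild_of_taxon.values()))

    def guild_abundance(self, table: AbundanceTable) -> pd.DataFrame:
        """True-guild abundance series (member sums), (participant, day) x guild."""
        cols = {}
        for g in self.guilds:
            cols[g] = table.values[self.members(g)].sum(axis=1)
        return pd.DataFrame(cols)

    def to_json(self, path) -> None:
        payload = {
            "guild_of_taxon": self.guild_of_taxon,
            "archetype_of_guild": self.archetype_of_guild,
            "planted_links": [vars(l) for l in self.planted_links],
            "planted_mediation": (
                vars(self.planted_mediation) if self.planted_mediation else None
            ),
            "seeds": self.seeds,
            "rho_w": self.rho_w,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# archetype curves


def archetype_curve(archetype: str, days: Sequence[int], amplitude: float,
                    phase_of_day: dict[int, str]) -> np.ndarray:
    """Piecewise-linear log-scale response curve of one temporal archetype.

    Curves are 0 throughout the habitual-diet phase and move from the first
    intervention day; the transient archetype peaks at the end of the
    low-dose phase and reverses during the high-dose phase.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    days = np.asarray(days)
    interv = np.array([phase_of_day[d] != NORMAL for d in days])
    if not interv.any():
        return np.zeros(len(days), dtype=float)
    onset = days[interv].min()          # first intervention day (14)
    high = [d for d in days if phase_of_day[d] == "high"]
    peak = (min(high) - 1) if high else days.max()   # end of low-dose (20)
    last = days.max()

    def ramp(d, start, stop, lo, hi):
        if d <= start:
            return lo
        if d >= stop:
            return hi
        return lo + (hi - lo) * (d - start) / (stop - start)

    a = amplitude
    out = np.zeros(len(days), dtype=float)
    for i, d in enumerate(days):
        if phase_of_day[d] == NORMAL:
            continue
        if archetype == "stable":
            out[i] = 0.0
        elif archetype == "sustained-increase":
            out[i] = ramp(d, onset - 1, onset + 3, 0.0, a)
        elif archetype == "transient-increase":
            if d <= peak:
                out[i] = ramp(d, onset - 1, peak, 0.0, a)
            else:
                out[i] = ramp(d, peak, last, a, 0.0)
        elif archetype == "late-increase":
            out[i] = ramp(d, peak, last, 0.0, a)
        elif archetype == "rapid-decline":
            out[i] = ramp(d, onset - 1, onset + 2, 0.0, -a)
        elif archetype == "late-decline":
            out[i] = ramp(d, peak, last, 0.0, -a)
    return out


# ---------------------------------------------------------------------------
# abundance


def generate_abundance(
    design: StudyDesign,
    n_taxa: int = 200,
    n_guilds: int = 20,
    seed: int = 0,
    rho_w: float = 0.7,
    amplitude: float = 1.5,
    sigma_base: float = 1.0,
    sigma_participant: float = 0.5,
    sigma_noise: float = 0.7,
    dirichlet_multinomial_depth: int | None = None,
) -> tuple[AbundanceTable, GroundTruth]:
    """Simulate a guild-structured compositional abundance table.

    Taxa are assigned to ``n_guilds`` guilds (each at least 5 members);
    guilds cycle through the six temporal archetypes.  Returns the closed
    relative-abundance table for every participant of every group together
    with the :class:`GroundTruth` plantings (including the uncomposed log
    basis, used by generator self-tests as the correlation oracle).
    """
    if n_taxa <= 0 or n_guilds <= 0:
        raise ValueError("n_taxa and n_guilds must be positive")
    if n_taxa < 5 * n_guilds:
        raise ValueError("need n_taxa >= 5 * n_guilds so every guild has >= 5 members")
    if not 0.0 <= rho_w < 1.0:
        raise ValueError("rho_w must be in [0, 1)")

    rng = np.random.default_rng(seed)
    taxa = [f"taxon{i:04d}" for i in range(n_taxa)]
    guilds = [f"guild{i:02d}" for i in range(n_guilds)]
    guild_of_taxon = {t: guilds[i % n_guilds] for i, t in enumerate(taxa)}
    archetype_of_guild = {g: ARCHETYPES[i % len(ARCHETYPES)] for i, g in enumerate(guilds)}

    days = list(design.days)
    n_days = len(days)
    curves = {
        g: archetype_curve(archetype_of_guild[g], days, amplitude, design.phase_of_day)
        for g in guilds
    }
    guild_idx = np.array([guilds.index(guild_of_taxon[t]) for t in taxa])
    curve_mat = np.stack([curves[g] for g in guilds])           # guilds x days

    mu = rng.normal(0.0, sigma_base, size=n_taxa)
    participants = design.all_participants()

    rows = []
    index = []
    basis_rows = []
    for p in participants:
        b = rng.normal(0.0, sigma_participant, size=n_taxa)
        u = rng.normal(0.0, 1.0, size=(n_days, n_guilds))       # guild latent factor
        e = rng.normal(0.0, 1.0, size=(n_days, n_taxa))
        noise = sigma_noise * (
            np.sqrt(rho_w) * u[:, guild_idx] + np.sqrt(1.0 - rho_w) * e
        )
        log_basis = mu[None, :] + b[None, :] + curve_mat[guild_idx, :].T + noise
        x = np.exp(log_basis)
        x /= x.sum(axis=1, keepdims=True)
        if dirichlet_multinomial_depth is not None:
            counts = np.stack(
                [rng.multinomial(dirichlet_multinomial_depth, row) for row in x]
            ).astype(float)
            x = counts / counts.sum(axis=1, keepdims=True)
        rows.append(x)
        basis_rows.append(log_basis)
        index.extend((p, d) for d in days)

    idx = pd.MultiIndex.from_tuples(index, names=["participant", "day"])
    values = pd.DataFrame(np.vstack(rows), index=idx, columns=taxa)
    basis = pd.DataFrame(np.vstack(basis_rows), index=idx, columns=taxa)

    truth = GroundTruth(
        guild_of_taxon=guild_of_taxon,
        archetype_of_guild=archetype_of_guild,
        seeds={"abundance": int(seed)},
        rho_w=rho_w,
        log_basis=basis,
    )
    return AbundanceTable(values), truth


# ---------------------------------------------------------------------------
# metabolites


def default_links(truth: GroundTruth, n_metabolites: int) -> list[PlantedLink]:
    """Five planted couplings spread over response archetypes.

    Delays cover 0-3 days with both signs; the headline planting is a
    positive 3-day-delayed coupling to a sustained-increase guild, the
    pattern the delay-limited association screen is meant to recover.
    """
    by_arch: dict[str, list[str]] = {}
    for g in truth.guilds:
        by_arch.setdefault(truth.archetype_of_guild[g], []).append(g)

    def pick(arch: str, k: int = 0) -> str | None:
        gs = by_arch.get(arch, [])
        return gs[k] if len(gs) > k else None

    wanted = [
        (pick("sustained-increase"), 3, +1),
        (pick("transient-increase"), 1, +1),
        (pick("late-increase"), 2, -1),
        (pick("rapid-decline"), 0, +1),
        (pick("sustained-increase", 1) or pick("late-decline"), 3, -1),
    ]
    links = []
    for i, (g, delay, sign) in enumerate(wanted):
        if g is None or i >= n_metabolites:
            continue
        links.append(PlantedLink(g, f"met{i:03d}", delay, sign, 1.0))
    return links


def generate_metabolites(
    abundance: AbundanceTable,
    truth: GroundTruth,
    n_metabolites: int = 20,
    links: Iterable[PlantedLink] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> MetaboliteTable:
    """Simulate fecal metabolite concentrations with lag-coupled plantings.

    A linked metabolite on day ``t`` follows the per-participant z-scored
    log guild abundance at day ``t - delay`` scaled by the planted effect,
    plus Gaussian noise; the coupling is undefined for the first ``delay``
    days, which carry noise only.  Unlinked metabolites are pure noise.  Values are exponentiated so concentrations stay
    positive.  The plantings are recorded into ``truth.planted_links``.
    """
    rng = np.random.default_rng(seed)
    if links is None:
        links = default_links(truth, n_metabolites)
    links = list(links)
    max_day_span = len(abundance.days) - 1
    for link in links:
        if link.guild not in truth.guilds:
            raise ValueError(f"planted link references unknown guild {link.guild!r}")
        if not 0 <= link.delay <= max_day_span:
            raise ValueError(f"planted delay {link.delay} outside day range")

    guild_ab = truth.guild_abundance(abundance)
    mets = [f"met{i:03d}" for i in range(n_metabolites)]
    link_of_met = {l.metabolite: l for l in links}
    days = abundance.days
    out = {}
    for p in abundance.participants:
        g_log = np.log(guild_ab.xs(p, level=0).sort_index())
        g_z = (g_log - g_log.mean()) / g_log.std(ddof=0).replace(0.0, 1.0)
        block = np.empty((len(days), n_metabolites))
        for j, m in enumerate(mets):
            eps = rng.normal(0.0, noise_sd, size=len(days))
            if m in link_of_met:
                l = link_of_met[m]
                z = g_z[l.guild].to_numpy()
                # the coupling is undefined before day `delay`: noise only
                signal = np.zeros(len(days))
                if l.delay > 0:
                    signal[l.delay:] = l.effect * l.sign * z[:-l.delay]
                else:
                    signal[:] = l.effect * l.sign * z
            else:
                signal = 0.0
            block[:, j] = np.exp(0.5 * (signal + eps))
        out[p] = block

    idx = pd.MultiIndex.from_tuples(
        [(p, d) for p in abundance.participants for d in days],
        names=["participant", "day"],
    )
    values = pd.DataFrame(
        np.vstack([out[p] for p in abundance.participants]), index=idx, columns=mets
    )
    truth.planted_links = links
    truth.seeds["metabolites"] = int(seed)
    return MetaboliteTable(values)


def generate_mediation_dataset(
    truth: GroundTruth,
    guild: str | None = None,
    metabolite: str = "serum_met000",
    outcome: str = "fasting_glucose",
    a: float = 1.0,
    b: float = 0.5,
    c_prime: float = 0.3,
    n_participants: int = 10,
    n_obs: int = 14,
    sd_random: float = 0.5,
    sd_resid: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a treatment -> mediator -> outcome panel with random intercepts.

    Treatment is a standardized guild-abundance surrogate; the serum
    mediator follows M = a*T + u_M + e and the glycemic outcome
    Y = c'*T + b*M + u_Y + e, with participant random intercepts u.  The
    planted (a, b) path is recorded in ``truth.planted_mediation``.
    """
    rng = np.random.default_rng(seed)
    if guild is None:
        guild = truth.guilds[0]
    rows = []
    for i in range(n_participants):
        u_m, u_y = rng.normal(0.0, sd_random, 2)
        for _ in range(n_obs):
            t = rng.standard_normal()
            m = a * t + u_m + rng.normal(0.0, sd_resid)
            y = c_prime * t + b * m + u_y + rng.normal(0.0, sd_resid)
            rows.append({"treatment": t, "mediator": m, "outcome": y,
                         "participant": f"p{i:02d}"})
    truth.planted_mediation = PlantedMediation(guild, metabolite, outcome, a, b)
    truth.seeds["mediation"] = int(seed)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# glucose


def generate_glucose(
    design: StudyDesign,
    participants: Sequence[str] | None = None,
    intervention_effect: float = 0.35,
    seed: int = 0,
    baseline_mean: float = 110.0,
    baseline_sd: float = 10.0,
    excursion_amplitude: float = 55.0,
    ar_phi: float = 0.6,
    ar_sd: float = 6.0,
) -> pd.DataFrame:
    """Simulate CGM traces: baseline + three daily meal excursions + AR(1).

    Meal excursions are smooth Gaussian peaks after breakfast, lunch and
    dinner; from the first intervention day their amplitude is multiplied by
    ``1 - intervention_effect``, lowering within-day glycemic variability
    while leaving the baseline untouched.  Returns a long DataFrame with
    columns ``participant``, ``timestamp_min`` (minutes since day-0
    midnight) and ``glucose_mgdl``.
    """
    if not 0.0 <= intervention_effect < 1.0:
        raise ValueError("intervention_effect must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if participants is None:
        participants = design.all_participants()

    step = design.cgm_cadence_minutes
    per_day = design.readings_per_day
    days = list(design.days)
    minutes_of_day = np.arange(per_day) * step
    meal_times = np.array([7.5, 12.5, 18.5]) * 60.0
    meal_width = 50.0  # minutes

    frames = []
    for p in participants:
        base = rng.normal(baseline_mean, baseline_sd)
        amps = rng.normal(excursion_amplitude, 8.0, size=3).clip(min=20.0)
        trace = np.empty(len(days) * per_day)
        ar = 0.0
        for di, d in enumerate(days):
            scale = 1.0 - intervention_effect if design.phase_of_day[d] != NORMAL else 1.0
            bumps = np.zeros(per_day)
            for mt, amp in zip(meal_times, amps):
                bumps += scale * amp * np.exp(-0.5 * ((minutes_of_day - mt) / meal_width) ** 2)
            for k in range(per_day):
                ar = ar_phi * ar + rng.normal(0.0, ar_sd)
                trace[di * per_day + k] = base + bumps[k] + ar
        ts = np.concatenate([d * 1440 + minutes_of_day for d in days])
        glucose = np.clip(trace, 40.0, 400.0)
        frames.append(
            pd.DataFrame(
                {"participant": p, "timestamp_min": ts, "glucose_mgdl": glucose}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gene annotations


FIBER_SUBSTRATES = ("starch", "inulin", "sucrose_fructans")
OTHER_SUBSTRATES = ("pectin", "mucin", "cellulose")
PTS_GROUPS = ("pts_bglF", "pts_ptsH")
OTHER_KO_GROUPS = ("galactitol_transport", "nitrogen_transport")


def generate_annotations(
    truth: GroundTruth,
    seed: int = 0,
    enrichment: float = 3.0,
    base_rate: float = 8.0,
) -> pd.DataFrame:
    """Per-taxon CAZy / KO annotation counts tied to planted archetypes.

    Taxa in increase-archetype guilds draw fiber-substrate CAZy counts
    (starch, inulin, sucrose/fructans) and PTS transport KOs at
    ``enrichment`` times the base Poisson rate; decline-guild taxa are
    enriched for pectin CAZy genes and galactitol/nitrogen transport KOs.
    Totals are sums over categories, so every per-substrate count is
    bounded by its total by construction.
    """
    rng = np.random.default_rng(seed)
    taxa = sorted(truth.guild_of_taxon)
    rows = {}
    for t in taxa:
        arch = truth.archetype_of_guild[truth.guild_of_taxon[t]]
        up = arch in INCREASE_ARCHETYPES
        down = arch in DECLINE_ARCHETYPES
        row = {}
        for s in FIBER_SUBSTRATES:
            row[f"cazy_{s}"] = rng.poisson(base_rate * (enrichment if up else 1.0))
        for s in OTHER_SUBSTRATES:
            rate = base_rate * (enrichment if (down and s == "pectin") else 1.0)
            row[f"cazy_{s}"] = rng.poisson(rate)
        row["cazy_other"] = rng.poisson(base_rate * 4)
        for s in PTS_GROUPS:
            row[f"ko_{s}"] = rng.poisson(base_rate * (enrichment if up else 1.0))
        for s in OTHER_KO_GROUPS:
            row[f"ko_{s}"] = rng.poisson(base_rate * (enrichment if down else 1.0))
        row["ko_other"] = rng.poisson(base_rate * 4)
        rows[t] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    cazy_cols = [c for c in table.columns if c.startswith("cazy_")]
    ko_cols = [c for c in table.columns if c.startswith("ko_")]
    table["cazy_total"] = table[cazy_cols].sum(axis=1)
    table["ko_total"] = table[ko_cols].sum(axis=1)
    truth.seeds["annotations"] = int(seed)
    table.index.name = "taxon"
    return table
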