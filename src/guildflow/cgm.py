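"""Continuous-glucose-monitoring metric panel from 15-minute traces.

Per participant-day: mean blood glucose (MBG), SD (overall and split into
daytime 06:00-22:00 / nighttime 22:00-06:00), time in/above/below the
70-180 mg/dL target range, % time < 180, MAGE, CONGA at 1 h, J index,
low/high blood-glucose risk indices (Kovatchev symmetrizing transform),
LAGE (largest amplitude of glycemic excursions), CV%, estimated A1C and
the glucose management indicator.  Range percentages use the partitioning
convention TIR = %[70, 180], TAR = % > 180, TBR = % < 70, so the three
always sum to exactly 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .design import StudyDesign

DAY_START_MIN = 6 * 60     # 06:00
NIGHT_START_MIN = 22 * 60  # 22:00


def _mage(glucose: np.ndarray, smooth_window: int = 9) -> float:
    """Mean amplitude of glycemic excursions exceeding one within-day SD.

    Turning points are taken from a centered moving-average smoothed
    series; excursion amplitudes are read off the original readings at the
    turning points, and only excursions in the direction of the first
    qualifying excursion are averaged.
    """
    n = glucose.size
    sd = glucose.std(ddof=1) if n > 1 else 0.0
    if sd == 0 or n < 3:
        return 0.0
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    padded = np.pad(glucose, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    diffs = np.diff(smoothed)
    direction = np.sign(diffs)
    turning = [0]
    last_dir = 0.0
    for i, s in enumerate(direction):
        if s == 0:
            continue
        if last_dir != 0 and s != last_dir:
            turning.append(i)
        last_dir = s
    turning.append(n - 1)
    tp_values = glucose[np.array(sorted(set(turning)))]
    amplitudes = np.diff(tp_values)
    qualifying = amplitudes[np.abs(amplitudes) > sd]
    if qualifying.size == 0:
        return 0.0
    first_dir = np.sign(qualifying[0])
    use = qualifying[np.sign(qualifying) == first_dir]
    return float(np.abs(use).mean())


def _conga(glucose: np.ndarray, minutes: np.ndarray, lag_minutes: int = 60,
           tolerance: int = 5) -> float:
    """SD of differences between readings ``lag_minutes`` apart.

    Each reading is paired with the nearest earlier reading within
    ``tolerance`` minutes of the nominal lag.
    """
    diffs = []
    for i, t in enumerate(minutes):
        target = t - lag_minutes
        j = np.argmin(np.abs(minutes - target))
        if abs(minutes[j] - target) <= tolerance and minutes[j] < t:
            diffs.append(glucose[i] - glucose[j])
    if len(diffs) < 2:
        return np.nan
    return float(np.std(diffs, ddof=1))


def _bgi(glucose: np.ndarray) -> tuple[float, float]:
    """Low/high blood-glucose risk indices via f(g)=1.509((ln g)^1.084 - 5.381)."""
    f = 1.509 * (np.log(glucose) ** 1.084 - 5.381)
    risk = 10.0 * f ** 2
    lbgi = float(np.where(f < 0, risk, 0.0).mean())
    hbgi = float(np.where(f > 0, risk, 0.0).mean())
    return lbgi, hbgi


def compute_daily_metrics(
    traces: pd.DataFrame,
    exclusion_days: set[tuple[str, int]] | set[int] | None = None,
    low: float = 70.0,
    high: float = 180.0,
    min_coverage: float = 0.7,
    cadence_minutes: int = 15,
) -> pd.DataFrame:
    """Daily CGM metric panel from long traces.

    ``traces`` has columns participant, timestamp_min (minutes since day-0
    midnight, strictly increasing per participant) and glucose_mgdl.
    ``exclusion_days`` lists days to drop, either globally (ints, e.g.
    sensor-change days) or per participant ((participant, day) tuples).
    Days with fewer than ``min_coverage`` of the expected readings are
    dropped and reported in the ``coverage`` column of the returned frame.
    """
    exclusion_days = exclusion_days or set()
    expected = 1440 // cadence_minutes
    rows = []
    for participant, sub in traces.groupby("participant", sort=True):
        ts = sub["timestamp_min"].to_numpy(dtype=float)
        if (np.diff(ts) <= 0).any():
            raise ValueError(f"{participant}: non-monotone timestamps")
        glucose = sub["glucose_mgdl"].to_numpy(dtype=float)
        days = (ts // 1440).astype(int)
        for day in np.unique(days):
            if day in exclusion_days or (participant, day) in exclusion_days:
                continue
            m = days == day
            g = glucose[m]
            minutes = ts[m] - day * 1440
            if g.size == 0:
                continue
            coverage = g.size / expected
            if coverage < min_coverage:
                continue
            mbg = g.mean()
            sd = g.std(ddof=1) if g.size > 1 else 0.0
            is_day = (minutes >= DAY_START_MIN) & (minutes < NIGHT_START_MIN)
            sd_day = g[is_day].std(ddof=1) if is_day.sum() > 1 else np.nan
            sd_night = g[~is_day].std(ddof=1) if (~is_day).sum() > 1 else np.nan
            tir = 100.0 * ((g >= low) & (g <= high)).mean()
            tar = 100.0 * (g > high).mean()
            tbr = 100.0 * (g < low).mean()
            lbgi, hbgi = _bgi(g)
            rows.append({
                "participant": participant,
                "day": int(day),
                "n_readings": int(g.size),
                "coverage": coverage,
                "MBG": mbg,
                "SD": sd,
                "SD_day": sd_day,
                "SD_night": sd_night,
                "TIR": tir,
                "TAR": tar,
                "TBR": tbr,
                "pct_below_180": 100.0 * (g < high).mean(),
                "MAGE": _mage(g),
                "CONGA_1h": _conga(g, minutes),
                "J_index": 0.001 * (mbg + sd) ** 2,
                "LBGI": lbgi,
                "HBGI": hbgi,
                "LAGE": float(g.max() - g.min()),
                "CV": 100.0 * sd / mbg if mbg > 0 else np.nan,
                "eA1C": (mbg + 46.7) / 28.7,
                "GMI": 3.31 + 0.02392 * mbg,
            })
    return pd.DataFrame(rows)


def summarize_phases(
    metrics: pd.DataFrame,
    design: StudyDesign | None = None,
    group_of_participant: dict[str, str] | None = None,
    metric_columns: list[str] | None = None,
    direction: str = "less",
) -> dict[str, pd.DataFrame]:
    """Phase summaries with the trial's between/within-group tests.

    Per participant and metric: habitual-phase mean and intervention-phase
    mean.  Between groups: one-way ANCOVA of the intervention mean with the
    habitual mean as covariate.  Within each group: one-tailed Wilcoxon
    signed-rank of intervention vs habitual means (default alternative
    ``less``, i.e. variability decreases).  Groups with n < 3 are skipped.
    """
    if design is None:
        design = StudyDesign()
    if group_of_participant is None:
        group_of_participant = {
            p: design.group_of(p) for p in metrics["participant"].unique()
        }
    if metric_columns is None:
        metric_columns = [c for c in metrics.columns
                          if c not in ("participant", "day", "n_readings", "coverage")]

    metrics = metrics.copy()
    metrics["phase"] = [design.phase_of_day.get(d, "post") for d in metrics["day"]]
    metrics["in_intervention"] = metrics["phase"].isin(["low", "high"])

    per_part = metrics.groupby(["participant", "in_intervention"])[metric_columns].mean()
    summary_rows, ancova_rows, wilcoxon_rows = [], [], []
    for col in metric_columns:
        wide = per_part[col].unstack("in_intervention")
        if True not in wide.columns or False not in wide.columns:
            continue
        wide = wide.rename(columns={False: "normal_mean", True: "intervention_mean"})
        wide = wide.dropna()
        wide["group"] = [group_of_participant[p] for p in wide.index]
        for g, sub in wide.groupby("group"):
            summary_rows.append({
                "metric": col, "group": g, "n": len(sub),
                "normal_mean": sub["normal_mean"].mean(),
                "intervention_mean": sub["intervention_mean"].mean(),
            })
            if len(sub) >= 3:
                try:
                    stat, p = sps.wilcoxon(
                        sub["intervention_mean"], sub["normal_mean"],
                        alternative=direction,
                    )
                except ValueError:
                    stat, p = np.nan, 1.0
                wilcoxon_rows.append({"metric": col, "group": g,
                                      "W": stat, "p": p})
        groups = wide["group"].unique()
        if len(groups) == 2 and (wide.groupby("group").size() >= 3).all():
            fit = smf.ols(
                "intervention_mean ~ normal_mean + C(group)", data=wide
            ).fit()
            term = [t for t in fit.params.index if t.startswith("C(group)")][0]
            ancova_rows.append({
                "metric": col,
                "group_effect": fit.params[term],
                "p": fit.pvalues[term],
            })
    return {
        "summary": pd.DataFrame(summary_rows),
        "ancova": pd.DataFrame(ancova_rows),
        "wilcoxon": pd.DataFrame(wilcoxon_rows),
    }
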