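"""Indirect calorimetry: Weir energy expenditure, hourly binning, and
detection of the onset of energy-expenditure/intake coupling.

Energy expenditure follows the abbreviated Weir equation,

    EE (kcal/h) = 60 * (3.941 * VO2 + 1.106 * VCO2) / 1000,

with gas-exchange rates in ml/min.  Hourly summaries bin EE (mean of
per-sample values) and food intake (difference of cumulative grams times the
diet energy density, default 3.56 kcal/g) into hours indexed relative to the
onset of the cold transition.

The coupling analysis mirrors the observation that, after a switch to cold,
energy expenditure rises immediately while intake catches up only hours
later.  A sliding-window Pearson correlation between hourly EE and hourly
intake, pooled over (animal, hour) pairs, yields a correlation profile r(h);
the cold-induced energy-compensation (CIEC) onset is the earliest window
centre at which r reaches a threshold and stays at or above it for every
later defined window ("remaining elevated thereafter").
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WEIR_KCAL_PER_L_O2",
    "WEIR_KCAL_PER_L_CO2",
    "DIET_KCAL_PER_G",
    "PELLET_MASS_G",
    "CalorimetrySeries",
    "HourlySummary",
    "CorrelationProfile",
    "CIECOnset",
    "weir_energy_expenditure",
    "hourly_bin",
    "pool_hourly",
    "group_hourly_stats",
    "ee_intake_correlation_profile",
    "detect_ciec_onset",
    "read_calorimetry",
    "write_calorimetry",
]

# Abbreviated Weir coefficients, kcal per litre of O2 consumed / CO2 produced.
WEIR_KCAL_PER_L_O2 = 3.941
WEIR_KCAL_PER_L_CO2 = 1.106
#: Diet energy density (kcal per gram of chow).
DIET_KCAL_PER_G = 3.56
#: Mass of one dispensed food pellet (grams).
PELLET_MASS_G = 0.020


@dataclass
class CalorimetrySeries:
    """Per-animal gas exchange, cumulative intake and ambient temperature."""

    t_min: np.ndarray
    vo2_ml_min: np.ndarray
    vco2_ml_min: np.ndarray
    intake_cum_g: np.ndarray
    temp_c: np.ndarray
    animal_id: str = ""

    def __post_init__(self) -> None:
        for name in ("t_min", "vo2_ml_min", "vco2_ml_min", "intake_cum_g", "temp_c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_min)
        for name in ("vo2_ml_min", "vco2_ml_min", "intake_cum_g", "temp_c"):
            if len(getattr(self, name)) != n:
                raise ValueError("all columns must share a length")
        if n > 1 and np.any(np.diff(self.t_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.vo2_ml_min < 0) or np.any(self.vco2_ml_min < 0):
            raise ValueError("gas-exchange rates must be non-negative")
        if np.any(np.diff(self.intake_cum_g) < -1e-12):
            raise ValueError("cumulative intake must be non-decreasing")

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass
class HourlySummary:
    """Hourly EE (kcal/h) and intake (kcal) indexed relative to cold onset."""

    hours: np.ndarray  # integer hour index; hour h covers [h, h+1)
    ee_kcal_h: np.ndarray
    intake_kcal: np.ndarray
    animal_id: str = ""

    def __len__(self) -> int:
        return len(self.hours)


@dataclass
class CorrelationProfile:
    """Sliding-window Pearson r between pooled hourly EE and intake."""

    hours: np.ndarray  # window centres
    r: np.ndarray  # NaN where undefined
    n_pairs: np.ndarray
    window_h: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.r)


@dataclass
class CIECOnset:
    """Detected onset of sustained EE-intake coupling (None if never sustained)."""

    onset_h: int | None
    threshold: float
    sustained: bool


def weir_energy_expenditure(vo2_ml_min, vco2_ml_min):
    """Abbreviated Weir equation; accepts scalars or arrays, returns kcal/h."""
    vo2 = np.asarray(vo2_ml_min, dtype=float)
    vco2 = np.asarray(vco2_ml_min, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas-exchange rates must be non-negative")
    ee = 60.0 * (WEIR_KCAL_PER_L_O2 * vo2 + WEIR_KCAL_PER_L_CO2 * vco2) / 1000.0
    return float(ee) if ee.ndim == 0 else ee


def _cum_at(t: np.ndarray, cum: np.ndarray, tau: float) -> float:
    """Cumulative intake at time tau: value of the last sample at or before tau."""
    i = int(np.searchsorted(t, tau + 1e-9)) - 1
    return float(cum[max(i, 0)])


def hourly_bin(
    series: CalorimetrySeries,
    cold_onset_min: float,
    energy_density_kcal_g: float = DIET_KCAL_PER_G,
) -> HourlySummary:
    """Bin a calorimetry series into hours relative to cold onset.

    Hour h covers [h, h+1) hours after ``cold_onset_min``.  Only hours fully
    covered by the recording are kept (partial leading/trailing hours are
    excluded).  EE is the mean per-sample Weir value; intake is the cumulative
    difference across the hour times the diet energy density.
    """
    t = series.t_min
    if t[-1] - t[0] < 60.0:
        raise ValueError("recording spans less than one hour")
    rel_h = (t - cold_onset_min) / 60.0
    h_first = int(np.ceil(rel_h[0] - 1e-9))
    h_last = int(np.floor(rel_h[-1] + 1e-9)) - 1  # last fully covered hour
    if h_last < h_first:
        raise ValueError("no fully covered hour in the recording")
    ee_all = weir_energy_expenditure(series.vo2_ml_min, series.vco2_ml_min)
    hours, ee_out, intake_out = [], [], []
    for h in range(h_first, h_last + 1):
        lo = cold_onset_min + 60.0 * h
        hi = lo + 60.0
        m = (t >= lo - 1e-9) & (t < hi - 1e-9)
        if not np.any(m):
            continue
        hours.append(h)
        ee_out.append(float(np.mean(ee_all[m])))
        intake_out.append(
            (_cum_at(t, series.intake_cum_g, hi) - _cum_at(t, series.intake_cum_g, lo))
            * energy_density_kcal_g
        )
    return HourlySummary(
        hours=np.asarray(hours, dtype=int),
        ee_kcal_h=np.asarray(ee_out),
        intake_kcal=np.asarray(intake_out),
        animal_id=series.animal_id,
    )


def pool_hourly(summaries: list[HourlySummary]) -> pd.DataFrame:
    """Long-format pooled table of (animal, hour, ee_kcal_h, intake_kcal)."""
    if not summaries:
        raise ValueError("no hourly summaries to pool")
    ref = summaries[0].hours
    for s in summaries[1:]:
        if len(s.hours) != len(ref) or np.any(s.hours != ref):
            raise ValueError("hour grids differ between animals")
    frames = [
        pd.DataFrame(
            {
                "animal": s.animal_id or f"animal{i}",
                "hour": s.hours,
                "ee_kcal_h": s.ee_kcal_h,
                "intake_kcal": s.intake_kcal,
            }
        )
        for i, s in enumerate(summaries)
    ]
    return pd.concat(frames, ignore_index=True)


def group_hourly_stats(pooled: pd.DataFrame) -> pd.DataFrame:
    """Per-hour group mean and s.e.m. of EE and intake."""
    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    g = pooled.groupby("hour")
    return pd.DataFrame(
        {
            "ee_mean": g["ee_kcal_h"].mean(),
            "ee_sem": g["ee_kcal_h"].apply(sem),
            "intake_mean": g["intake_kcal"].mean(),
            "intake_sem": g["intake_kcal"].apply(sem),
        }
    ).reset_index()


def ee_intake_correlation_profile(
    pooled: pd.DataFrame, window_h: int = 1
) -> CorrelationProfile:
    """Sliding-window Pearson r(h) over pooled (animal, hour) pairs.

    At each window centre h, all pairs with hour in [h - window_h, h + window_h]
    enter the correlation.  Windows with fewer than 3 pairs or zero variance
    in either variable are flagged undefined (NaN), not errors.
    """
    hours = np.sort(pooled["hour"].unique())
    if window_h < 0 or 2 * window_h + 1 < 2:
        raise ValueError("window must span at least 2 pooled hours")
    r_out = np.full(len(hours), np.nan)
    n_out = np.zeros(len(hours), dtype=int)
    for i, h in enumerate(hours):
        m = (pooled["hour"] >= h - window_h) & (pooled["hour"] <= h + window_h)
        ee = pooled.loc[m, "ee_kcal_h"].to_numpy()
        intake = pooled.loc[m, "intake_kcal"].to_numpy()
        n_out[i] = len(ee)
        if len(ee) < 3 or np.ptp(ee) == 0 or np.ptp(intake) == 0:
            continue
        r_out[i] = float(np.corrcoef(ee, intake)[0, 1])
    return CorrelationProfile(hours=hours, r=r_out, n_pairs=n_out, window_h=window_h)


def detect_ciec_onset(profile: CorrelationProfile, threshold: float = 0.5) -> CIECOnset:
    """Earliest window centre with r >= threshold sustained to the end.

    "Sustained" means every later defined window also has r >= threshold; an
    onset that is never sustained yields ``onset_h=None``.
    """
    defined = profile.defined
    if not np.any(defined):
        raise ValueError("correlation profile has no defined window")
    idx_def = np.flatnonzero(defined)
    above = profile.r[idx_def] >= threshold
    # scan from the right: find the earliest defined index after which all
    # defined windows stay above threshold
    onset = None
    for j in range(len(idx_def) - 1, -1, -1):
        if above[j]:
            onset = int(profile.hours[idx_def[j]])
        else:
            break
    return CIECOnset(onset_h=onset, threshold=threshold, sustained=onset is not None)


def read_calorimetry(path) -> CalorimetrySeries:
    """Read `time_min,vo2_ml_min,vco2_ml_min,intake_cum_g,temp_c` CSV."""
    animal_id = ""
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("animal_id="):
                    animal_id = stripped.split("=", 1)[1].strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    return CalorimetrySeries(
        t_min=df["time_min"].to_numpy(dtype=float),
        vo2_ml_min=df["vo2_ml_min"].to_numpy(dtype=float),
        vco2_ml_min=df["vco2_ml_min"].to_numpy(dtype=float),
        intake_cum_g=df["intake_cum_g"].to_numpy(dtype=float),
        temp_c=df["temp_c"].to_numpy(dtype=float),
        animal_id=animal_id,
    )


def write_calorimetry(series: CalorimetrySeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if series.animal_id:
            fh.write(f"# animal_id={series.animal_id}\n")
        fh.write("time_min,vo2_ml_min,vco2_ml_min,intake_cum_g,temp_c\n")
        for row in zip(
            series.t_min,
            series.vo2_ml_min,
            series.vco2_ml_min,
            series.intake_cum_g,
            series.temp_c,
        ):
            fh.write(",".join(f"{float(v)!r}" for v in row) + "\n")
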