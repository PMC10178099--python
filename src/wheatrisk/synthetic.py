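"""Synthetic weekly heavy-metal surveillance data for wheat.

Real provincial sampling data of this kind are access-restricted, so the
package ships a generator that reproduces the statistical structure the
downstream analysis depends on:

* a province x week x metal x replicate sampling frame (default 20 provinces,
  159 weeks ~ three years, 5 metals, 8 samples per cell);
* log-normal baseline concentrations sitting near the instrument detection
  limits, so that roughly half of all raw measurements are non-detects and
  must be imputed at half the LOD;
* recurring seasonal contamination episodes (multiplicative spikes on the
  log-normal mean, tied to fixed weeks of the year) that induce a
  common-low / occasional-medium / rare-high risk-level structure; and
* a per-province mean wheat consumption (kg/d) drawn once per province.

Because episodes recur at fixed weeks of the year, the induced indicator
series are predictable from a week-of-year covariate, which is what the
forecasting stage exploits.

All randomness flows from a single integer seed through fixed
``numpy.random.SeedSequence`` spawn keys, one per stage, so a configuration
plus seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .toxicology import METALS

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["province", "week", "metal", "value_mg_per_kg", "nondetect", "lod_mg_per_kg"]

# SeedSequence spawn keys, one per random stage.
_PROFILE_STREAM = 0
_CONCENTRATION_STREAM = 1


def week_of_year(week: int | np.ndarray) -> int | np.ndarray:
    """Map a 1-based global week index onto a fixed 52-week year (week 53 wraps to 1)."""
    return (np.asarray(week) - 1) % 52 + 1


@dataclass(frozen=True)
class ContaminationEvent:
    """A recurring seasonal contamination episode.

    During every global week whose week-of-year falls in ``weeks_of_year``,
    the log-normal mean concentration of each metal in ``metals`` is
    multiplied by ``factor`` for every province in ``provinces``.
    """

    provinces: tuple[str, ...]
    weeks_of_year: tuple[int, ...]
    metals: tuple[str, ...]
    factor: float

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("event_spec: spike factor must be >= 1")
        if not all(1 <= w <= 52 for w in self.weeks_of_year):
            raise ValueError("event_spec: weeks_of_year must lie in 1..52")


def _default_events(province_ids: Sequence[str]) -> tuple[ContaminationEvent, ...]:
    """Default episode calendar: two national medium episodes, one national
    high episode in autumn, and an early-February high episode confined to
    three provinces (the kind of regional holiday-season event reported for
    wheat surveillance)."""
    all_p = tuple(province_ids)
    return (
        ContaminationEvent(all_p, (24, 25, 26), METALS, 3.0),
        ContaminationEvent(all_p, (46, 47, 48), METALS, 3.0),
        ContaminationEvent(all_p, (40, 41), METALS, 6.0),
        ContaminationEvent(all_p[:3], (5, 6), METALS, 6.0),
    )


# Instrument-level detection limits (mg/kg) typical of GF-AAS / ICP-MS / cold
# AAS wheat assays.  Baseline medians sit at the LODs so that about half of
# the raw baseline measurements are non-detects.
DEFAULT_LOD = {"Hg": 2e-4, "Cd": 2e-4, "As": 4e-4, "Pb": 1e-3, "Cr": 2e-3}
DEFAULT_LOGSD = {"Hg": 0.18, "Cd": 0.10, "As": 0.10, "Pb": 0.20, "Cr": 0.10}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic surveillance dataset."""

    n_provinces: int = 20
    n_weeks: int = 159
    samples_per_cell: int = 8
    lod_per_metal: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOD))
    nondetect_target_frac: float = 0.5
    consumption_range: tuple[float, float] = (0.2, 0.4)
    baseline_logmean: dict[str, float] | None = None  # default: ln(LOD) per metal
    baseline_logsd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOGSD))
    event_spec: tuple[ContaminationEvent, ...] | None = None  # default calendar
    # episode-severity jitter: log-sd of a common multiplicative factor shared
    # by all metals within one (province, event week), so episode intensity
    # varies realistically between occurrences
    event_jitter_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 1:
            raise ValueError("n_provinces must be >= 1")
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        if self.samples_per_cell < 1:
            raise ValueError("samples_per_cell must be >= 1")
        for metal in METALS:
            if self.lod_per_metal.get(metal, 0.0) < 0:
                raise ValueError(f"lod_per_metal[{metal}] must be >= 0")
            if self.baseline_logsd.get(metal, 0.0) < 0:
                raise ValueError(f"baseline_logsd[{metal}] must be >= 0")
        if self.event_jitter_sd < 0:
            raise ValueError("event_jitter_sd must be >= 0")
        if not 0.0 <= self.nondetect_target_frac <= 1.0:
            raise ValueError("nondetect_target_frac must lie in [0, 1]")
        lo, hi = self.consumption_range
        if not (0 < lo <= hi):
            raise ValueError("consumption_range must be a positive interval")

    @property
    def province_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_provinces))

    def resolved_logmean(self) -> dict[str, float]:
        if self.baseline_logmean is not None:
            return dict(self.baseline_logmean)
        return {m: float(np.log(self.lod_per_metal[m])) for m in METALS}

    def resolved_events(self) -> tuple[ContaminationEvent, ...]:
        if self.event_spec is not None:
            return tuple(self.event_spec)
        return _default_events(self.province_ids)


@dataclass(frozen=True)
class ProvinceProfile:
    """Static description of one province: consumption and per-metal baselines."""

    province_id: str
    f50_kg_per_day: float
    logmean: dict[str, float]
    logsd: dict[str, float]

    def __post_init__(self) -> None:
        if self.f50_kg_per_day <= 0:
            raise ValueError("f50_kg_per_day must be > 0")


def make_profiles(config: GeneratorConfig) -> list[ProvinceProfile]:
    """Draw one :class:`ProvinceProfile` per province.

    Mean wheat consumption F50 is drawn uniformly from
    ``config.consumption_range``; the per-metal log-normal baselines are
    shared across provinces (provincial differences enter through the
    episode calendar and consumption).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_PROFILE_STREAM,)))
    lo, hi = config.consumption_range
    f50 = rng.uniform(lo, hi, size=config.n_provinces)
    logmean = config.resolved_logmean()
    logsd = dict(config.baseline_logsd)
    return [
        ProvinceProfile(pid, float(f), dict(logmean), dict(logsd))
        for pid, f in zip(config.province_ids, f50)
    ]


def _spike_factors(profiles: Sequence[ProvinceProfile], config: GeneratorConfig) -> np.ndarray:
    """(province, week, metal) multiplicative factor implied by the event calendar."""
    pid_index = {p.province_id: i for i, p in enumerate(profiles)}
    factors = np.ones((len(profiles), config.n_weeks, len(METALS)))
    woy = week_of_year(np.arange(1, config.n_weeks + 1))
    for event in config.resolved_events():
        week_mask = np.isin(woy, event.weeks_of_year)
        for pid in event.provinces:
            if pid not in pid_index:
                raise ValueError(f"event_spec references unknown province {pid!r}")
            for metal in event.metals:
                j = METALS.index(metal)
                factors[pid_index[pid], week_mask, j] *= event.factor
    return factors


def simulate_concentrations(
    profiles: Sequence[ProvinceProfile], config: GeneratorConfig
) -> pd.DataFrame:
    """Draw raw (uncensored) concentrations for the full sampling frame.

    Concentrations are log-normal around the province/metal baseline
    log-mean; within event windows the mean is multiplied by the spike
    factor.  Returns a record table with one row per sample, ordered by
    (province, week, metal, replicate).
    """
    n_p, n_w, n_m, n_s = len(profiles), config.n_weeks, len(METALS), config.samples_per_cell
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_CONCENTRATION_STREAM,))
    )
    logmean = np.array([[p.logmean[m] for m in METALS] for p in profiles])  # (p, m)
    logsd = np.array([[p.logsd[m] for m in METALS] for p in profiles])
    factors = _spike_factors(profiles, config)  # (p, w, m)
    mu = logmean[:, None, :] + np.log(factors)  # (p, w, m)
    if config.event_jitter_sd > 0:
        # one severity draw per (province, week), applied to every spiked metal
        jitter = config.event_jitter_sd * rng.standard_normal(size=(n_p, n_w))
        mu = mu + np.where(factors > 1.0, jitter[:, :, None], 0.0)
    z = rng.standard_normal(size=(n_p, n_w, n_m, n_s))
    values = np.exp(mu[..., None] + logsd[:, None, :, None] * z)

    lod = np.array([config.lod_per_metal[m] for m in METALS])
    frame = pd.DataFrame(
        {
            "province": np.repeat([p.province_id for p in profiles], n_w * n_m * n_s),
            "week": np.tile(np.repeat(np.arange(1, n_w + 1), n_m * n_s), n_p),
            "metal": np.tile(np.repeat(METALS, n_s), n_p * n_w),
            "value_mg_per_kg": values.reshape(-1),
            "nondetect": np.zeros(n_p * n_w * n_m * n_s, dtype=np.int64),
            "lod_mg_per_kg": np.tile(np.repeat(lod, n_s), n_p * n_w),
        }
    )
    return frame[RECORD_COLUMNS]


def censor_nondetects(batch: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Apply left-censoring at the per-metal LOD.

    Samples with value strictly below the LOD are flagged as non-detects and
    their measured value is cleared (ties at the LOD count as detected).  If
    the realized non-detect fraction deviates from the configured target by
    more than 0.15 a warning is logged; the cure is to adjust the LODs or
    baselines in the configuration, never the data.
    """
    out = batch.copy()
    censored = out["value_mg_per_kg"] < out["lod_mg_per_kg"]
    out.loc[censored, "value_mg_per_kg"] = np.nan
    out["nondetect"] = censored.astype(np.int64)
    realized = float(censored.mean()) if len(out) else 0.0
    if abs(realized - config.nondetect_target_frac) > 0.15:
        logger.warning(
            "realized non-detect fraction %.3f deviates from target %.3f by more than 0.15; "
            "consider tuning LODs or baselines",
            realized,
            config.nondetect_target_frac,
        )
    return out


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, list[ProvinceProfile]]:
    """Convenience wrapper: profiles -> raw concentrations -> censoring."""
    profiles = make_profiles(config)
    batch = censor_nondetects(simulate_concentrations(profiles, config), config)
    return batch, profiles


def consumption_table(profiles: Sequence[ProvinceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "province": [p.province_id for p in profiles],
            "f50_kg_per_day": [p.f50_kg_per_day for p in profiles],
        }
    )


def write_dataset(
    batch: pd.DataFrame, profiles: Sequence[ProvinceProfile], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the records and consumption CSVs; round-trips exactly through
    :func:`read_records` / :func:`read_consumption`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_path = out / "records.csv"
    consumption_path = out / "consumption.csv"
    batch.to_csv(records_path, index=False)
    consumption_table(profiles).to_csv(consumption_path, index=False)
    return records_path, consumption_path


def read_records(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={
            "province": str,
            "week": np.int64,
            "metal": str,
            "value_mg_per_kg": np.float64,
            "nondetect": np.int64,
            "lod_mg_per_kg": np.float64,
        },
    )
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"records file {path} lacks columns {sorted(missing)}")
    return frame[RECORD_COLUMNS]


def read_consumption(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"province": str, "f50_kg_per_day": np.float64})
    if not {"province", "f50_kg_per_day"} <= set(frame.columns):
        raise ValueError(f"consumption file {path} lacks required columns")
    return frame


__all__ = [
    "ContaminationEvent",
    "GeneratorConfig",
    "ProvinceProfile",
    "censor_nondetects",
    "consumption_table",
    "generate_dataset",
    "make_profiles",
    "read_consumption",
    "read_records",
    "simulate_concentrations",
    "week_of_year",
    "write_dataset",
    "DEFAULT_LOD",
    "DEFAULT_LOGSD",
    "RECORD_COLUMNS",
]
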