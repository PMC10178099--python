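"""Weekly province-level food-safety risk indicators for heavy metals in wheat.

Three indicators are computed per (province, week) from the surveillance
records and a per-province mean wheat consumption F50 (kg/d):

* **NIPI** — Nemerow integrated pollution index over the five metals.  Each
  metal's single-factor index is P_j = C_avg,j / S_j (concentration over the
  national limit), and NIPI = sqrt((P_max^2 + P_mean^2) / 2).
* **THQ** — total target hazard quotient, the sum over metals of
  EF*ED*F50*C_avg,j / (RfD_j * W * AT).  With EF = 365 d/yr and
  AT = 365*ED d this is exactly F50*C_avg,j / (RfD_j * W) per metal.
* **TCR** — total carcinogenic risk over the four carcinogenic metals
  (Cd, As, Pb, Cr; Hg has no slope factor), the sum of
  EF*ED*CSF_j*EDI_j / ATC with EDI_j = F50*C_avg,j / W.  With ED equal to
  the 70-yr carcinogenic exposure assumption the prefactor is again one.

Non-detect measurements are imputed at half the limit of detection before
averaging (the WHO convention for low-level contaminants when the
non-detect share is moderate); C_avg is then the arithmetic mean over the
samples of one (province, week, metal) cell.

Scalar operations are exposed individually for testing and reuse;
:func:`compute_indicators` is the vectorized batch entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .toxicology import CARCINOGENIC_METALS, METALS, ToxicologyTable, load_toxicology

INDICATOR_NAMES = ("nipi", "thq", "tcr")
INDICATOR_COLUMNS = ["province", "week", "nipi", "thq", "tcr"]


@dataclass(frozen=True)
class ConcentrationRecord:
    """One laboratory measurement of one metal in one wheat sample."""

    province_id: str
    week: int
    metal: str
    value: float | None  # mg/kg; None iff nondetect
    nondetect: bool
    lod: float  # mg/kg

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValueError("week must be >= 1")
        if not self.nondetect and (self.value is None or self.value < 0):
            raise ValueError("detected record must carry a non-negative value")


def substitute_nondetect(record: ConcentrationRecord) -> float:
    """Measured value for a detected record, half the LOD for a non-detect."""
    if not record.nondetect:
        return float(record.value)
    if record.lod is None or not record.lod > 0 or math.isnan(record.lod):
        raise ValueError(
            f"non-detect record ({record.province_id}, week {record.week}, {record.metal}) "
            "has no usable LOD"
        )
    return record.lod / 2.0


def weekly_mean(records: Sequence[ConcentrationRecord]) -> float:
    """Arithmetic mean of substituted values over one (province, week, metal) cell."""
    if not records:
        raise ValueError("weekly_mean: empty cell")
    return float(np.mean([substitute_nondetect(r) for r in records]))


def single_factor_index(cavg: float, limit: float) -> float:
    """Single-factor pollution index P = C_avg / S."""
    if limit <= 0:
        raise ValueError("limit must be > 0")
    if cavg < 0:
        raise ValueError("cavg must be >= 0")
    return cavg / limit


def nipi(p_indices: Iterable[float]) -> float:
    """Nemerow integrated pollution index over the five single-factor indices."""
    p = np.asarray(list(p_indices), dtype=float)
    if p.shape != (len(METALS),):
        raise ValueError(f"nipi expects exactly {len(METALS)} single-factor indices")
    if (p < 0).any():
        raise ValueError("single-factor indices must be >= 0")
    return float(np.sqrt((p.max() ** 2 + p.mean() ** 2) / 2.0))


def thq_metal(f50: float, cavg: float, rfd: float, tox: ToxicologyTable) -> float:
    """Target hazard quotient of one metal: EF*ED*F50*C_avg / (RfD*W*AT)."""
    if rfd <= 0:
        raise ValueError("rfd must be > 0")
    numerator = tox.ef_days_per_year * tox.ed_years * f50 * cavg
    return numerator / (rfd * tox.body_weight_kg * tox.at_days)


def thq_total(thq_values: Iterable[float]) -> float:
    """Total THQ: sum of the five per-metal quotients."""
    values = np.asarray(list(thq_values), dtype=float)
    if (values < 0).any():
        raise ValueError("per-metal THQ values must be >= 0")
    return float(values.sum())


def edi(f50: float, cavg: float, w: float) -> float:
    """Estimated daily intake EDI = F50 * C_avg / W in mg/(kg*d)."""
    if w <= 0:
        raise ValueError("body weight must be > 0")
    return f50 * cavg / w


def tcr_total(edis: Mapping[str, float], tox: ToxicologyTable) -> float:
    """Total carcinogenic risk: sum over Cd, As, Pb, Cr of EF*ED*CSF*EDI / ATC."""
    extra = set(edis) - set(CARCINOGENIC_METALS)
    if extra:
        raise ValueError(f"metals without a cancer slope factor passed to tcr_total: {sorted(extra)}")
    missing = set(CARCINOGENIC_METALS) - set(edis)
    if missing:
        raise ValueError(f"tcr_total requires all four carcinogenic metals; missing {sorted(missing)}")
    prefactor = tox.ef_days_per_year * tox.ed_years / tox.atc_days
    return float(
        sum(prefactor * tox.csf_kg_day_per_mg[m] * edis[m] for m in CARCINOGENIC_METALS)
    )


def weekly_mean_table(batch: pd.DataFrame) -> pd.DataFrame:
    """Per-(province, week, metal) mean concentration after 1/2-LOD substitution.

    Raises if any non-detect lacks a positive LOD or any cell is missing a
    metal entirely.
    """
    values = batch["value_mg_per_kg"].to_numpy(dtype=float, copy=True)
    nondetect = batch["nondetect"].to_numpy() == 1
    lod = batch["lod_mg_per_kg"].to_numpy(dtype=float)
    bad = nondetect & ~(lod > 0)
    if bad.any():
        row = batch[bad].iloc[0]
        raise ValueError(
            f"non-detect record ({row['province']}, week {int(row['week'])}, {row['metal']}) "
            "has no usable LOD"
        )
    values[nondetect] = lod[nondetect] / 2.0
    work = batch[["province", "week", "metal"]].copy()
    work["cavg"] = values
    table = work.groupby(["province", "week", "metal"], sort=True)["cavg"].mean().unstack("metal")
    missing = table.isna()
    if missing.to_numpy().any():
        prov, week = table.index[missing.any(axis=1)][0]
        metal = table.columns[missing.loc[(prov, week)]][0]
        raise ValueError(f"missing cell: no records for ({prov}, week {week}, {metal})")
    absent = set(METALS) - set(table.columns)
    if absent:
        raise ValueError(f"missing cell: metals {sorted(absent)} absent from the batch")
    return table[list(METALS)]


def compute_indicators(
    batch: pd.DataFrame,
    consumption: pd.DataFrame,
    tox: ToxicologyTable | None = None,
) -> pd.DataFrame:
    """Compute one (NIPI, THQ, TCR) triple per (province, week).

    ``batch`` is a records table (see :mod:`wheatrisk.synthetic`) and
    ``consumption`` maps each province to its mean wheat intake F50 (kg/d).
    Every province present in the batch must have a consumption entry and
    every (province, week) cell must cover all five metals.
    """
    tox = tox or load_toxicology()
    f50_map = dict(zip(consumption["province"], consumption["f50_kg_per_day"]))
    provinces = batch["province"].unique()
    missing = [p for p in provinces if p not in f50_map]
    if missing:
        raise ValueError(f"no consumption entry for provinces {sorted(missing)}")

    cavg = weekly_mean_table(batch)  # index (province, week), columns METALS
    limits = np.array([tox.limit_mg_per_kg[m] for m in METALS])
    rfd = np.array([tox.rfd_mg_per_kg_day[m] for m in METALS])
    csf = np.array([tox.csf_kg_day_per_mg.get(m, 0.0) for m in METALS])
    carcinogenic = np.array([m in CARCINOGENIC_METALS for m in METALS])

    c = cavg.to_numpy()  # (cells, metals)
    f50 = np.array([f50_map[p] for p, _ in cavg.index])
    w = tox.body_weight_kg

    p_idx = c / limits
    nipi_vals = np.sqrt((p_idx.max(axis=1) ** 2 + p_idx.mean(axis=1) ** 2) / 2.0)

    thq_pref = tox.ef_days_per_year * tox.ed_years / tox.at_days
    thq_vals = thq_pref * (f50[:, None] * c / (rfd * w)).sum(axis=1)

    tcr_pref = tox.ef_days_per_year * tox.ed_years / tox.atc_days
    edi_vals = f50[:, None] * c / w
    tcr_vals = tcr_pref * (csf * edi_vals)[:, carcinogenic].sum(axis=1)

    out = pd.DataFrame(
        {
            "province": [p for p, _ in cavg.index],
            "week": np.array([wk for _, wk in cavg.index], dtype=np.int64),
            "nipi": nipi_vals,
            "thq": thq_vals,
            "tcr": tcr_vals,
        }
    )
    return out.sort_values(["province", "week"], ignore_index=True)


def write_indicators(indicators: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    indicators[INDICATOR_COLUMNS].to_csv(path, index=False)
    return path


def read_indicators(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"province": str, "week": np.int64})
    missing = set(INDICATOR_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"indicators file {path} lacks columns {sorted(missing)}")
    return frame[INDICATOR_COLUMNS]


__all__ = [
    "ConcentrationRecord",
    "INDICATOR_COLUMNS",
    "INDICATOR_NAMES",
    "compute_indicators",
    "edi",
    "nipi",
    "read_indicators",
    "single_factor_index",
    "substitute_nondetect",
    "tcr_total",
    "thq_metal",
    "thq_total",
    "weekly_mean",
    "weekly_mean_table",
    "write_indicators",
]
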