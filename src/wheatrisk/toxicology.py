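"""Toxicological reference values for the five surveyed heavy metals.

The table bundles, per metal, the Chinese national food-safety limit for
wheat (``limit_mg_per_kg``), the US-EPA chronic oral reference dose
(``rfd_mg_per_kg_day``) and, for the four carcinogenic metals (Cd, As, Pb,
Cr), the oral cancer slope factor (``csf_kg_day_per_mg``), together with the
exposure constants used by the hazard-quotient and carcinogenic-risk
formulas: intake frequency EF (d/yr), exposure duration ED (yr), adult body
weight W (kg) and the carcinogenic averaging period (yr).

With EF = 365 d/yr and averaging times of 365*ED (non-carcinogenic) and
365*70 d (carcinogenic, ED = 70 yr), the ratios EF*ED/AT and EF*ED/ATC both
equal one, so THQ and TCR reduce to simple closed forms; the identities are
asserted in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

METALS = ("Hg", "Cd", "As", "Pb", "Cr")
CARCINOGENIC_METALS = ("Cd", "As", "Pb", "Cr")


@dataclass(frozen=True)
class ToxicologyTable:
    """Per-metal regulatory limits, reference doses, slope factors and exposure constants."""

    limit_mg_per_kg: Mapping[str, float]
    rfd_mg_per_kg_day: Mapping[str, float]
    csf_kg_day_per_mg: Mapping[str, float]
    ef_days_per_year: float = 365.0
    ed_years: float = 70.0
    body_weight_kg: float = 60.0
    atc_years: float = 70.0
    metals: tuple[str, ...] = field(default=METALS)

    @property
    def at_days(self) -> float:
        """Non-carcinogenic averaging time AT = 365 d/yr x ED."""
        return 365.0 * self.ed_years

    @property
    def atc_days(self) -> float:
        """Carcinogenic averaging time ATC = 365 d/yr x assumed 70-yr exposure."""
        return 365.0 * self.atc_years

    def __post_init__(self) -> None:
        for metal in self.metals:
            if self.limit_mg_per_kg[metal] <= 0:
                raise ValueError(f"non-positive limit for {metal}")
            if self.rfd_mg_per_kg_day[metal] <= 0:
                raise ValueError(f"non-positive RfD for {metal}")
        if "Hg" in self.csf_kg_day_per_mg:
            raise ValueError("Hg has no cancer slope factor; it must not appear in the CSF table")
        for metal, csf in self.csf_kg_day_per_mg.items():
            if csf <= 0:
                raise ValueError(f"non-positive CSF for {metal}")


def load_toxicology(path: str | None = None) -> ToxicologyTable:
    """Load the toxicology table from ``path`` or the packaged default resource."""
    if path is None:
        raw = resources.files("wheatrisk.data").joinpath("toxicology.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = json.loads(raw)
    return ToxicologyTable(
        limit_mg_per_kg=doc["limit_mg_per_kg"],
        rfd_mg_per_kg_day=doc["rfd_mg_per_kg_day"],
        csf_kg_day_per_mg=doc["csf_kg_day_per_mg"],
        ef_days_per_year=float(doc.get("ef_days_per_year", 365.0)),
        ed_years=float(doc.get("ed_years", 70.0)),
        body_weight_kg=float(doc.get("body_weight_kg", 60.0)),
        atc_years=float(doc.get("atc_years", 70.0)),
        metals=tuple(doc.get("metals", METALS)),
    )
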