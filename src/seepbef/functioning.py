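"""Ecosystem-functioning proxies: density, standing stock, BPc, calcification.

Community bioturbation potential follows the index of Queiros et al.::

    BPc = sum_i  B_i/A_i x A_i x M_i x R_i

summed over families i, where A_i is family abundance, M_i and R_i are
ordinal mobility and sediment-reworking scores, and B_i/A_i (mean
individual biomass of the family) is replaced by the sample-wide mean
individual biomass because family-level biomass is typically not
recorded in blind-sorted samples.  The original index uses
sqrt(B_i/A_i); both variants are available via ``variant`` and the
plain mean-biomass form (no square root) is the default.

Calcification degree is the abundance-weighted sum of 0-5 family
calcification scores, a semi-quantitative proxy for biogenic carbonate
standing stock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FamilyParams",
    "sampled_area",
    "density_per_m2",
    "biomass_per_m2",
    "bpc",
    "calcification_index",
    "load_family_registry",
    "family_param_fallback",
    "functioning_table",
]


@dataclass(frozen=True)
class FamilyParams:
    """Per-family scores: mobility Mi, reworking Ri, calcification 0-5."""

    family: str
    mi: float
    ri: float
    calc_score: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.mi <= 0 or self.ri <= 0:
            raise ValueError(f"{self.family}: Mi and Ri must be positive")
        if not 0 <= self.calc_score <= 5:
            raise ValueError(f"{self.family}: calcification score must be in [0, 5]")


def sampled_area(n_cores: int, internal_diameter_m: float) -> float:
    """Total seafloor area (m^2) of ``n_cores`` circular push cores."""
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    if internal_diameter_m <= 0:
        raise ValueError("core diameter must be positive")
    return n_cores * math.pi * (internal_diameter_m / 2.0) ** 2


def density_per_m2(total_count: float, area_m2: float) -> float:
    """Faunal density, individuals per square metre."""
    if area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    if total_count < 0:
        raise ValueError("count must be non-negative")
    return total_count / area_m2


def biomass_per_m2(total_wet_biomass_g: float, area_m2: float) -> float:
    """Standing stock, g wet weight per square metre."""
    if area_m2 <= 0:
        raise ValueError("sampled area must be positive")
    if total_wet_biomass_g < 0:
        raise ValueError("biomass must be non-negative")
    return total_wet_biomass_g / area_m2


def _lookup(params: dict[str, FamilyParams], family: str) -> FamilyParams:
    try:
        return params[family]
    except KeyError:
        raise KeyError(f"no parameters registered for family {family!r}") from None


def bpc(
    family_abundances: dict[str, float] | pd.Series,
    mean_individual_biomass_g: float,
    params: dict[str, FamilyParams],
    variant: str = "plain",
) -> float:
    """Community bioturbation potential.

    ``variant='plain'`` uses mean individual biomass m directly
    (BPc = sum m * A_i * M_i * R_i); ``variant='sqrt'`` uses sqrt(m)
    as in the original Queiros formulation.
    """
    if mean_individual_biomass_g < 0:
        raise ValueError("mean individual biomass must be non-negative")
    if variant not in ("plain", "sqrt"):
        raise ValueError(f"unknown BPc variant {variant!r}")
    m = mean_individual_biomass_g
    if variant == "sqrt":
        m = math.sqrt(m)
    total = 0.0
    for family, a in dict(family_abundances).items():
        if a < 0:
            raise ValueError(f"negative abundance for family {family!r}")
        if a == 0:
            continue
        p = _lookup(params, family)
        total += m * a * p.mi * p.ri
    return total


def calcification_index(
    family_abundances: dict[str, float] | pd.Series,
    params: dict[str, FamilyParams],
) -> float:
    """Abundance-weighted calcification degree: sum score_f * A_f."""
    total = 0.0
    for family, a in dict(family_abundances).items():
        if a < 0:
            raise ValueError(f"negative abundance for family {family!r}")
        if a == 0:
            continue
        total += _lookup(params, family).calc_score * a
    return total


def load_family_registry(path=None) -> pd.DataFrame:
    """Load a family parameter registry CSV.

    Expected columns: family, species (may be blank for family-level
    entries), mi, ri, calc_score, provenance.  Without ``path`` the
    synthetic registry shipped with the package is used (the published
    family-score datasets are not openly deposited; the shipped table is
    a synthetic stand-in with plausible score ranges).
    """
    if path is None:
        ref = resources.files("seepbef.data") / "family_params_synthetic.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def family_param_fallback(
    family: str,
    registry: pd.DataFrame,
    default_policy: str = "error",
    default: FamilyParams | None = None,
) -> FamilyParams:
    """Resolve one family's parameters from a registry table.

    Species-level rows for the family are averaged (arithmetic mean of
    Mi, Ri and calcification score).  An absent family raises under
    ``default_policy='error'`` or returns ``default`` under
    ``default_policy='default'``.
    """
    rows = registry[registry["family"] == family]
    if len(rows) == 0:
        if default_policy == "error":
            raise KeyError(f"family {family!r} absent from the parameter registry")
        if default_policy == "default":
            if default is None:
                raise ValueError("default_policy='default' requires a default FamilyParams")
            return default
        raise ValueError(f"unknown default_policy {default_policy!r}")
    prov = "queiros-mean" if len(rows) > 1 else str(rows["provenance"].iloc[0])
    return FamilyParams(
        family=family,
        mi=float(rows["mi"].mean()),
        ri=float(rows["ri"].mean()),
        calc_score=float(rows["calc_score"].mean()),
        provenance=prov,
    )


def functioning_table(
    abundance,
    sample_biomass_g: pd.Series,
    params: dict[str, FamilyParams],
    n_cores: int = 2,
    core_diameter_m: float = 0.064,
    bpc_variant: str = "plain",
) -> pd.DataFrame:
    """Per-sample functioning proxies (density, biomass, BPc, calcification).

    ``abundance`` is an :class:`~seepbef.biodiversity.AbundanceMatrix`;
    ``sample_biomass_g`` gives total wet biomass per sample.  Density and
    biomass are scaled to the pooled core area (default two 6.4 cm cores
    per sample).
    """
    area = sampled_area(n_cores, core_diameter_m)
    fam_counts = abundance.family_abundance()
    rows = {}
    for sample in abundance.samples:
        fa = fam_counts.loc[sample]
        n = float(fa.sum())
        biomass = float(sample_biomass_g.loc[sample])
        mean_ind = biomass / n if n > 0 else 0.0
        rows[sample] = {
            "density": density_per_m2(n, area),
            "biomass": biomass_per_m2(biomass, area),
            "bpc": bpc(fa, mean_ind, params, variant=bpc_variant),
            "calcification": calcification_index(fa, params),
            "area_m2": area,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
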