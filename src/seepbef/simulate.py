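"""Synthetic seep-gradient communities with known BEF ground truth.

The study design being emulated: 38 push-core samples along a methane
seep activity gradient (13 active seep, 13 transitional chemotone, 12
background sediment; two 6.4 cm cores per sample), with denser, more
dominance-skewed communities at active seeps and seep-specialist taxa
restricted to active/transition habitat.

Each sample's species relative abundances are drawn from a Dirichlet
over its habitat's species pool (lower concentration = stronger
dominance), and the total count is Poisson with a log-mean equal to the
habitat density level plus a configurable function of the sample's
latent diversity — this is how a chosen biodiversity-functioning
relationship (null / linear / unimodal / accelerating / saturating) is
imposed per habitat, with effect size expressed as signal sd over noise
sd on the log scale.  Ground truth (form labels and per-sample latent
signal) is recorded for recovery tests.

The generator deliberately treats samples as exchangeable within
habitat: within-habitat spatial autocorrelation of communities is not
simulated (it is not characterized in the field setting emulated here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biodiversity import AbundanceMatrix
from .environment import Grid, write_ascii_grid
from .functioning import FamilyParams

__all__ = [
    "TRAIT_CATALOG",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_bathymetry",
    "write_dataset",
]

BEF_FORMS = ("null", "linear", "unimodal", "accelerating", "saturating")
HABITATS = ("active", "transition", "background")

# Synthetic stand-in trait catalog: 32 functional traits in 7 groupings,
# scored 0-5 at family level.  The trait names are invented placeholders
# with the structure (sizes, feeding modes, mobility, bioturbation
# modes, sediment position, reproduction, protection/calcification)
# a benthic trait analysis would use.
TRAIT_CATALOG: dict[str, tuple[str, ...]] = {
    "size": ("sz_small", "sz_medium", "sz_large", "sz_xlarge"),
    "feeding": ("fd_suspension", "fd_surface_deposit", "fd_subsurface_deposit",
                "fd_predator", "fd_scavenger", "fd_chemosymbiotic"),
    "mobility": ("mb_sessile", "mb_crawler", "mb_burrower", "mb_swimmer"),
    "bioturbation": ("bt_none", "bt_surficial", "bt_upward_conveyor",
                     "bt_downward_conveyor", "bt_biodiffusor"),
    "position": ("ps_epifauna", "ps_shallow_infauna", "ps_mid_infauna", "ps_deep_infauna"),
    "reproduction": ("rp_broadcast", "rp_brooder", "rp_lecithotrophic", "rp_planktotrophic"),
    "protection": ("pr_soft", "pr_tube", "pr_chitinous", "pr_calc_partial", "pr_calc_full"),
}
assert sum(len(v) for v in TRAIT_CATALOG.values()) == 32


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the emulated sampling design."""

    n_active: int = 13
    n_transition: int = 13
    n_background: int = 12
    species_pool_size: int = 60
    n_families: int = 20
    habitat_density_multipliers: dict = field(
        default_factory=lambda: {"active": 5.0, "transition": 2.0, "background": 1.0})
    dominance: dict = field(
        default_factory=lambda: {"active": 0.12, "transition": 0.25, "background": 0.5})
    bef_form: dict = field(
        default_factory=lambda: {"active": "unimodal", "transition": "null",
                                 "background": "null"})
    bef_effect_size: float = 2.0   # signal sd / noise sd on the log-density scale
    noise_sd: float = 0.3          # lognormal noise sd on total density
    base_mean_count: float = 80.0  # background-habitat mean total count per sample
    specialist_fraction: float = 0.3  # species restricted to active/transition
    seed: int = 0
    cores_per_sample: int = 2
    core_diameter_m: float = 0.064

    def __post_init__(self) -> None:
        for name in ("n_active", "n_transition", "n_background",
                     "species_pool_size", "n_families", "cores_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.species_pool_size < self.n_families:
            raise ValueError("species_pool_size must be >= n_families")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.bef_effect_size < 0:
            raise ValueError("bef_effect_size must be non-negative")
        for hab in HABITATS:
            if self.habitat_density_multipliers[hab] <= 0:
                raise ValueError("density multipliers must be positive")
            if self.dominance[hab] <= 0:
                raise ValueError("Dirichlet concentrations must be positive")
            if self.bef_form[hab] not in BEF_FORMS:
                raise ValueError(
                    f"unknown BEF form {self.bef_form[hab]!r}; pick one of {BEF_FORMS}")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    form: dict                       # habitat -> form label
    effect_size: float
    noise_sd: float
    latent_biodiversity: pd.Series   # per sample, habitat-standardized
    latent_functioning: pd.Series    # per sample log-scale signal, before noise
    peak: dict                       # habitat -> latent-diversity value of the
                                     # interior extremum (unimodal forms only)


@dataclass
class SyntheticDataset:
    config: SimConfig
    abundance: AbundanceMatrix
    family_params: dict[str, FamilyParams]
    traits: pd.DataFrame             # family x 32 trait scores
    samples: pd.DataFrame            # sample, activity, x, y, biomass_g
    env_points: pd.DataFrame         # x, y, variable, value, source
    npp_monthly: pd.DataFrame        # month, npp
    bathymetry: Grid
    truth: SyntheticTruth


def _stream(seed: int, name: str) -> np.random.Generator:
    codes = {"families": 11, "species": 12, "community": 13, "biomass": 14,
             "environment": 15, "bathymetry": 16}
    return np.random.default_rng([seed % 2**31, codes[name]])


def _form_function(form: str, z: np.ndarray) -> np.ndarray:
    """Raw generating shapes on a habitat-standardized diversity axis."""
    if form == "null":
        return np.zeros_like(z)
    if form == "linear":
        return z
    if form == "unimodal":
        return -(z**2)
    if form == "accelerating":
        return np.exp(z)
    if form == "saturating":
        zz = z - z.min()
        return zz / (1.0 + zz)
    raise ValueError(form)


def generate_bathymetry(nx: int, ny: int, cell_size_m: float = 1.0,
                        roughness: float = 5.0, seed: int = 0,
                        base_depth_m: float = 1000.0) -> Grid:
    """Synthetic single-band depth grid (m, positive down).

    A smooth regional depth gradient plus band-limited random relief;
    ``roughness`` scales the whole non-constant part, so roughness=0
    yields a constant-depth grid.
    """
    if nx < 3 or ny < 3:
        raise ValueError("grid must be at least 3x3")
    rng = _stream(seed, "bathymetry")
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    gradient = 0.5 * (xx / max(nx - 1, 1)) + 0.2 * (yy / max(ny - 1, 1))
    noise = rng.normal(size=(ny, nx))
    # cheap smoothing: three passes of a 3x3 box filter with edge padding
    for _ in range(3):
        padded = np.pad(noise, 1, mode="edge")
        noise = sum(padded[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx]
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)) / 9.0
    relief = gradient * 10.0 + noise
    return Grid(base_depth_m + roughness * relief, cell_size_m)


def _draw_family_table(cfg: SimConfig) -> tuple[dict[str, FamilyParams], pd.DataFrame]:
    rng = _stream(cfg.seed, "families")
    fams = [f"F{i + 1:02d}" for i in range(cfg.n_families)]
    params = {}
    trait_names = [t for grp in TRAIT_CATALOG.values() for t in grp]
    scores = np.zeros((cfg.n_families, 32), dtype=int)
    for i, fam in enumerate(fams):
        params[fam] = FamilyParams(
            family=fam,
            mi=int(rng.integers(1, 5)),
            ri=int(rng.integers(1, 6)),
            calc_score=int(rng.integers(0, 6)),
            provenance="synthetic",
        )
        # sparse fuzzy coding: most families associate with a minority of
        # traits, so per-sample trait richness varies realistically
        present = rng.random(32) < 0.2
        scores[i] = np.where(present, rng.integers(1, 6, size=32), 0)
    traits = pd.DataFrame(scores, index=pd.Index(fams, name="family"), columns=trait_names)
    return params, traits


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one complete synthetic dataset. Deterministic given the seed."""
    cfg = config
    family_params, traits = _draw_family_table(cfg)
    fams = list(traits.index)

    rng_sp = _stream(cfg.seed, "species")
    species = [f"sp{i + 1:03d}" for i in range(cfg.species_pool_size)]
    # every family gets at least one species; the rest are assigned at random
    assignment = fams + list(rng_sp.choice(fams, size=cfg.species_pool_size - len(fams)))
    rng_sp.shuffle(assignment)
    species_family = dict(zip(species, assignment))
    n_specialists = int(round(cfg.specialist_fraction * cfg.species_pool_size))
    specialist = np.zeros(cfg.species_pool_size, dtype=bool)
    specialist[rng_sp.choice(cfg.species_pool_size, size=n_specialists, replace=False)] = True

    sample_ids, habitats = [], []
    for hab, n in (("active", cfg.n_active), ("transition", cfg.n_transition),
                   ("background", cfg.n_background)):
        for i in range(n):
            sample_ids.append(f"{hab[:3].upper()}{i + 1:02d}")
            habitats.append(hab)
    habitats = np.array(habitats)

    rng = _stream(cfg.seed, "community")
    counts = np.zeros((len(sample_ids), cfg.species_pool_size), dtype=int)
    latent_div = np.full(len(sample_ids), np.nan)
    latent_fun = np.full(len(sample_ids), np.nan)
    peaks: dict[str, float] = {}

    for hab in HABITATS:
        rows = np.where(habitats == hab)[0]
        pool = np.ones(cfg.species_pool_size, dtype=bool)
        if hab == "background":
            pool &= ~specialist
        alpha = np.full(pool.sum(), cfg.dominance[hab])
        p = rng.dirichlet(alpha, size=len(rows))
        shan = -np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0), axis=1)
        z = (shan - shan.mean()) / (shan.std(ddof=1) if len(rows) > 1 else 1.0)
        raw = _form_function(cfg.bef_form[hab], z)
        sd = raw.std(ddof=1)
        signal = np.zeros_like(raw) if sd == 0 else \
            (raw - raw.mean()) / sd * cfg.bef_effect_size * cfg.noise_sd
        # center on the exp scale so habitat mean density obeys the multiplier
        signal -= np.log(np.mean(np.exp(signal)))
        if cfg.bef_form[hab] == "unimodal":
            peaks[hab] = 0.0  # peak sits at mean latent diversity by construction
        log_mu = (np.log(cfg.base_mean_count * cfg.habitat_density_multipliers[hab])
                  + signal + cfg.noise_sd * rng.normal(size=len(rows)))
        totals = rng.poisson(np.exp(log_mu))
        for j, row in enumerate(rows):
            counts[row, pool] = rng.multinomial(totals[j], p[j])
        latent_div[rows] = z
        latent_fun[rows] = signal

    abundance = AbundanceMatrix(
        pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample"), columns=species),
        species_family,
    )

    # wet biomass: lognormal individual body mass per family
    rng_b = _stream(cfg.seed, "biomass")
    fam_mass = {f: float(np.exp(rng_b.normal(np.log(0.005), 0.5))) for f in fams}
    biomass = np.zeros(len(sample_ids))
    for i in range(len(sample_ids)):
        for j, sp in enumerate(species):
            nij = counts[i, j]
            if nij > 0:
                biomass[i] += nij * fam_mass[species_family[sp]] * float(
                    np.exp(rng_b.normal(0.0, 0.2)))

    # environment: bathymetry grid, scattered CTD-style points, monthly NPP
    rng_e = _stream(cfg.seed, "environment")
    bathy = generate_bathymetry(60, 60, cell_size_m=1.0, roughness=2.0, seed=cfg.seed)
    extent = 60.0
    xy = rng_e.uniform(2.0, extent - 2.0, size=(len(sample_ids), 2))
    env_rows = []
    n_pts = 25
    pts = rng_e.uniform(0.5, extent - 0.5, size=(n_pts, 2))
    depth_at = [bathy.values[bathy.cell_index(x, y)] for x, y in pts]
    for (x, y), d in zip(pts, depth_at):
        env_rows.append((x, y, "temperature", 4.0 - 0.001 * d + rng_e.normal(0, 0.05), "auv"))
        env_rows.append((x, y, "salinity", 34.6 + rng_e.normal(0, 0.01), "auv"))
        env_rows.append((x, y, "oxygen", 20.0 + 0.01 * d + rng_e.normal(0, 0.5), "auv"))
    env_points = pd.DataFrame(env_rows, columns=["x", "y", "variable", "value", "source"])
    month = np.arange(1, 13)
    npp = 350.0 + 150.0 * np.sin(2 * np.pi * (month - 3) / 12.0) + rng_e.normal(0, 10, 12)
    npp_monthly = pd.DataFrame({"month": month, "npp": np.maximum(npp, 0.0)})

    samples = pd.DataFrame({
        "sample": sample_ids,
        "activity": habitats,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "biomass_g": biomass,
    }).set_index("sample")

    truth = SyntheticTruth(
        form=dict(cfg.bef_form),
        effect_size=cfg.bef_effect_size,
        noise_sd=cfg.noise_sd,
        latent_biodiversity=pd.Series(latent_div, index=sample_ids, name="latent_biodiversity"),
        latent_functioning=pd.Series(latent_fun, index=sample_ids, name="latent_functioning"),
        peak=peaks,
    )
    return SyntheticDataset(
        config=cfg, abundance=abundance, family_params=family_params, traits=traits,
        samples=samples, env_points=env_points, npp_monthly=npp_monthly,
        bathymetry=bathy, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the CSV/ASC schemas the pipeline reads, plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    long = (
        ds.abundance.counts.stack()
        .rename("count").rename_axis(["sample", "species"]).reset_index()
    )
    long = long[long["count"] > 0]
    long.to_csv(out / "abundance.csv", index=False)
    pd.DataFrame({
        "species": list(ds.abundance.species_family),
        "family": list(ds.abundance.species_family.values()),
    }).to_csv(out / "families.csv", index=False)
    grouping_of = {t: g for g, ts in TRAIT_CATALOG.items() for t in ts}
    (ds.traits.stack().rename("score").rename_axis(["family", "trait"]).reset_index()
     .assign(grouping=lambda d: d["trait"].map(grouping_of))
     [["family", "trait", "grouping", "score"]]
     .to_csv(out / "traits.csv", index=False))
    pd.DataFrame([
        {"family": p.family, "mi": p.mi, "ri": p.ri, "calc_score": p.calc_score,
         "provenance": p.provenance}
        for p in ds.family_params.values()
    ]).to_csv(out / "family_params.csv", index=False)
    ds.samples.reset_index().to_csv(out / "samples.csv", index=False)
    ds.env_points.to_csv(out / "env_points.csv", index=False)
    ds.npp_monthly.to_csv(out / "npp_monthly.csv", index=False)
    write_ascii_grid(ds.bathymetry, out / "bathymetry.asc")
    truth = {
        "form": ds.truth.form,
        "effect_size": ds.truth.effect_size,
        "noise_sd": ds.truth.noise_sd,
        "peak": ds.truth.peak,
        "latent_biodiversity": ds.truth.latent_biodiversity.to_dict(),
        "latent_functioning": ds.truth.latent_functioning.to_dict(),
        "config": {k: v for k, v in asdict(ds.config).items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
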