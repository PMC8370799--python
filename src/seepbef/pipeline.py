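"""End-to-end orchestration: inputs -> proxies -> PCA -> GAM -> shape calls.

The stages compose in the fixed analysis order: biodiversity metrics and
functioning proxies from the abundance/trait/biomass inputs,
environmental covariates from point measurements and the bathymetry
grid, standardization + 0-imputation + per-grouping PCA, then
habitat-stratified GAMs (one per functioning axis x biodiversity
grouping) with backward selection and relationship-shape
classification.  Every run is reproducible: the only randomness lives
in the synthetic generator's seed, and outputs are hashed into a
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biodiversity import AbundanceMatrix, biodiversity_table
from .environment import (
    Grid, annual_npp, export_flux, extract_at_samples, interpolate_to_grid,
    read_ascii_grid, slope_grid, tpi_grid, tri_grid,
)
from .functioning import FamilyParams, functioning_table
from .gam import backward_select, bef_spec, classify_shape, fit_gam, select_family_link, select_knots, smooth_estimate
from .reduce import DEFAULT_GROUPINGS, reduce_groupings
from .simulate import SimConfig, SyntheticDataset, generate_dataset, write_dataset

__all__ = [
    "RunConfig",
    "load_dataset",
    "validate_inputs",
    "build_variable_table",
    "run_bef_models",
    "run_pipeline",
]

DEFAULT_MODELS: tuple[tuple[str, str], ...] = (
    ("functioning_PC1", "taxonomic_biodiversity"),
    ("functioning_PC1", "trait_biodiversity"),
    ("functioning_PC2", "taxonomic_biodiversity"),
    ("functioning_PC2", "trait_biodiversity"),
)


@dataclass
class RunConfig:
    """One pipeline run: either a data directory or a simulation config."""

    input_dir: str | None = None
    sim: SimConfig | None = None
    out_dir: str = "seepbef_out"
    models: tuple[tuple[str, str], ...] = DEFAULT_MODELS
    alpha: float = 0.05
    aic_tol: float = 2.0
    k: int = 4  # small default basis: ~12-13 samples per habitat level
    select_family: bool = False
    select_k: bool = False
    k_candidates: tuple[int, ...] = (4, 5, 6)
    interpolation: str = "idw"
    npp_convention: str = "totals"
    lutz: dict = field(default_factory=lambda: {"prd": 0.4, "rld": 400.0, "prr": 0.01})
    bpc_variant: str = "plain"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("exactly one of input_dir or sim must be given")


def load_dataset(indir) -> SyntheticDataset:
    """Load a dataset directory written in the pipeline's CSV/ASC schemas."""
    d = Path(indir)
    fam_map = pd.read_csv(d / "families.csv")
    species_family = dict(zip(fam_map["species"], fam_map["family"]))
    samples = pd.read_csv(d / "samples.csv").set_index("sample")
    abundance = AbundanceMatrix.from_long(pd.read_csv(d / "abundance.csv"), species_family)
    # species never observed still belong to the pool; samples with no
    # individuals still belong to the design
    for sp in species_family:
        if sp not in abundance.counts.columns:
            abundance.counts[sp] = 0
    abundance.counts = abundance.counts.reindex(samples.index, fill_value=0)
    traits_long = pd.read_csv(d / "traits.csv")
    traits = traits_long.pivot(index="family", columns="trait", values="score")
    fp = pd.read_csv(d / "family_params.csv")
    family_params = {
        r.family: FamilyParams(r.family, float(r.mi), float(r.ri), float(r.calc_score),
                               str(getattr(r, "provenance", "unspecified")))
        for r in fp.itertuples()
    }
    env_points = pd.read_csv(d / "env_points.csv")
    npp_monthly = pd.read_csv(d / "npp_monthly.csv")
    bathy = read_ascii_grid(d / "bathymetry.asc")
    return SyntheticDataset(
        config=None, abundance=abundance, family_params=family_params, traits=traits,
        samples=samples, env_points=env_points, npp_monthly=npp_monthly,
        bathymetry=bathy, truth=None,
    )


def validate_inputs(indir) -> dict:
    """Schema/content validation of a dataset directory.

    Returns ``{"ok": bool, "errors": [...], "checked": [...]}`` with
    file- and row-level messages rather than raising.
    """
    d = Path(indir)
    errors: list[str] = []
    checked: list[str] = []

    required = ["abundance.csv", "families.csv", "traits.csv", "family_params.csv",
                "samples.csv", "env_points.csv", "npp_monthly.csv", "bathymetry.asc"]
    for name in required:
        if not (d / name).exists():
            errors.append(f"{name}: missing input file")
    if errors:
        return {"ok": False, "errors": errors, "checked": checked}

    ab = pd.read_csv(d / "abundance.csv")
    checked.append("abundance.csv")
    bad = ab[ab["count"] < 0]
    for _, r in bad.iterrows():
        errors.append(f"abundance.csv: negative count for sample {r['sample']} species {r['species']}")

    fam = pd.read_csv(d / "families.csv")
    checked.append("families.csv")
    orphan = set(ab["species"]) - set(fam["species"])
    for sp in sorted(orphan):
        errors.append(f"families.csv: species {sp!r} has no family mapping")

    tr = pd.read_csv(d / "traits.csv")
    checked.append("traits.csv")
    bad = tr[(tr["score"] < 0) | (tr["score"] > 5)]
    for _, r in bad.iterrows():
        errors.append(f"traits.csv: score {r['score']} out of [0,5] for trait {r['trait']!r} "
                      f"family {r['family']!r}")
    unmapped = set(fam["family"]) - set(tr["family"])
    for f in sorted(unmapped):
        errors.append(f"traits.csv: family {f!r} has no trait scores")

    npp = pd.read_csv(d / "npp_monthly.csv")
    checked.append("npp_monthly.csv")
    if len(npp) != 12:
        errors.append(f"npp_monthly.csv: expected 12 monthly rows, found {len(npp)}")
    if (npp["npp"] < 0).any():
        errors.append("npp_monthly.csv: negative NPP value")

    try:
        read_ascii_grid(d / "bathymetry.asc")
        checked.append("bathymetry.asc")
    except ValueError as err:
        errors.append(f"bathymetry.asc: {err}")

    return {"ok": not errors, "errors": errors, "checked": checked}


def build_variable_table(ds: SyntheticDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Assemble the per-sample raw variable table (proxies, diversity, environment)."""
    cfg = config or RunConfig(sim=SimConfig())
    biodiv = biodiversity_table(ds.abundance, ds.traits)
    n_cores = ds.config.cores_per_sample if ds.config is not None else 2
    diam = ds.config.core_diameter_m if ds.config is not None else 0.064
    fun = functioning_table(
        ds.abundance, ds.samples["biomass_g"], ds.family_params,
        n_cores=n_cores, core_diameter_m=diam, bpc_variant=cfg.bpc_variant,
    ).drop(columns=["area_m2"])

    coords = ds.samples[["x", "y"]]
    grids: dict[str, Grid] = {"depth": ds.bathymetry}
    for var in sorted(ds.env_points["variable"].unique()):
        pts = ds.env_points[ds.env_points["variable"] == var]
        grids[var] = interpolate_to_grid(pts, ds.bathymetry, method=cfg.interpolation)
    grids["slope"] = slope_grid(ds.bathymetry)
    grids["tri"] = tri_grid(ds.bathymetry)
    grids["tpi"] = tpi_grid(ds.bathymetry)
    env = extract_at_samples(grids, coords)
    npp_year = annual_npp(ds.npp_monthly["npp"].to_numpy(), convention=cfg.npp_convention)
    env["export_flux"] = [export_flux(npp_year, z, **cfg.lutz) for z in env["depth"]]

    table = fun.join(biodiv).join(env)
    table["activity"] = ds.samples["activity"]
    return table


def _drop_degenerate_by_smooths(spec, design: pd.DataFrame, max_corr: float = 0.99):
    """Remove by-habitat smooths that are unidentifiable within their group.

    PCA axes are orthogonal over all samples but can collapse onto one
    line *within* a habitat subgroup (e.g. when trait richness is almost
    constant there); a smooth of the lower-variance axis then duplicates
    the other smooth's information and makes the model rank-deficient.
    Such smooths are dropped before fitting, which downstream shape
    classification reports as a null call for that habitat/axis.
    """
    kept: list = []
    seen: dict[str, list[str]] = {}
    for term in spec.smooths:
        if term.by is None:
            kept.append(term)
            continue
        sub = design.loc[design[spec.factor].astype(str) == term.by, term.covariate]
        if sub.std(ddof=1) < 1e-10:
            continue
        degenerate = any(
            abs(np.corrcoef(sub, design.loc[design[spec.factor].astype(str) == term.by,
                                            prev])[0, 1]) > max_corr
            for prev in seen.get(term.by, ())
        )
        if degenerate:
            continue
        seen.setdefault(term.by, []).append(term.covariate)
        kept.append(term)
    return replace(spec, smooths=tuple(kept))


def run_bef_models(
    design: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Fit, select and classify every configured (response, biodiversity) model.

    Returns the term table (edf/F/p per retained term), the per-habitat
    shape calls, the gridded smooth estimates, and the fitted models.
    """
    levels = tuple(sorted(design["activity"].unique()))
    term_rows, shape_rows, smooth_rows = [], [], []
    fits = {}
    for response, biodiv in config.models:
        spec = bef_spec(response, biodiv, levels=levels, k=config.k)
        spec = _drop_degenerate_by_smooths(spec, design)
        if config.select_family:
            fam, link, _ = select_family_link(
                (("gaussian", "identity"), ("gamma", "log")), spec, design)
            spec = replace(spec, family=fam, link=link)
        if config.select_k:
            spec, _ = select_knots(spec, design, config.k_candidates)
        full = fit_gam(spec, design)
        fit, trace = backward_select(full, design, alpha=config.alpha, aic_tol=config.aic_tol)
        fits[(response, biodiv)] = {"full": full, "final": fit, "trace": trace}
        for _, row in fit.terms.iterrows():
            term_rows.append({"response": response, "model": biodiv, **row.to_dict(),
                              "adj_r2": fit.adj_r2, "aic": fit.aic})
        for axis in ("PC1", "PC2"):
            cov = f"{biodiv}_{axis}"
            for lev in levels:
                term = f"s({cov}):{lev}"
                call = classify_shape(fit, term)
                p = fit.term_p(term) if fit.has_term(term) else float("nan")
                shape_rows.append({
                    "response": response, "covariate": cov, "habitat": lev,
                    "shape": call.label, "extremum": call.extremum, "p": p,
                })
                if fit.has_term(term):
                    sm = smooth_estimate(fit, term)
                    sm.insert(0, "term", term)
                    sm.insert(0, "response", response)
                    smooth_rows.append(sm)
    terms = pd.DataFrame(term_rows)
    shapes = pd.DataFrame(shape_rows)
    smooths = pd.concat(smooth_rows, ignore_index=True) if smooth_rows else pd.DataFrame()
    return terms, shapes, smooths, fits


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes outputs + manifest.json, returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.sim is not None:
        ds = generate_dataset(config.sim)
    else:
        report = validate_inputs(config.input_dir)
        if not report["ok"]:
            raise ValueError("input validation failed:\n" + "\n".join(report["errors"]))
        ds = load_dataset(config.input_dir)

    table = build_variable_table(ds, config)
    biodiv_cols = [c for c in table.columns if c.startswith(("species_", "trait_"))]
    fun_cols = ["density", "biomass", "bpc", "calcification"]
    table[fun_cols].to_csv(out / "functioning.csv")
    table[biodiv_cols].to_csv(out / "biodiversity.csv")
    env_cols = [c for c in table.columns
                if c not in fun_cols + biodiv_cols + ["activity"]]
    table[env_cols].to_csv(out / "env.csv")

    design, bundles = reduce_groupings(table, DEFAULT_GROUPINGS)
    design["activity"] = table["activity"]
    design.rename_axis("sample").to_csv(out / "pca_scores.csv")
    pd.concat(
        {name: b.loadings for name, b in bundles.items()}, names=["grouping", "variable"]
    ).to_csv(out / "pca_loadings.csv")
    pd.DataFrame([
        {"grouping": name,
         **{f"PC{i + 1}_pct": 100.0 * v for i, v in enumerate(b.variance_fraction)}}
        for name, b in bundles.items()
    ]).to_csv(out / "pca_variance.csv", index=False)

    terms, shapes, smooths, _ = run_bef_models(design, config)
    terms.to_csv(out / "terms.csv", index=False)
    shapes.to_csv(out / "shapes.csv", index=False)
    smooths.to_csv(out / "smooths.csv", index=False)

    outputs = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "seepbef_version": __version__,
        "seed": config.seed if config.sim is None else ds.config.seed,
        "n_samples": int(len(table)),
        "models": [list(m) for m in config.models],
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
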