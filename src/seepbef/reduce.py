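"""Standardization, mean-imputation and per-grouping PCA.

The fixed preprocessing order is: z-score every continuous variable,
replace missing values with 0 (the variable's mean on the standardized
scale), then reduce each variable grouping to its leading principal
components.  Groupings and the number of retained components follow the
analysis design: functioning proxies (2 PCs), taxonomic biodiversity
(2), trait biodiversity (2), oceanographic (2), terrain (1); the terrain
position index enters the downstream model unreduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "DEFAULT_GROUPINGS",
    "VariableGrouping",
    "PCABundle",
    "standardize",
    "standardize_table",
    "impute_missing",
    "pca",
    "orient_axes",
    "reduce_groupings",
]


@dataclass(frozen=True)
class VariableGrouping:
    name: str
    variables: tuple[str, ...]
    n_components: int


DEFAULT_GROUPINGS: tuple[VariableGrouping, ...] = (
    VariableGrouping("functioning", ("bpc", "calcification", "density", "biomass"), 2),
    VariableGrouping(
        "taxonomic_biodiversity",
        ("species_richness", "species_shannon", "species_pielou"), 2),
    VariableGrouping(
        "trait_biodiversity",
        ("trait_richness", "trait_shannon", "trait_pielou"), 2),
    VariableGrouping(
        "oceanographic",
        ("depth", "temperature", "salinity", "oxygen", "export_flux"), 2),
    VariableGrouping("terrain", ("tri", "slope"), 1),
    VariableGrouping("terrain_position_index", ("tpi",), 0),
)


@dataclass
class PCABundle:
    """Loadings, scores and variance fractions of one grouping's PCA."""

    loadings: pd.DataFrame        # variables x components
    scores: pd.DataFrame          # samples x components
    variance_fraction: np.ndarray  # all components, sums to 1
    flipped: list[str] = field(default_factory=list)


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores with sample (n-1) standard deviation; NaN passes through."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("standardization needs at least 2 observed values")
    sd = np.std(x[ok], ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    out = x.copy()
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def standardize_table(table: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in table.columns:
        try:
            out[col] = standardize(table[col].to_numpy(dtype=float))
        except ValueError as err:
            raise ValueError(f"variable {col!r}: {err}") from None
    return pd.DataFrame(out, index=table.index)


def impute_missing(z_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing standardized values with 0; returns (table, count)."""
    n_missing = int(z_table.isna().to_numpy().sum())
    return z_table.fillna(0.0), n_missing


def pca(grouping_table: pd.DataFrame) -> PCABundle:
    """Full PCA of a standardized samples x variables table (SVD-based)."""
    if grouping_table.shape[0] < 2 or grouping_table.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples and 2 variables")
    model = PCA(n_components=min(grouping_table.shape), svd_solver="full")
    scores = model.fit_transform(grouping_table.to_numpy(dtype=float))
    comps = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCABundle(
        loadings=pd.DataFrame(model.components_.T, index=grouping_table.columns, columns=comps),
        scores=pd.DataFrame(scores, index=grouping_table.index, columns=comps),
        variance_fraction=model.explained_variance_ratio_,
    )


def orient_axes(bundle: PCABundle) -> PCABundle:
    """Fix each component's sign: its largest-|loading| variable loads positively.

    PCA signs are arbitrary; a deterministic convention keeps scores and
    loadings reproducible across runs, platforms and library versions.
    Idempotent; scores flip together with loadings so reconstructions
    are unchanged.
    """
    loadings = bundle.loadings.copy()
    scores = bundle.scores.copy()
    flipped = []
    for comp in loadings.columns:
        v = loadings[comp].to_numpy()
        if v[np.argmax(np.abs(v))] < 0:
            loadings[comp] = -loadings[comp]
            scores[comp] = -scores[comp]
            flipped.append(comp)
    return PCABundle(loadings, scores, bundle.variance_fraction, flipped)


def reduce_groupings(
    table: pd.DataFrame,
    groupings: tuple[VariableGrouping, ...] = DEFAULT_GROUPINGS,
) -> tuple[pd.DataFrame, dict[str, PCABundle]]:
    """standardize -> 0-impute -> per-grouping PCA -> oriented retained axes.

    Returns the model-ready design columns (e.g. ``functioning_PC1``,
    ``tpi``) and the full PCA bundles keyed by grouping name.
    """
    missing_cols = [
        v for g in groupings for v in g.variables if v not in table.columns
    ]
    if missing_cols:
        raise KeyError(f"variables missing from input table: {missing_cols}")
    z, _ = impute_missing(standardize_table(
        table[[v for g in groupings for v in g.variables]]
    ))
    design = {}
    bundles: dict[str, PCABundle] = {}
    for g in groupings:
        if g.n_components == 0:
            for v in g.variables:
                design[v] = z[v]
            continue
        bundle = orient_axes(pca(z[list(g.variables)]))
        bundles[g.name] = bundle
        for i in range(g.n_components):
            design[f"{g.name}_PC{i + 1}"] = bundle.scores[f"PC{i + 1}"]
    return pd.DataFrame(design, index=table.index), bundles
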