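"""Taxonomic and functional-trait biodiversity metrics.

Per sample the module computes richness (number of categories present),
Shannon diversity H (natural log, as in vegan's default) and Pielou
evenness J = H / ln(richness), both on the raw species abundance matrix
and on the trait-weighted abundance matrix obtained by multiplying each
taxon's 0-5 trait scores by its abundance and totalling over taxa.

Pielou is undefined for samples with fewer than two categories; such
values are returned as NaN and handled downstream by the mean-imputation
rule of :mod:`seepbef.reduce`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "richness",
    "shannon",
    "pielou",
    "build_trait_matrix",
    "biodiversity_table",
]


@dataclass
class AbundanceMatrix:
    """Samples x species count matrix plus the species -> family map.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are species ids,
        values are non-negative integer counts.
    species_family
        Mapping from species id to family id; every column of
        ``counts`` must be present.
    """

    counts: pd.DataFrame
    species_family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("abundance counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.species_family]
        if missing:
            raise ValueError(f"species without a family mapping: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    def family_abundance(self) -> pd.DataFrame:
        """Collapse species counts to family-level counts."""
        fam = pd.Series({s: self.species_family[s] for s in self.counts.columns})
        return self.counts.T.groupby(fam).sum().T

    @classmethod
    def from_long(cls, long_df: pd.DataFrame, species_family: dict[str, str]) -> "AbundanceMatrix":
        """Build from a long table with columns (sample, species, count)."""
        wide = (
            long_df.pivot_table(index="sample", columns="species", values="count",
                                aggfunc="sum", fill_value=0)
            .astype(int)
        )
        return cls(wide, species_family)


def richness(abundance_row: np.ndarray) -> int:
    """Number of categories with strictly positive abundance."""
    x = np.asarray(abundance_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    return int((x > 0).sum())


def shannon(abundance_row: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over positive entries."""
    x = np.asarray(abundance_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero row")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(abundance_row: np.ndarray) -> float:
    """Pielou evenness J = H / ln(S). NaN when S < 2 (undefined)."""
    s = richness(abundance_row)
    if s < 2:
        return float("nan")
    return shannon(abundance_row) / np.log(s)


def build_trait_matrix(abundance: AbundanceMatrix, traits: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted trait matrix: samples x traits.

    ``traits`` is a family x trait score table (values 0-5).  Each
    species' family-level trait scores are weighted by that species'
    abundance and summed over all taxa in the sample, so
    ``entry(sample, trait) = sum_species score(family(species), trait)
    * abundance(sample, species)``.
    """
    scores = traits.to_numpy()
    if ((scores < 0) | (scores > 5)).any():
        raise ValueError("trait scores must lie in [0, 5]")
    fams = []
    for sp in abundance.counts.columns:
        fam = abundance.species_family[sp]
        if fam not in traits.index:
            raise KeyError(f"family {fam!r} missing from the trait score table")
        fams.append(fam)
    # species x trait score matrix, then sample x trait = counts @ scores
    sp_scores = traits.loc[fams].to_numpy(dtype=float)
    mat = abundance.counts.to_numpy(dtype=float) @ sp_scores
    return pd.DataFrame(mat, index=abundance.counts.index, columns=traits.columns)


def _metrics_frame(mat: pd.DataFrame, prefix: str) -> pd.DataFrame:
    rows = {}
    for sample, row in mat.iterrows():
        x = row.to_numpy(dtype=float)
        s = richness(x)
        h = shannon(x) if s >= 1 else float("nan")
        rows[sample] = {
            f"{prefix}_richness": s,
            f"{prefix}_shannon": h,
            f"{prefix}_pielou": pielou(x),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def biodiversity_table(abundance: AbundanceMatrix, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-sample species and trait richness/Shannon/Pielou (six columns).

    Trait metrics are computed from the trait-weighted matrix exactly as
    if it were a species abundance matrix.
    """
    species = _metrics_frame(abundance.counts, "species")
    trait_mat = build_trait_matrix(abundance, traits)
    trait = _metrics_frame(trait_mat, "trait")
    out = species.join(trait)
    out.index.name = "sample"
    return out
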