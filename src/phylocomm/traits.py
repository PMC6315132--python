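"""Trait tables, z-standardization, Euclidean trait distances, and the UPGMA
trait dendrogram.

Functional diversity (MFD) is computed on cophenetic distances of a
dendrogram clustered from Euclidean distances in standardized trait space —
the trait-space analogue of patristic distances on a phylogeny.  Traits are
z-standardized first because raw trait units span orders of magnitude (leaf
area in mm² against nitrogen content in %): unscaled Euclidean distances
would be dominated by the largest-unit trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix

log = logging.getLogger(__name__)

#: Default trait set: leaf area (mm²), leaf carbon content (%), leaf dry
#: matter content (%), leaf nitrogen content (%), plant height (cm), and
#: specific leaf area (cm²/g).
DEFAULT_TRAITS = ("LA", "LCC", "LDMC", "LNC", "PH", "SLA")

_POSITIVE_TRAITS = {"LA", "PH", "SLA"}
_PERCENT_TRAITS = {"LCC", "LDMC", "LNC"}


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a species × trait table (species in the index, numeric columns).

    Known trait columns get unit-range checks: LA/PH/SLA strictly positive,
    LCC/LDMC/LNC within [0, 100] percent.  NaN marks a missing measurement.
    """
    if traits.index.has_duplicates:
        dups = sorted(traits.index[traits.index.duplicated()].unique())
        raise ValueError(f"duplicate species in trait table: {dups}")
    out = traits.copy()
    for col in out.columns:
        out[col] = pd.to_numeric(out[col], errors="raise")
        vals = out[col].dropna()
        if col in _POSITIVE_TRAITS and (vals <= 0).any():
            bad = sorted(out.index[out[col] <= 0])
            raise ValueError(f"trait {col} must be strictly positive; offending species: {bad}")
        if col in _PERCENT_TRAITS and ((vals < 0) | (vals > 100)).any():
            bad = sorted(out.index[(out[col] < 0) | (out[col] > 100)])
            raise ValueError(f"trait {col} must lie in [0, 100] percent; offending species: {bad}")
    return out


def read_trait_table(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, engine="python")
    first = df.columns[0]
    df = df.set_index(first)
    df.index = df.index.astype(str)
    df.index.name = "species"
    return validate_traits(df)


def write_trait_table(traits: pd.DataFrame, path, sep: str = "\t") -> None:
    traits.to_csv(path, sep=sep, index_label="species")


def standardize_traits(traits: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Rescale each trait column to mean 0 and standard deviation 1.

    Means and SDs are taken over the non-missing species of each column.
    A zero-variance column is an error (it carries no distance information
    and would divide by zero).
    """
    out = traits.copy().astype(float)
    for col in out.columns:
        vals = out[col].dropna()
        if len(vals) < 2:
            raise ValueError(f"trait {col} has fewer than 2 non-missing species")
        sd = vals.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait {col} has zero variance and cannot be standardized")
        out[col] = (out[col] - vals.mean()) / sd
    return out


def drop_incomplete_species(traits: pd.DataFrame) -> pd.DataFrame:
    """Drop species with any missing trait value, logging who was removed."""
    mask = traits.isna().any(axis=1)
    if mask.any():
        dropped = sorted(traits.index[mask])
        log.warning("dropping %d species with missing trait values: %s", len(dropped), dropped)
    return traits.loc[~mask]


def trait_euclidean(traits: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between species trait vectors (standardized input)."""
    if traits.isna().any().any():
        bad = sorted(traits.index[traits.isna().any(axis=1)])
        raise ValueError(f"missing trait values for species: {bad}")
    d = squareform(pdist(traits.to_numpy(float), metric="euclidean"))
    return DistanceMatrix(labels=tuple(traits.index), values=d, kind="trait-euclidean")


@dataclass(frozen=True)
class Dendrogram:
    """An ultrametric binary merge tree over species.

    ``merges`` is a scipy linkage matrix; merge *heights* (half the linkage
    fusion distance, so cophenetic distance = 2 × height) are nondecreasing
    from leaves to root.
    """

    labels: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match label count")
        if np.any(np.diff(Z[:, 2]) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")
        object.__setattr__(self, "merges", Z)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def heights(self) -> np.ndarray:
        """Ultrametric merge heights (fusion distance / 2), leaves upward."""
        return self.merges[:, 2] / 2.0

    def cophenetic(self) -> DistanceMatrix:
        """Cophenetic distances: twice the height of the smallest shared cluster."""
        d = squareform(cophenet(self.merges))
        return DistanceMatrix(labels=self.labels, values=d, kind="dendrogram-cophenetic")


def upgma(dist: DistanceMatrix | pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    UPGMA is the ultrametric analogue of a phylogeny in trait space: each
    fusion joins the pair of clusters with minimal average pairwise distance,
    so the dendrogram's cophenetic distances obey the three-point condition.
    """
    if isinstance(dist, pd.DataFrame):
        dist = DistanceMatrix(
            labels=tuple(dist.index.astype(str)), values=dist.to_numpy(float), kind="trait-euclidean"
        )
    if dist.n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    Z = linkage(squareform(dist.values, checks=False), method="average")
    return Dendrogram(labels=dist.labels, merges=Z)


def trait_dendrogram(traits: pd.DataFrame, standardize: bool = True) -> Dendrogram:
    """Convenience chain: (standardize) → Euclidean distances → UPGMA."""
    table = drop_incomplete_species(validate_traits(traits))
    if standardize:
        table = standardize_traits(table)
    return upgma(trait_euclidean(table))
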