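"""Plot × species community tables and abundance-weighted diversity metrics.

Metrics per plot:

* **MPD** — abundance-weighted mean pairwise phylogenetic distance:
  ``Σ_{i≠j} p_i p_j d(i,j) / Σ_{i≠j} p_i p_j`` with relative covers p and
  patristic distances d (self-pairs excluded, denominator renormalized).
* **MFD** — the same statistic on trait-dendrogram cophenetic distances
  (or, optionally, raw Euclidean trait distances).
* **CWM** — community-weighted trait mean ``Σ p_i x_i``.
* **CWV** — community-weighted trait variance ``Σ p_i (x_i − CWM)²``.

A single-species plot has no pairwise distances, so MPD/MFD are returned as
NaN (missing), never 0 — a 0 would later masquerade as extreme clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class CommunityTable:
    """Plot × species percent-cover matrix plus per-plot stand age (years).

    ``cover`` rows are plots, columns species; entries are nonnegative raw
    covers (any common scale — metrics only use within-plot relative
    abundance).  ``ages`` is indexed by plot.
    """

    cover: pd.DataFrame
    ages: pd.Series

    def __post_init__(self) -> None:
        cov = self.cover.astype(float)
        if cov.index.has_duplicates:
            raise ValueError("duplicate plot identifiers")
        if cov.columns.has_duplicates:
            raise ValueError("duplicate species columns")
        if (cov.to_numpy() < 0).any() or not np.isfinite(cov.to_numpy()).all():
            raise ValueError("covers must be finite and nonnegative")
        empty = cov.index[(cov.to_numpy() > 0).sum(axis=1) == 0]
        if len(empty):
            raise ValueError(f"plots with no positive cover: {sorted(empty)}")
        ages = self.ages.reindex(cov.index)
        if ages.isna().any():
            raise ValueError(
                f"missing stand age for plots: {sorted(cov.index[ages.isna()])}"
            )
        self.cover = cov
        self.ages = ages.astype(float)

    @property
    def plots(self) -> list[str]:
        return list(self.cover.index)

    @property
    def species(self) -> list[str]:
        return list(self.cover.columns)

    def relative(self) -> pd.DataFrame:
        """Within-plot relative abundances (rows sum to 1)."""
        cov = self.cover.to_numpy()
        return pd.DataFrame(
            cov / cov.sum(axis=1, keepdims=True),
            index=self.cover.index,
            columns=self.cover.columns,
        )

    def write(self, path, sep: str = "\t") -> None:
        out = self.cover.copy()
        out.insert(0, "age", self.ages)
        out.to_csv(path, sep=sep, index_label="plot")


def read_community_table(path, sep: str = "\t") -> CommunityTable:
    """Read a community table, wide or long.

    Wide: plot id column, an ``age`` column, then one column per species.
    Long: columns ``plot``, ``age``, ``species``, ``cover`` (detected by
    header), one row per plot × species occurrence.
    """
    head = pd.read_csv(path, sep=sep, nrows=0)
    if {"plot", "species", "cover", "age"} <= set(head.columns):
        long = pd.read_csv(path, sep=sep, dtype={"plot": str, "species": str})
        wide = long.pivot_table(index="plot", columns="species", values="cover",
                                aggfunc="sum", fill_value=0.0)
        wide.columns.name = None
        ages = long.drop_duplicates("plot").set_index("plot")["age"]
        return CommunityTable(cover=wide, ages=ages.reindex(wide.index))
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "age" not in df.columns:
        raise ValueError("community table must contain an 'age' column")
    ages = df.pop("age")
    df.index = df.index.astype(str)
    return CommunityTable(cover=df, ages=ages)


def write_community_long(community: CommunityTable, path, sep: str = "\t") -> None:
    """Write the long (plot, age, species, cover) form, positive covers only."""
    long = (community.cover.stack().rename("cover").reset_index())
    long.columns = ["plot", "species", "cover"]
    long = long[long["cover"] > 0]
    long.insert(1, "age", long["plot"].map(community.ages).astype(float))
    long.to_csv(path, sep=sep, index=False)


def aggregate_quadrats(quadrat_cover: pd.DataFrame, plot_of: pd.Series) -> pd.DataFrame:
    """Average quadrat-level covers per species within each plot.

    Averaging (not summing) preserves the percent-cover scale when a plot was
    surveyed as several fixed-area quadrats.
    """
    return quadrat_cover.groupby(plot_of).mean()


def relative_abundance(cover) -> np.ndarray:
    """Normalize a raw cover vector to relative abundances summing to 1."""
    vec = np.asarray(cover, dtype=float)
    total = vec.sum()
    if np.any(vec < 0):
        raise ValueError("covers must be nonnegative")
    if total <= 0:
        raise ValueError("all-zero cover vector")
    return vec / total


def weighted_mpd(d: np.ndarray, p: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance; NaN for a 1-species plot."""
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if p.ndim != 1 or d.shape != (p.size, p.size):
        raise ValueError("distance matrix must be square and match the weights")
    if p.size < 2:
        log.warning("plot with a single species: MPD undefined")
        return float("nan")
    denom = 1.0 - float(p @ p)
    if denom <= 0:
        return float("nan")
    return float(p @ d @ p) / denom


def cwm(x, p) -> float:
    """Community-weighted mean trait value Σ p_i x_i."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("trait values must be finite for all present species")
    return float(p @ x)


def cwv(x, p) -> float:
    """Community-weighted trait variance Σ p_i (x_i − CWM)²."""
    x = np.asarray(x, dtype=float)
    m = cwm(x, p)
    return float(np.asarray(p, float) @ (x - m) ** 2)


def plot_metrics(
    community: CommunityTable,
    phylo_dist: DistanceMatrix | None,
    func_dist: DistanceMatrix | None,
    traits: pd.DataFrame | None,
    strict: bool = True,
) -> pd.DataFrame:
    """Tidy per-plot metric table: MPD, MFD, and CWM/CWV per trait.

    Every species with positive cover must be present in the distance
    matrices and trait table; with ``strict=False`` unknown species are
    dropped (with a logged warning) instead of raising.
    """
    community = _restrict(community, phylo_dist, func_dist, traits, strict)
    rel = community.relative()
    rows = []
    for plot in community.plots:
        w_full = rel.loc[plot].to_numpy()
        present = w_full > 0
        species = [s for s, keep in zip(community.species, present) if keep]
        w = w_full[present]
        w = w / w.sum()
        richness = len(species)
        age = float(community.ages.loc[plot])

        def add(metric: str, value: float) -> None:
            rows.append(
                {"plot": plot, "age": age, "metric": metric,
                 "value": value, "richness": richness}
            )

        if phylo_dist is not None:
            add("MPD", weighted_mpd(phylo_dist.submatrix(species), w))
        if func_dist is not None:
            add("MFD", weighted_mpd(func_dist.submatrix(species), w))
        if traits is not None:
            sub = traits.reindex(species)
            for col in traits.columns:
                x = sub[col].to_numpy(float)
                if np.any(~np.isfinite(x)):
                    bad = sorted(sub.index[~np.isfinite(sub[col])])
                    raise ValueError(f"missing {col} for present species: {bad}")
                add(f"CWM.{col}", cwm(x, w))
                add(f"CWV.{col}", cwv(x, w))
    return pd.DataFrame(rows)


def _restrict(community, phylo_dist, func_dist, traits, strict) -> CommunityTable:
    known: set | None = None
    for source in (phylo_dist, func_dist):
        if source is not None:
            s = set(source.labels)
            known = s if known is None else known & s
    if traits is not None:
        s = set(traits.index)
        known = s if known is None else known & s
    if known is None:
        return community
    unknown = [s for s in community.species if s not in known]
    if not unknown:
        return community
    if strict:
        raise ValueError(
            f"species present in the community but absent from tree/traits: {sorted(unknown)}"
        )
    log.warning("dropping %d species unknown to tree/traits: %s", len(unknown), sorted(unknown))
    kept = community.cover.drop(columns=unknown)
    return CommunityTable(cover=kept, ages=community.ages)
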