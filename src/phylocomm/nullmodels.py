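"""Randomization null models, standardized effect sizes, and pattern labels.

Three null models, mirroring the classic community-phylogenetics scheme:

1. **Taxa shuffle on the phylogeny** — per run, one permutation of species
   labels across the tips of the phylogenetic distance matrix; MPD is
   recomputed for every plot from the permuted matrix (abundances fixed).
2. **Taxa shuffle on the trait dendrogram** — the same permutation scheme
   applied to the dendrogram-cophenetic distances; recomputes MFD.
3. **Within-plot abundance shuffle** — per run, each plot's cover values are
   permuted among its own present species (species set and traits fixed);
   recomputes CWV per trait.  Tests whether abundance is distributed at
   random with respect to trait values.

The standardized effect size of a metric against its ensemble is

    SES = (observed − mean(null)) / sd(null)      (sample SD, n−1)

and the quantile rank uses an add-one, tie-splitting rule so it lies
strictly inside (0, 1).  Classification requires both the sign of SES and
the quantile tail: rank < 0.05 with SES < 0 → clustering (convergence for
CWV); rank > 0.95 with SES > 0 → overdispersion (divergence); anything else
is random.  An ensemble with zero spread leaves SES undefined; such records
are labelled ``undefined`` and excluded from averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityTable
from .distances import DistanceMatrix

log = logging.getLogger(__name__)

LOWER_LABELS = {"MPD": "clustering", "MFD": "clustering", "CWV": "convergence"}
UPPER_LABELS = {"MPD": "overdispersion", "MFD": "overdispersion", "CWV": "divergence"}


@dataclass(frozen=True)
class NullEnsemble:
    """Null-model values of one metric for one plot."""

    metric: str
    plot: str
    observed: float
    values: np.ndarray
    model: int
    runs: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.runs < 99:
            raise ValueError("null model needs at least 99 runs")
        if vals.shape != (self.runs,) or not np.all(np.isfinite(vals)):
            raise ValueError("null values must be finite, one per run")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SESRecord:
    plot: str
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    rank: float
    pattern: str


def quantile_rank(observed: float, null: np.ndarray) -> float:
    """Tie-splitting, add-one quantile of the observed value in its ensemble:
    (#{null < obs} + 0.5·#{null = obs} + 1) / (runs + 1) ∈ (0, 1)."""
    null = np.asarray(null, dtype=float)
    below = int(np.sum(null < observed))
    ties = int(np.sum(null == observed))
    return (below + 0.5 * ties + 1.0) / (null.size + 1.0)


def ses(observed: float, null: np.ndarray) -> tuple[float, float, float]:
    """(SES, null mean, null sd); SES is NaN when the ensemble has no spread.

    Spread below 1e-10 of the ensemble's own scale counts as zero: a
    degenerate ensemble (all permutations equivalent) differs only by
    floating-point round-off, which must not masquerade as real variation.
    """
    null = np.asarray(null, dtype=float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    tol = 1e-10 * max(abs(mean), abs(observed))
    if sd <= tol or not np.isfinite(sd):
        return float("nan"), mean, sd
    return (observed - mean) / sd, mean, sd


def classify_pattern(
    ses_value: float,
    rank: float,
    metric: str,
    lower: float = 0.05,
    upper: float = 0.95,
) -> str:
    """Map (SES, quantile rank) to a pattern label for one metric family."""
    family = metric.split(".")[0]
    if family not in LOWER_LABELS:
        raise ValueError(f"unknown metric family {family!r}")
    if not np.isfinite(ses_value):
        return "undefined"
    if rank < lower and ses_value < 0:
        return LOWER_LABELS[family]
    if rank > upper and ses_value > 0:
        return UPPER_LABELS[family]
    return "random"


def make_record(
    plot: str, metric: str, observed: float, null: np.ndarray,
    lower: float = 0.05, upper: float = 0.95,
) -> SESRecord:
    if not np.isfinite(observed):
        return SESRecord(plot, metric, observed, float("nan"), float("nan"),
                         float("nan"), float("nan"), "undefined")
    s, mean, sd = ses(observed, null)
    rank = quantile_rank(observed, null)
    return SESRecord(plot, metric, observed, mean, sd, s, rank,
                     classify_pattern(s, rank, metric, lower, upper))


# ---------------------------------------------------------------------------
# model 1 & 2: taxa-label shuffle across the tips of a distance matrix
# ---------------------------------------------------------------------------

def _plot_layout(community: CommunityTable, pool: list[str]):
    """Per-plot species positions (within the pool ordering) and weights."""
    pos = {s: k for k, s in enumerate(pool)}
    rel = community.relative()
    layouts = []
    for plot in community.plots:
        w_full = rel.loc[plot].to_numpy()
        present = np.flatnonzero(w_full > 0)
        species = [community.species[k] for k in present]
        idx = np.asarray([pos[s] for s in species], dtype=np.intp)
        w = w_full[present]
        layouts.append((plot, idx, w / w.sum()))
    return layouts


def null_taxa_shuffle(
    dist: DistanceMatrix,
    community: CommunityTable,
    runs: int = 999,
    seed: int | np.random.Generator | None = None,
    model: int = 1,
    pool: list[str] | None = None,
) -> list[NullEnsemble]:
    """Null models 1/2: shuffle species labels across the distance matrix tips.

    The species pool defaults to every species in the community table (one
    study-wide shuffle per run, shared by all plots, as when tip labels of a
    single tree or dendrogram are permuted).  Abundances stay attached to
    their plot positions.
    """
    if seed is None:
        raise ValueError("seed is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pool is None:
        pool = list(community.species)
    if len(pool) < 2:
        raise ValueError("species pool must contain at least 2 species")
    idx_pool = dist.index_of(pool)
    D = dist.values[np.ix_(idx_pool, idx_pool)]
    P = len(pool)
    perms = rng.permuted(np.tile(np.arange(P), (runs, 1)), axis=1)

    out = []
    for plot, idx, w in _plot_layout(community, pool):
        if idx.size < 2:
            log.warning("plot %s has a single species: null MPD/MFD undefined", plot)
            continue
        obs = float(w @ D[np.ix_(idx, idx)] @ w) / (1.0 - float(w @ w))
        sub = perms[:, idx]  # (runs, S) permuted positions
        dsub = D[sub[:, :, None], sub[:, None, :]]
        nulls = np.einsum("rij,i,j->r", dsub, w, w) / (1.0 - float(w @ w))
        out.append(NullEnsemble(metric={1: "MPD", 2: "MFD"}.get(model, "MPD"),
                                plot=plot, observed=obs, values=nulls,
                                model=model, runs=runs))
    return out


# ---------------------------------------------------------------------------
# model 3: within-plot abundance shuffle, traits fixed
# ---------------------------------------------------------------------------

def null_abundance_shuffle(
    community: CommunityTable,
    traits: pd.DataFrame,
    runs: int = 999,
    seed: int | np.random.Generator | None = None,
) -> list[NullEnsemble]:
    """Null model 3: permute each plot's covers among its present species and
    recompute CWV per trait.  One permutation per run is shared across traits
    (a run is one randomized community)."""
    if seed is None:
        raise ValueError("seed is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for plot, idx, w in _plot_layout(community, list(community.species)):
        species = [community.species[k] for k in idx]
        if len(species) < 2:
            log.warning("plot %s has a single species: null CWV undefined", plot)
            continue
        W = rng.permuted(np.tile(w, (runs, 1)), axis=1)  # (runs, S)
        sub = traits.reindex(species)
        for col in traits.columns:
            x = sub[col].to_numpy(float)
            if np.any(~np.isfinite(x)):
                bad = sorted(sub.index[~np.isfinite(sub[col])])
                raise ValueError(f"missing {col} for present species: {bad}")
            obs = float(w @ x**2 - (w @ x) ** 2)
            means = W @ x
            nulls = W @ x**2 - means**2
            nulls = np.maximum(nulls, 0.0)  # guard tiny negative round-off
            out.append(NullEnsemble(metric=f"CWV.{col}", plot=plot,
                                    observed=max(obs, 0.0), values=nulls,
                                    model=3, runs=runs))
    return out


# ---------------------------------------------------------------------------
# high-level tidy SES table
# ---------------------------------------------------------------------------

def ses_table(
    community: CommunityTable,
    phylo_dist: DistanceMatrix | None = None,
    func_dist: DistanceMatrix | None = None,
    traits: pd.DataFrame | None = None,
    runs: int = 999,
    seed: int | None = None,
    lower: float = 0.05,
    upper: float = 0.95,
    pool: list[str] | None = None,
) -> pd.DataFrame:
    """Run all applicable null models and return a tidy SES table.

    Columns: plot, age, metric, observed, null_mean, null_sd, ses, rank,
    pattern.  Model 1 feeds MPD (phylogenetic distances), model 2 feeds MFD
    (dendrogram-cophenetic distances), model 3 feeds CWV per trait.
    """
    if seed is None:
        raise ValueError("seed is required")
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (np.random.default_rng(c) for c in ss.spawn(3))
    ensembles: list[NullEnsemble] = []
    if phylo_dist is not None:
        ensembles += null_taxa_shuffle(phylo_dist, community, runs, s1, model=1, pool=pool)
    if func_dist is not None:
        ensembles += null_taxa_shuffle(func_dist, community, runs, s2, model=2, pool=pool)
    if traits is not None:
        ensembles += null_abundance_shuffle(community, traits, runs, s3)
    records = [make_record(e.plot, e.metric, e.observed, e.values, lower, upper)
               for e in ensembles]
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    df.insert(1, "age", df["plot"].map(community.ages).astype(float))
    n_undef = int((df["pattern"] == "undefined").sum())
    if n_undef:
        log.warning("%d SES records undefined (zero null spread or missing metric)", n_undef)
    return df
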