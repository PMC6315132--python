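"""Synthetic trees, traits, and chronosequence communities with known
assembly processes.

The generator provides ground truth for every pipeline stage: a Yule
phylogeny over a regional species pool, traits evolved under Brownian motion
(phylogenetically conserved) or assigned from clade-crossing optima
(convergent), and plot communities assembled under one of three kernels —

* ``neutral``       — uniform sampling from the pool;
* ``filtering``     — sampling weighted by a Gaussian kernel around a trait
  optimum (an abiotic filter selecting similar species);
* ``limiting_similarity`` — sequential assembly that rejects candidates too
  close to an already-accepted species in trait space (competitive
  exclusion of similar competitors).

Covers follow a lognormal species-abundance distribution, the standard
stand-in for percent-cover data.  The chronosequence scenario labels plots
with seven stand ages (4–203 years) and shifts the kernel mixture from
purely neutral at early ages to mostly deterministic at late ages, so an
early-vs-late pattern-shift test has a true positive to find.

All randomness flows from one master seed through numpy SeedSequence
substreams (tree, traits, then one stream per plot), so any single plot is
reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import CommunityTable
from .traits import DEFAULT_TRAITS
from .tree import Phylogeny, parse_newick

AGE_CLASSES = (4.0, 14.0, 27.0, 55.0, 76.0, 98.0, 203.0)

#: Typical species-level trait means used to place simulated (latent,
#: dimensionless) trait values on realistic field scales: leaf area (mm²),
#: leaf carbon (%), leaf dry matter (%), leaf nitrogen (%), plant height
#: (cm), specific leaf area (cm²/g).
TRAIT_SCALES = {"LA": 1921.0, "LCC": 43.2, "LDMC": 31.1, "LNC": 1.71,
                "PH": 28.6, "SLA": 284.0}
_SCALE_CV = 0.15  # relative spread per unit of latent trait value

_POSITIVE = {"LA", "PH", "SLA"}
_PERCENT = {"LCC", "LDMC", "LNC"}


def _to_field_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Affine map of latent trait values onto realistic trait units.

    trait = mean × (1 + cv × latent); an affine map, so Blomberg's K and any
    z-standardized downstream quantity are unchanged.  Rare excursions past a
    physical bound are clipped (floor at 1% of the mean for positive traits,
    [0.1, 99.9] for percent traits).
    """
    out = {}
    for col in df.columns:
        latent = df[col].to_numpy(float)
        if col in TRAIT_SCALES:
            mean = TRAIT_SCALES[col]
            vals = mean * (1.0 + _SCALE_CV * latent)
            if col in _POSITIVE:
                vals = np.maximum(vals, 0.01 * mean)
            if col in _PERCENT:
                vals = np.clip(vals, 0.1, 99.9)
            out[col] = vals
        else:
            out[col] = latent
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, rate: float = 1.0,
                  seed: int | np.random.Generator | None = None) -> Phylogeny:
    """Simulate a Yule (pure-birth) tree with ``n_species`` tips.

    Waiting times between speciations are Exponential(rate × k) with k the
    current number of lineages; the lineage that splits is uniform.  The
    returned tree is ultrametric with tip labels ``s001 ... sNNN``.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # node: [child_a, child_b, birth_time] for internals; leaves carry birth time
    birth = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int]] = {}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (rate * len(active)))
        k = rng.integers(len(active))
        parent = active[k]
        a, b = next_id, next_id + 1
        next_id += 2
        birth[a] = birth[b] = t
        children[parent] = (a, b)
        active[k] = a
        active.append(b)
    t += rng.exponential(1.0 / (rate * len(active)))  # extend to the next event

    labels = iter(f"s{i + 1:03d}" for i in range(n_species))

    def newick(node: int) -> str:
        if node in children:
            a, b = children[node]
            length = birth[a] - birth[node]  # children share a birth time
            return f"({newick(a)},{newick(b)}):{length!r}"
        return f"{next(labels)}:{t - birth[node]!r}"

    text = f"({newick(0)},{newick(1)});"
    return parse_newick(text)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_bm_traits(
    tree: Phylogeny,
    trait_names=DEFAULT_TRAITS,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int | np.random.Generator | None = None,
    field_scale: bool = True,
) -> pd.DataFrame:
    """Evolve traits by Brownian motion on the tree.

    Each branch adds an independent Normal(0, sigma2 × length) increment, so
    tip values are jointly Normal with covariance sigma2 × VCV; traits are
    mutually independent.  With ``field_scale`` (default), recognized trait
    names are affinely mapped onto realistic field units; latent
    (dimensionless) values are returned otherwise.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vcv = tree.vcv()
    L = np.linalg.cholesky(vcv.values + 1e-12 * np.eye(vcv.n))
    Z = rng.standard_normal((vcv.n, len(trait_names)))
    X = root_value + np.sqrt(sigma2) * (L @ Z)
    df = pd.DataFrame(X, index=list(vcv.labels), columns=list(trait_names))
    return _to_field_scale(df) if field_scale else df


def simulate_convergent_traits(
    tree: Phylogeny,
    trait_names=DEFAULT_TRAITS,
    n_optima: int = 3,
    attraction: float = 25.0,
    optima_spread: float = 2.0,
    seed: int | np.random.Generator | None = None,
    field_scale: bool = True,
) -> pd.DataFrame:
    """Assign each tip, per trait, to one of ``n_optima`` trait optima drawn
    independently of the phylogeny, with residual noise shrinking as
    ``attraction`` grows (attraction → ∞ pins tips exactly at their optima).

    Distant clades share optima, so Blomberg's K is well below 1 on average.
    """
    if n_optima < 2:
        raise ValueError("need at least 2 optima")
    if attraction <= 0:
        raise ValueError("attraction must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(tree.tip_labels)
    n = len(labels)
    cols = {}
    for name in trait_names:
        optima = rng.normal(0.0, optima_spread, size=n_optima)
        assign = rng.integers(n_optima, size=n)
        noise = rng.standard_normal(n) / np.sqrt(attraction)
        cols[name] = optima[assign] + noise
    df = pd.DataFrame(cols, index=labels)
    return _to_field_scale(df) if field_scale else df


# ---------------------------------------------------------------------------
# community assembly kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kernel:
    """Assembly kernel: ``neutral``, ``filtering(optimum, bandwidth)``, or
    ``limiting_similarity(strength)``."""

    name: str
    optimum: float | None = None
    bandwidth: float | None = None
    strength: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("neutral", "filtering", "limiting_similarity"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name == "filtering" and (self.bandwidth is None or self.bandwidth <= 0):
            raise ValueError("filtering kernel needs bandwidth > 0")
        if self.name == "limiting_similarity" and (self.strength is None or self.strength <= 0):
            raise ValueError("limiting-similarity kernel needs strength > 0")


def _standardized(traits: pd.DataFrame) -> pd.DataFrame:
    mu = traits.mean(axis=0)
    sd = traits.std(axis=0, ddof=1)
    return (traits - mu) / sd


def _sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Weighted sampling without replacement via the Gumbel-max trick."""
    w = np.clip(weights, 1e-300, None)
    keys = np.log(w) + rng.gumbel(size=w.size)
    return np.argsort(keys)[::-1][:k]


def sample_plot(
    traits: pd.DataFrame,
    kernel: Kernel,
    richness: int,
    rng: np.random.Generator,
    focal_trait: str | None = None,
) -> list[str]:
    """Draw one plot's species set from the pool under an assembly kernel.

    Filtering weights species by a Gaussian kernel on distance to the trait
    optimum in standardized trait space: over the single ``focal_trait`` when
    one is named, otherwise over the full multivariate phenotype (distance to
    the trait vector of the pool species nearest the optimum coordinate).
    Limiting similarity accepts candidates in random order only if their
    minimum Euclidean distance (standardized trait space) to already accepted
    species is at least ``strength``.
    """
    pool = list(traits.index)
    if richness > len(pool):
        raise ValueError("richness exceeds pool size")
    z = _standardized(traits)
    if kernel.name == "neutral":
        idx = rng.choice(len(pool), size=richness, replace=False)
        return [pool[i] for i in idx]
    if kernel.name == "filtering":
        opt = kernel.optimum if kernel.optimum is not None else 0.0
        if focal_trait is not None:
            x = z[focal_trait].to_numpy(float)
            d2 = (x - opt) ** 2
        else:
            # multivariate filter: the optimum is the phenotype of the pool
            # species whose first-trait value is nearest the optimum coordinate
            Zm = z.to_numpy(float)
            anchor = Zm[np.argmin(np.abs(Zm[:, 0] - opt))]
            d2 = np.sum((Zm - anchor) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * kernel.bandwidth**2))
        idx = _sample_without_replacement(rng, w, richness)
        return [pool[i] for i in idx]
    # limiting similarity
    Zm = z.to_numpy(float)
    order = rng.permutation(len(pool))
    accepted: list[int] = []
    for cand in order:
        if not accepted:
            accepted.append(cand)
        else:
            dmin = np.min(np.linalg.norm(Zm[accepted] - Zm[cand], axis=1))
            if dmin >= kernel.strength:
                accepted.append(cand)
        if len(accepted) == richness:
            return [pool[i] for i in accepted]
    raise ValueError(
        f"limiting-similarity threshold {kernel.strength} unsatisfiable at "
        f"richness {richness}; request a smaller richness or weaker strength"
    )


def assemble_plots(
    traits: pd.DataFrame,
    kernel: Kernel,
    n_plots: int,
    richness_range: tuple[int, int] = (6, 20),
    seed: int | np.random.Generator | None = None,
    focal_trait: str | None = None,
    ages=None,
    plot_prefix: str = "plot",
    cover_sigma: float = 1.0,
) -> tuple[CommunityTable, pd.DataFrame]:
    """Assemble ``n_plots`` communities under one kernel.

    Covers are lognormal(0, cover_sigma) draws per present species.  Returns
    the community table and a ground-truth record per plot (kernel, params,
    focal trait, richness).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(traits.index)
    ages = list(ages) if ages is not None else [0.0] * n_plots
    if len(ages) != n_plots:
        raise ValueError("ages must match n_plots")
    lo, hi = richness_range
    cover = pd.DataFrame(0.0, index=[f"{plot_prefix}{i + 1:03d}" for i in range(n_plots)],
                         columns=pool)
    truth_rows = []
    for i, plot in enumerate(cover.index):
        richness = int(rng.integers(lo, hi + 1))
        species = sample_plot(traits, kernel, richness, rng, focal_trait)
        cover.loc[plot, species] = rng.lognormal(0.0, cover_sigma, size=len(species))
        truth_rows.append(
            {"plot": plot, "age": ages[i], "kernel": kernel.name,
             "params": json.dumps({k: v for k, v in asdict(kernel).items()
                                   if k != "name" and v is not None}),
             "focal_trait": focal_trait or "", "richness": richness}
        )
    community = CommunityTable(cover=cover, ages=pd.Series(ages, index=cover.index, dtype=float))
    return community, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# full chronosequence scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Conditions for one synthetic chronosequence dataset.

    Defaults emulate a regional understory flora: a 60-species pool, six
    continuous traits, 6–20 co-occurring species per plot, twelve plots in
    each of seven post-fire age classes.  ``deterministic_weight`` is the
    probability that a late-age plot is assembled by a deterministic kernel
    (filtering or limiting similarity) rather than neutrally; early ages are
    fully neutral.
    """

    n_species: int = 60
    yule_rate: float = 1.0
    trait_regime: str = "brownian"  # brownian | convergent
    trait_names: tuple = DEFAULT_TRAITS
    age_classes: tuple = AGE_CLASSES
    plots_per_age: int = 12
    richness_range: tuple = (6, 20)
    neutral_ages: tuple = (4.0, 14.0, 27.0)
    deterministic_weight: float = 0.8
    filter_bandwidth: float = 0.5
    limiting_strength: float = 1.5
    filter_share: float = 0.8  # among deterministic plots, fraction filtered
    cover_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3 or self.plots_per_age < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.deterministic_weight <= 1 and 0 <= self.filter_share <= 1):
            raise ValueError("mixture weights must lie in [0, 1]")
        if self.filter_bandwidth <= 0 or self.limiting_strength <= 0:
            raise ValueError("kernel bandwidth/strength must be positive")
        if self.trait_regime not in ("brownian", "convergent"):
            raise ValueError("trait_regime must be 'brownian' or 'convergent'")
        if self.seed is None:
            raise ValueError("a master seed is required")


@dataclass(frozen=True)
class Scenario:
    tree: Phylogeny
    traits: pd.DataFrame
    community: CommunityTable
    ground_truth: pd.DataFrame
    config: ScenarioConfig


def chronosequence_scenario(config: ScenarioConfig) -> Scenario:
    """Generate one full synthetic dataset along the stand-age chronosequence.

    Plots in ``neutral_ages`` are neutral; in older ages each plot is
    deterministic with probability ``deterministic_weight``, split between
    multivariate Gaussian filtering (the filter's anchor coordinate drawn
    uniform in [−1, 1] per plot) and limiting similarity.  A
    limiting-similarity draw that cannot reach its requested richness falls
    back to the largest feasible richness at or above the range minimum.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_ss, trait_ss, plots_ss = ss.spawn(3)
    tree = simulate_tree(config.n_species, config.yule_rate, np.random.default_rng(tree_ss))
    if config.trait_regime == "brownian":
        traits = simulate_bm_traits(tree, config.trait_names,
                                    seed=np.random.default_rng(trait_ss))
    else:
        traits = simulate_convergent_traits(tree, config.trait_names,
                                            seed=np.random.default_rng(trait_ss))

    n_total = len(config.age_classes) * config.plots_per_age
    plot_streams = plots_ss.spawn(n_total)
    lo, hi = config.richness_range
    cover = pd.DataFrame(0.0,
                         index=[f"plot{i + 1:03d}" for i in range(n_total)],
                         columns=list(traits.index))
    ages_list = []
    truth_rows = []
    i = 0
    for age in config.age_classes:
        for _ in range(config.plots_per_age):
            plot = cover.index[i]
            rng = np.random.default_rng(plot_streams[i])
            kernel = _draw_kernel(config, age, rng)
            richness = int(rng.integers(lo, hi + 1))
            # a too-strict limiting-similarity draw falls back to lower richness
            while True:
                try:
                    species = sample_plot(traits, kernel, richness, rng, focal_trait=None)
                    break
                except ValueError:
                    if richness <= lo:
                        raise
                    richness -= 1
            cover.loc[plot, species] = rng.lognormal(0.0, config.cover_sigma,
                                                     size=len(species))
            truth_rows.append(
                {"plot": plot, "age": age, "kernel": kernel.name,
                 "params": json.dumps({k: v for k, v in asdict(kernel).items()
                                       if k != "name" and v is not None}),
                 "focal_trait": "multivariate", "richness": richness}
            )
            ages_list.append(age)
            i += 1
    community = CommunityTable(
        cover=cover, ages=pd.Series(ages_list, index=cover.index, dtype=float)
    )
    return Scenario(tree=tree, traits=traits, community=community,
                    ground_truth=pd.DataFrame(truth_rows), config=config)


def _draw_kernel(config: ScenarioConfig, age: float, rng: np.random.Generator) -> Kernel:
    if age in config.neutral_ages or rng.random() >= config.deterministic_weight:
        return Kernel("neutral")
    if rng.random() < config.filter_share:
        return Kernel("filtering", optimum=float(rng.uniform(-1.0, 1.0)),
                      bandwidth=config.filter_bandwidth)
    return Kernel("limiting_similarity", strength=config.limiting_strength)
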