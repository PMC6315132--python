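"""Calibration and recovery experiments run end-to-end through the package.

These are the package's reproducibility workloads: estimator calibration for
Blomberg's K under Brownian motion, type-I-error calibration of the
randomization null models under neutral assembly, and assembly-process
recovery on synthetic datasets with known kernels.  Each function generates
its own inputs from a seed, runs the ordinary public API, and returns plain
dictionaries of measured quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityTable
from .inference import shift_test_from_ses
from .nullmodels import make_record, null_abundance_shuffle, null_taxa_shuffle, ses_table
from .signal import blomberg_k
from .simulate import Kernel, ScenarioConfig, assemble_plots, chronosequence_scenario, simulate_bm_traits, simulate_tree
from .traits import trait_dendrogram


def _uniform_community(pool: list[str], n_plots: int, richness: int,
                       rng: np.random.Generator) -> CommunityTable:
    """Neutrally assembled plots: uniform species draws, lognormal covers."""
    cover = pd.DataFrame(0.0, index=[f"p{i + 1:04d}" for i in range(n_plots)],
                         columns=pool)
    for i in range(n_plots):
        sp = rng.choice(len(pool), size=richness, replace=False)
        cover.iloc[i, sp] = rng.lognormal(0.0, 1.0, richness)
    return CommunityTable(cover=cover, ages=pd.Series(0.0, index=cover.index))


def bm_k_calibration(seed: int, n_tips: int = 100, n_reps: int = 500) -> dict:
    """Mean Blomberg's K over Brownian-motion trait replicates on one fixed
    Yule tree.  Under Brownian motion the expectation is ≈ 1."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_reps = ss.spawn(2)
    tree = simulate_tree(n_tips, seed=np.random.default_rng(s_tree))
    v = tree.vcv()
    L = np.linalg.cholesky(v.values + 1e-12 * np.eye(v.n))
    rng = np.random.default_rng(s_reps)
    ks = [blomberg_k(v, L @ rng.standard_normal(v.n)).k for _ in range(n_reps)]
    return {"mean_k": float(np.mean(ks)), "sd_k": float(np.std(ks, ddof=1)),
            "n_reps": n_reps, "n_tips": n_tips}


def neutral_mpd_calibration(seed: int, n_species: int = 60, n_plots: int = 500,
                            richness: int = 10, runs: int = 999) -> dict:
    """Type-I-error calibration of null model 1 (taxa shuffle) for SES.MPD.

    Plots are uniform random draws from the pool with lognormal covers, so
    the observed MPD is exchangeable with its null ensemble; the clustering
    and overdispersion rates should match the one-tailed quantile rule's
    nominal levels (49/1000 and 50/1000 at 999 runs).
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_comm, s_null = ss.spawn(3)
    tree = simulate_tree(n_species, seed=np.random.default_rng(s_tree))
    dist = tree.cophenetic_distances()
    community = _uniform_community(list(tree.tip_labels), n_plots, richness,
                                   np.random.default_rng(s_comm))
    ensembles = null_taxa_shuffle(dist, community, runs=runs,
                                  seed=np.random.default_rng(s_null), model=1)
    patterns = pd.Series(
        [make_record(e.plot, e.metric, e.observed, e.values).pattern for e in ensembles]
    )
    return {"clustering_rate": float((patterns == "clustering").mean()),
            "overdispersion_rate": float((patterns == "overdispersion").mean()),
            "n_plots": int(len(patterns)), "runs": runs}


def neutral_cwv_calibration(seed: int, n_species: int = 60, n_plots: int = 500,
                            richness: int = 10, runs: int = 999) -> dict:
    """Type-I-error calibration of null model 3 (abundance shuffle) for SES.CWV.

    Covers are assigned independently of a Brownian trait, so shuffling
    abundances within plots reproduces the observed CWV's distribution.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_trait, s_comm, s_null = ss.spawn(4)
    tree = simulate_tree(n_species, seed=np.random.default_rng(s_trait))
    traits = simulate_bm_traits(tree, trait_names=("LA",),
                                seed=np.random.default_rng(s_tree))
    community = _uniform_community(list(tree.tip_labels), n_plots, richness,
                                   np.random.default_rng(s_comm))
    ensembles = null_abundance_shuffle(community, traits, runs=runs,
                                       seed=np.random.default_rng(s_null))
    patterns = pd.Series(
        [make_record(e.plot, e.metric, e.observed, e.values).pattern for e in ensembles]
    )
    return {"convergence_rate": float((patterns == "convergence").mean()),
            "divergence_rate": float((patterns == "divergence").mean()),
            "n_plots": int(len(patterns)), "runs": runs}


def kernel_recovery(seed: int, kernel_name: str, n_species: int = 60,
                    n_plots: int = 200, n_datasets: int = 4, runs: int = 999,
                    richness_range: tuple[int, int] | None = None) -> dict:
    """Mean SES.MFD and pattern shares for plots assembled under one kernel.

    Filtering should drive SES.MFD below zero with mostly functional
    clustering; limiting similarity should push SES.MFD above zero.  Plots
    are spread over ``n_datasets`` independent tree/trait realizations so the
    measurement reflects the kernel rather than one random phylogeny; the
    filter's optimum is the trait-space centroid (one filter = one
    environment, at the canonical reference point).
    """
    cfg = ScenarioConfig(seed=0)  # source of the default kernel parameters
    if kernel_name == "limiting_similarity":
        # joint feasibility: mutually spaced sets larger than ~12 of 60 are
        # not guaranteed at the default strength
        richness_range = richness_range or (6, 12)
    else:
        richness_range = richness_range or cfg.richness_range
    frames = []
    per_dataset = max(1, n_plots // n_datasets)
    for child in np.random.SeedSequence(seed).spawn(n_datasets):
        s_tree, s_traits, s_plots, s_null = child.spawn(4)
        if kernel_name == "filtering":
            kernel = Kernel("filtering", optimum=0.0, bandwidth=cfg.filter_bandwidth)
        elif kernel_name == "limiting_similarity":
            kernel = Kernel("limiting_similarity", strength=cfg.limiting_strength)
        else:
            kernel = Kernel("neutral")
        tree = simulate_tree(n_species, seed=np.random.default_rng(s_tree))
        traits = simulate_bm_traits(tree, seed=np.random.default_rng(s_traits))
        func_dist = trait_dendrogram(traits).cophenetic()
        community, _ = assemble_plots(traits, kernel, per_dataset,
                                      richness_range=richness_range,
                                      seed=np.random.default_rng(s_plots))
        seed_null = int(s_null.generate_state(1)[0] % (2**31))
        frames.append(ses_table(community, func_dist=func_dist, runs=runs,
                                seed=seed_null))
    df = pd.concat(frames, ignore_index=True)
    sub = df[df["metric"] == "MFD"]
    return {"mean_ses_mfd": float(sub["ses"].mean()),
            "clustering_share": float((sub["pattern"] == "clustering").mean()),
            "overdispersion_share": float((sub["pattern"] == "overdispersion").mean()),
            "n_plots": int(len(sub)), "runs": runs}


def shift_detection_power(seed: int, n_reps: int = 50, runs: int = 999,
                          alpha: float = 0.05) -> dict:
    """Fraction of default chronosequence datasets whose early-vs-late
    functional-pattern shift is detected by the chi-squared test."""
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_reps):
        s_data, s_null = child.spawn(2)
        data_seed = int(s_data.generate_state(1)[0] % (2**31))
        scenario = chronosequence_scenario(ScenarioConfig(seed=data_seed))
        func_dist = trait_dendrogram(scenario.traits).cophenetic()
        seed_null = int(s_null.generate_state(1)[0] % (2**31))
        df = ses_table(scenario.community, func_dist=func_dist, runs=runs,
                       seed=seed_null)
        _, _, p, _ = shift_test_from_ses(df, "MFD")
        rejections += int(p < alpha)
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "runs": runs}
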