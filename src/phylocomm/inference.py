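"""Chronosequence aggregation, pattern summaries, shift and group tests, and
the conservatism × pattern → process decision matrix.

The interpretive logic: whether a community pattern (phylogenetic or
functional clustering/overdispersion, trait convergence/divergence) points
to environmental filtering or to competitive exclusion depends on whether
trait evolution on the regional phylogeny is conserved or convergent.  With
conserved traits, filtering clusters both phylogeny and traits; with
convergent traits the phylogenetic reading flips: phylogenetic clustering
signals competitive exclusion, while functional clustering and trait
convergence still signal filtering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable

log = logging.getLogger(__name__)

EARLY_AGES = (4.0, 14.0)
LATE_AGES = (98.0, 203.0)

_LOW = {"clustering", "convergence"}
_HIGH = {"overdispersion", "divergence"}


# ---------------------------------------------------------------------------
# aggregation and summaries
# ---------------------------------------------------------------------------

def aggregate_by_age(community: CommunityTable) -> CommunityTable:
    """Sum plot composition within each stand age into one pseudo-plot per age.

    Covers are summed species-wise across the member plots of an age class;
    downstream metrics renormalize, so the sum and the mean are equivalent.
    """
    summed = community.cover.groupby(community.ages).sum()
    ages = pd.Series(summed.index.to_numpy(float), index=summed.index)
    summed.index = [f"age_{a:g}" for a in summed.index]
    ages.index = summed.index
    return CommunityTable(cover=summed, ages=ages)


def pattern_summary(ses_df: pd.DataFrame) -> pd.DataFrame:
    """Per (age, metric): percentage of plots in each pattern, over plots with
    a defined SES, plus the mean SES.

    Columns ``clustering``/``random``/``overdispersion`` hold the low-tail /
    interior / high-tail percentages; for CWV metrics the low tail is trait
    convergence and the high tail divergence.
    """
    rows = []
    for (age, metric), grp in ses_df.groupby(["age", "metric"], sort=True):
        defined = grp[grp["pattern"] != "undefined"]
        n = len(defined)
        if n == 0:
            log.warning("age %s metric %s: no defined SES records; omitted", age, metric)
            continue
        counts = defined["pattern"].value_counts()
        low = int(sum(counts.get(p, 0) for p in _LOW))
        high = int(sum(counts.get(p, 0) for p in _HIGH))
        rand = int(counts.get("random", 0))
        rows.append(
            {"age": age, "metric": metric, "n": n,
             "clustering": 100.0 * low / n,
             "random": 100.0 * rand / n,
             "overdispersion": 100.0 * high / n,
             "mean_ses": float(defined["ses"].mean())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# early-vs-late shift test and rank-based group tests
# ---------------------------------------------------------------------------

def shift_chisq(
    early_patterns,
    late_patterns,
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-squared (no continuity correction) on the 2 × k table of
    pattern counts in early vs late successional plots.

    Pattern categories empty in both groups are dropped (their expected
    counts would be zero); at least two categories must remain.
    Returns (statistic, df, p, contingency table).
    """
    order = ["clustering", "random", "overdispersion", "convergence", "divergence"]
    early = pd.Series(list(early_patterns))
    late = pd.Series(list(late_patterns))
    cats = [c for c in order if (early == c).sum() + (late == c).sum() > 0]
    table = pd.DataFrame(
        [[int((grp == c).sum()) for c in cats] for grp in (early, late)],
        index=["early", "late"], columns=cats,
    )
    if table.shape[1] < 2:
        raise ValueError("need at least two pattern categories with counts")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("each successional group needs at least one classified plot")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p), table


def shift_test_from_ses(
    ses_df: pd.DataFrame,
    metric: str,
    early_ages=EARLY_AGES,
    late_ages=LATE_AGES,
) -> tuple[float, int, float, pd.DataFrame]:
    """Early-vs-late pattern shift for one metric, taken from a tidy SES table."""
    sub = ses_df[(ses_df["metric"] == metric) & (ses_df["pattern"] != "undefined")]
    early = sub[sub["age"].isin(early_ages)]["pattern"]
    late = sub[sub["age"].isin(late_ages)]["pattern"]
    return shift_chisq(early, late)


def rank_group_test(values_by_group: dict) -> tuple[float, float]:
    """Kruskal–Wallis rank test (tie-corrected) across stand-age groups.

    Returns (H, p).  All-tied data gives H = 0, p = 1.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(values_by_group: dict, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on mean ranks after a Kruskal–Wallis test.

    Uses the tie-corrected variance
    ``(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)`` with T = Σ(t³ − t) over
    tie groups.  ``adjust`` ∈ {None, 'bonferroni', 'bh'} controls the
    multiplicity adjustment of the two-sided normal p-values.
    """
    names = list(values_by_group.keys())
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, g in zip(names, groups):
        mean_ranks[name] = ranks[start:start + g.size].mean()
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for (na, ga), (nb, gb) in itertools.combinations(zip(names, groups), 2):
        se = np.sqrt(base_var * (1.0 / ga.size + 1.0 / gb.size))
        z = (mean_ranks[na] - mean_ranks[nb]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": na, "group_b": nb, "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust is None:
        out["p_adjusted"] = out["p"]
    elif adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjust == "bh":
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        prev = 1.0
        for rank_pos, k in enumerate(reversed(order), start=0):
            i = m - rank_pos
            prev = min(prev, out["p"].iloc[k] * m / i)
            adj[k] = prev
        out["p_adjusted"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


# ---------------------------------------------------------------------------
# process interpretation (conservatism × pattern decision matrix)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessCall:
    conservatism: str  # conserved | convergent
    phylo_pattern: str
    functional_pattern: str
    trait_dispersion: str
    process: str  # environmental filtering | competitive exclusion | stochastic | ambiguous
    conflicts: tuple[str, ...] = ()


_VOTES = {
    # (conservatism, component, pattern) -> implied process
    ("conserved", "phylo", "clustering"): "environmental filtering",
    ("conserved", "phylo", "overdispersion"): "competitive exclusion",
    ("conserved", "functional", "clustering"): "environmental filtering",
    ("conserved", "functional", "overdispersion"): "competitive exclusion",
    ("conserved", "dispersion", "convergence"): "environmental filtering",
    ("conserved", "dispersion", "divergence"): "competitive exclusion",
    ("convergent", "phylo", "clustering"): "competitive exclusion",
    ("convergent", "phylo", "overdispersion"): "environmental filtering",
    ("convergent", "functional", "clustering"): "environmental filtering",
    ("convergent", "functional", "overdispersion"): "competitive exclusion",
    ("convergent", "dispersion", "convergence"): "environmental filtering",
    ("convergent", "dispersion", "divergence"): "competitive exclusion",
}


def interpret_process(
    conservatism: str,
    phylo_pattern: str,
    functional_pattern: str,
    trait_dispersion: str,
) -> ProcessCall:
    """Apply the conservatism × pattern decision matrix.

    Each non-random component casts a vote for filtering or exclusion under
    the given trait-evolution regime; unanimous votes name the process, no
    votes is stochastic, and disagreement is ambiguous with the conflicting
    components listed.
    """
    if conservatism not in ("conserved", "convergent"):
        raise ValueError("conservatism must be 'conserved' or 'convergent'")
    components = (
        ("phylo", phylo_pattern),
        ("functional", functional_pattern),
        ("dispersion", trait_dispersion),
    )
    votes = []
    for comp, pattern in components:
        if pattern in ("random", "undefined"):
            continue
        key = (conservatism, comp, pattern)
        if key not in _VOTES:
            raise ValueError(f"pattern {pattern!r} is not valid for component {comp!r}")
        votes.append((comp, pattern, _VOTES[key]))
    if not votes:
        process, conflicts = "stochastic", ()
    elif len({v[2] for v in votes}) == 1:
        process, conflicts = votes[0][2], ()
    else:
        process = "ambiguous"
        conflicts = tuple(f"{c}:{pat}→{proc}" for c, pat, proc in votes)
    return ProcessCall(
        conservatism=conservatism,
        phylo_pattern=phylo_pattern,
        functional_pattern=functional_pattern,
        trait_dispersion=trait_dispersion,
        process=process,
        conflicts=conflicts,
    )


def combine_dispersion(cwv_patterns) -> str:
    """Collapse per-trait CWV patterns into one plot-level dispersion label.

    Any convergence with no divergence → convergence; the reverse →
    divergence; both present → random (conflicting trait evidence); neither
    → random.
    """
    pats = set(cwv_patterns)
    has_low = "convergence" in pats
    has_high = "divergence" in pats
    if has_low and not has_high:
        return "convergence"
    if has_high and not has_low:
        return "divergence"
    return "random"


def classify_conservatism(signal_df: pd.DataFrame, k_threshold: float = 0.5,
                          alpha: float = 0.05) -> str:
    """Call the trait set conserved or convergent from a per-trait K table.

    Conserved requires a majority of traits with K ≥ ``k_threshold`` and
    significant signal; otherwise convergent (K well below 1 indicates
    trait evolution untracked by phylogeny even when signal is nonzero).
    """
    ok = signal_df[(signal_df["K"] >= k_threshold) & (signal_df["p"] < alpha)]
    return "conserved" if len(ok) > len(signal_df) / 2 else "convergent"


def process_calls(
    ses_df: pd.DataFrame,
    conservatism: str,
) -> pd.DataFrame:
    """Per-plot process interpretation from a tidy SES table."""
    rows = []
    for plot, grp in ses_df.groupby("plot", sort=False):
        lookup = dict(zip(grp["metric"], grp["pattern"]))
        phylo = lookup.get("MPD", "undefined")
        func = lookup.get("MFD", "undefined")
        disp = combine_dispersion(
            [v for k, v in lookup.items() if k.startswith("CWV.")]
        )
        call = interpret_process(conservatism, phylo, func, disp)
        rows.append(
            {"plot": plot, "age": float(grp["age"].iloc[0]),
             "conservatism": conservatism, "phylo_pattern": phylo,
             "functional_pattern": func, "trait_dispersion": disp,
             "process": call.process, "conflicts": ";".join(call.conflicts)}
        )
    return pd.DataFrame(rows)
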