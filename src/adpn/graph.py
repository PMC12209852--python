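"""Group-wise metabolic covariance networks and their graph-theoretical
characterization.

Within a selected node set (network regions), between-subject Pearson
correlation of regional metabolic activity defines each group's adjacency
matrix; the entries reported are medians over bootstrap resamples of
subjects.  Connection changes between two groups are gated on magnitude
(|r| >= 0.6 in at least one group, with that correlation itself significant,
and |dr| > 0.2), tested by permutation of subjects between groups, and
validated on bootstrap replicate pairs.  Graph metrics (mean degree,
clustering coefficient, characteristic path length, small-worldness against
degree-preserving randomizations) are swept over a grid of binarization
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .volumes import Atlas, roi_means_matrix

__all__ = [
    "AdjacencyMatrix",
    "node_activity",
    "bootstrap_adjacency",
    "detect_edge_changes",
    "graph_metrics",
    "metrics_over_thresholds",
    "compare_metrics_glm",
    "DEFAULT_THRESHOLD_GRID",
]

log = logging.getLogger(__name__)

#: binarization thresholds r = 0.3 ... 0.6 in 0.05 steps (7 levels)
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.30, 0.601, 0.05), 2))


@dataclass
class AdjacencyMatrix:
    """Bootstrap-median Pearson correlation matrix for one group."""

    r_values: pd.DataFrame = field(repr=False)  # nodes x nodes, unit diagonal
    group: str = ""
    n_boot: int = 0
    n_subjects: int = 0

    def __post_init__(self) -> None:
        v = self.r_values.to_numpy(float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("adjacency diagonal must be 1")


def node_activity(scans_or_roi, atlas: Atlas | None = None,
                  node_ids: list[int] | None = None, group: str = "",
                  scan_ids: list[str] | None = None) -> pd.DataFrame:
    """Subjects x nodes matrix of normalized regional metabolic activity.

    Accepts either a ready scans-x-regions ROI-mean DataFrame or a list of
    preprocessed :class:`Volume` plus an atlas.  ``node_ids`` restricts and
    orders the columns to the network's node set.  Zero-variance columns are
    flagged with a warning (they poison correlations downstream).
    """
    if isinstance(scans_or_roi, pd.DataFrame):
        roi = scans_or_roi
    else:
        if atlas is None:
            raise ValueError("atlas required when passing volumes")
        roi = roi_means_matrix(scans_or_roi, atlas, scan_ids)
    if node_ids is not None:
        if len(node_ids) == 0:
            raise ValueError("empty node set")
        missing = set(int(i) for i in node_ids) - set(int(c) for c in roi.columns)
        if missing:
            raise ValueError(f"node ids not in ROI table: {sorted(missing)}")
        roi = roi[list(node_ids)]
    degen = roi.std(axis=0) == 0
    if degen.any():
        log.warning("node activity: %d zero-variance column(s): %s",
                    int(degen.sum()), list(roi.columns[degen]))
    roi = roi.copy()
    roi.attrs["group"] = group
    return roi


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def bootstrap_adjacency(activity: pd.DataFrame, n_boot: int = 100,
                        seed: int = 0) -> AdjacencyMatrix:
    """Entrywise median of Pearson matrices over ``n_boot`` subject resamples.

    Replicates whose resample leaves a column constant contribute NaN to the
    affected entries; those are excluded from the median (logged).
    """
    n = len(activity)
    if n < 4:
        raise ValueError("need >= 4 subjects for bootstrap correlation")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    vals = activity.to_numpy(float)
    reps = np.empty((n_boot, vals.shape[1], vals.shape[1]))
    n_degen = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        r = _pearson_matrix(vals[idx])
        if np.isnan(r).any():
            n_degen += 1
        reps[b] = r
    if n_degen:
        log.warning("bootstrap adjacency: %d replicate(s) with degenerate columns", n_degen)
    med = np.nanmedian(reps, axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 1.0)
    df = pd.DataFrame(med, index=activity.columns, columns=activity.columns)
    return AdjacencyMatrix(r_values=df, group=activity.attrs.get("group", ""),
                           n_boot=n_boot, n_subjects=n)


def _r_significance_p(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via the t transform."""
    if n < 4 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(t, df=n - 2))


def detect_edge_changes(activity_a: pd.DataFrame, activity_b: pd.DataFrame,
                        r_gate: float = 0.6, dr_gate: float = 0.2,
                        alpha: float = 0.05, n_perm: int = 1000,
                        n_boot: int = 100, seed: int = 0,
                        validation_fraction: float = 0.95) -> pd.DataFrame:
    """Classify every node pair as enhanced/gained/reduced/lost in group A
    relative to reference group B, or leave it unclassified.

    Criteria per edge: at least one group's correlation has |r| >= ``r_gate``
    and is itself significant at ``alpha``; |dr| > ``dr_gate``; and the
    permutation p (subjects shuffled between the pooled groups, matrices
    recomputed per permutation) is below ``alpha``.  Classified edges are then
    re-tested on ``n_boot`` bootstrap replicate pairs: the fraction satisfying
    the same gates with consistent direction must reach
    ``validation_fraction`` with a Bonferroni-corrected binomial test over the
    classified set.

    Returns a tidy DataFrame with one row per node pair.
    """
    if list(activity_a.columns) != list(activity_b.columns):
        raise ValueError("groups must share an identical node set")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nodes = list(activity_a.columns)
    k = len(nodes)
    va, vb = activity_a.to_numpy(float), activity_b.to_numpy(float)
    na, nb = len(va), len(vb)

    degen = (va.std(axis=0) == 0) | (vb.std(axis=0) == 0)
    if degen.any():
        log.warning("edge changes: excluding %d degenerate node(s)", int(degen.sum()))

    ra = _pearson_matrix(va)
    rb = _pearson_matrix(vb)
    dr = ra - rb

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xED6E]))
    pooled = np.vstack([va, vb])
    iu = np.triu_indices(k, 1)
    exceed = np.zeros(len(iu[0]))
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        pa = _pearson_matrix(pooled[perm[:na]])
        pb = _pearson_matrix(pooled[perm[na:]])
        exceed += (np.abs((pa - pb)[iu]) >= np.abs(dr[iu])).astype(float)
    p_perm_flat = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for e, (i, j) in enumerate(zip(*iu)):
        r_a, r_b, d = float(ra[i, j]), float(rb[i, j]), float(dr[i, j])
        row = {"node_a": nodes[i], "node_b": nodes[j], "r_a": r_a, "r_b": r_b,
               "delta_r": d, "p_perm": float(p_perm_flat[e]), "change": "none",
               "validated": False, "boot_fraction": np.nan}
        if degen[i] or degen[j] or np.isnan(r_a) or np.isnan(r_b):
            row["change"] = "excluded"
            rows.append(row)
            continue
        present_a = abs(r_a) >= r_gate and _r_significance_p(r_a, na) < alpha
        present_b = abs(r_b) >= r_gate and _r_significance_p(r_b, nb) < alpha
        magnitude_ok = (present_a or present_b) and abs(d) > dr_gate
        if magnitude_ok and row["p_perm"] < alpha:
            if abs(r_a) > abs(r_b):
                row["change"] = "enhanced" if present_b else "gained"
            else:
                row["change"] = "reduced" if present_a else "lost"
        rows.append(row)
    table = pd.DataFrame(rows)

    classified = table.index[table["change"].isin(["enhanced", "gained", "reduced", "lost"])]
    if len(classified):
        n_tests = len(classified)
        for idx in classified:
            i = nodes.index(table.at[idx, "node_a"])
            j = nodes.index(table.at[idx, "node_b"])
            sign_obs = np.sign(abs(table.at[idx, "r_a"]) - abs(table.at[idx, "r_b"]))
            ok = 0
            for _ in range(n_boot):
                sa = va[rng.integers(0, na, size=na)][:, [i, j]]
                sb = vb[rng.integers(0, nb, size=nb)][:, [i, j]]
                with np.errstate(invalid="ignore"):
                    r_as = np.corrcoef(sa, rowvar=False)[0, 1]
                    r_bs = np.corrcoef(sb, rowvar=False)[0, 1]
                if np.isnan(r_as) or np.isnan(r_bs):
                    continue
                gates = (abs(r_as) >= r_gate or abs(r_bs) >= r_gate) \
                    and abs(r_as - r_bs) > dr_gate \
                    and np.sign(abs(r_as) - abs(r_bs)) == sign_obs
                ok += int(gates)
            frac = ok / n_boot
            p_binom = float(stats.binomtest(ok, n_boot, p=0.5, alternative="greater").pvalue)
            table.at[idx, "boot_fraction"] = frac
            table.at[idx, "validated"] = bool(frac >= validation_fraction
                                              and p_binom * n_tests < alpha)
    return table


# ---------------------------------------------------------------------------
# Graph metrics


def _binarize(adjacency, threshold: float, absolute: bool) -> nx.Graph:
    r = adjacency.r_values if isinstance(adjacency, AdjacencyMatrix) else adjacency
    if isinstance(r, pd.DataFrame):
        nodes = list(r.columns)
        vals = r.to_numpy(float)
    else:
        vals = np.asarray(r, float)
        nodes = list(range(vals.shape[0]))
    m = np.abs(vals) >= threshold if absolute else vals >= threshold
    np.fill_diagonal(m, False)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    iu = np.triu_indices(len(nodes), 1)
    for i, j in zip(*iu):
        if m[i, j]:
            g.add_edge(nodes[i], nodes[j])
    return g


def _char_path_length(g: nx.Graph) -> tuple[float, float]:
    """Mean shortest-path length over *connected* pairs, plus the fraction of
    disconnected pairs (the convention for fragmenting thresholded graphs)."""
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) / 2
    if total_pairs == 0:
        return float("nan"), float("nan")
    acc, connected_pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            acc += sum(dists.values())
        m = len(comp)
        connected_pairs += m * (m - 1) // 2
    if connected_pairs == 0:
        return float("nan"), 1.0
    return acc / (2 * connected_pairs), 1.0 - connected_pairs / total_pairs


def _maslov_sneppen(g: nx.Graph, rng: np.random.Generator, n_swaps: int) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps with
    *uniform* edge sampling (the Maslov-Sneppen chain, whose stationary
    distribution is uniform over graphs with the given degree sequence)."""
    h = g.copy()
    edges = [tuple(e) for e in h.edges()]
    if len(edges) < 2:
        return h
    done, tries, max_tries = 0, 0, 100 * n_swaps
    while done < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,c),(b,d)
        if len({a, b, c, d}) < 4 or h.has_edge(a, c) or h.has_edge(b, d):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, c)
        h.add_edge(b, d)
        edges[i], edges[j] = (a, c), (b, d)
        done += 1
    return h


def _randomized_reference(g: nx.Graph, n_random: int, seed: int) -> tuple[float, float]:
    """Mean clustering and path length of degree-preserving randomizations."""
    cs, ls = [], []
    for rep in range(n_random):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A9, rep]))
        h = _maslov_sneppen(g, rng, n_swaps=max(1, 10 * g.number_of_edges()))
        cs.append(nx.average_clustering(h))
        ls.append(_char_path_length(h)[0])
    return float(np.mean(cs)), float(np.nanmean(ls))


def graph_metrics(adjacency, threshold: float, absolute: bool = False,
                  n_random: int = 20, seed: int = 0) -> dict:
    """One row of the metric panel at a single binarization threshold.

    Edges are kept where r >= threshold (signed, positive-connectivity
    convention; ``absolute=True`` thresholds |r|).  Small-worldness is
    sigma = (C / C_rand) / (L / L_rand) against degree-preserving
    randomizations.  An edgeless graph yields NaN metrics (flagged, not zero).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    g = _binarize(adjacency, threshold, absolute)
    n, e = g.number_of_nodes(), g.number_of_edges()
    out = {"threshold": float(threshold), "n_nodes": n, "n_edges": e}
    if e == 0:
        out.update({"mean_degree": float("nan"), "clustering": float("nan"),
                    "path_length": float("nan"), "disconnected_fraction": float("nan"),
                    "small_worldness": float("nan"), "defined": False})
        return out
    out["mean_degree"] = 2.0 * e / n
    out["clustering"] = float(nx.average_clustering(g))
    L, frac_disc = _char_path_length(g)
    out["path_length"] = float(L)
    out["disconnected_fraction"] = float(frac_disc)
    c_rand, l_rand = _randomized_reference(g, n_random, seed)
    if c_rand > 0 and np.isfinite(l_rand) and l_rand > 0 and np.isfinite(L) and L > 0:
        out["small_worldness"] = float((out["clustering"] / c_rand) / (L / l_rand))
    else:
        out["small_worldness"] = float("nan")
    out["defined"] = True
    return out


def metrics_over_thresholds(activity: pd.DataFrame,
                            grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
                            n_boot: int = 100, seed: int = 0,
                            absolute: bool = False, n_random: int = 20) -> pd.DataFrame:
    """Metric panel per bootstrap replicate per threshold for one group.

    Each replicate resamples subjects, computes a plain Pearson matrix, and is
    swept over the (ascending, non-empty) threshold grid.
    """
    grid = tuple(grid)
    if not grid or list(grid) != sorted(grid):
        raise ValueError("threshold grid must be non-empty ascending")
    n = len(activity)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E17]))
    vals = activity.to_numpy(float)
    rows = []
    for b in range(n_boot):
        r = _pearson_matrix(vals[rng.integers(0, n, size=n)])
        for th in grid:
            m = graph_metrics(pd.DataFrame(r), th, absolute=absolute,
                              n_random=n_random, seed=seed + 31 * b)
            m.update({"replicate": b, "group": activity.attrs.get("group", "")})
            rows.append(m)
    return pd.DataFrame(rows)


def compare_metrics_glm(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        metric: str) -> dict:
    """Group comparison of one metric across the threshold grid: GLM with
    group and threshold as categorical factors (omnibus group F), then post
    hoc per-threshold two-sample t-tests with Bonferroni correction.

    Threshold levels where either group's metric is entirely undefined
    (fragmented graphs) are excluded and logged.
    """
    df = pd.concat([table_a.assign(_grp="A"), table_b.assign(_grp="B")], ignore_index=True)
    df = df[np.isfinite(df[metric])]
    levels = [th for th in sorted(df["threshold"].unique())
              if {"A", "B"} <= set(df.loc[df["threshold"] == th, "_grp"])]
    dropped = sorted(set(df["threshold"].unique()) - set(levels))
    if dropped:
        log.warning("compare_metrics_glm: excluding undefined threshold level(s) %s", dropped)
    df = df[df["threshold"].isin(levels)]
    model = smf.ols(f"{metric} ~ C(_grp) + C(threshold)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    out = {"metric": metric,
           "f_group": float(anova.loc["C(_grp)", "F"]),
           "p_group": float(anova.loc["C(_grp)", "PR(>F)"]),
           "per_threshold": []}
    for th in levels:
        a = df[(df["threshold"] == th) & (df["_grp"] == "A")][metric]
        b = df[(df["threshold"] == th) & (df["_grp"] == "B")][metric]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["per_threshold"].append({"threshold": float(th), "t": float(t),
                                     "p_raw": float(p),
                                     "p_corrected": float(min(1.0, p * len(levels)))})
    return out
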