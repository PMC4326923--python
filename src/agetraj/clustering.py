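"""Fuzzy c-means clustering of standardized temporal expression profiles.

Each gene's profile is its per-age mean expression, centered to mean 0 and
scaled to variance 1 across the ordered age groups, so that Euclidean
distance between profiles reflects shape rather than level. Profiles are
clustered by fuzzy c-means (FCM); the number of clusters is chosen by a
majority vote of five cluster validity indices — partition coefficient,
partition entropy, Xie-Beni, Fukuyama-Sugeno and fuzzy silhouette — which
capture complementary aspects of a partition (compactness, fuzziness,
separation). Clusters are reported in size order with mean profiles, 95%
confidence envelopes, and monotonicity / initial-direction bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .io import NormalizedMatrix, SampleSheet

__all__ = [
    "TemporalProfiles",
    "FuzzyClustering",
    "ClusterSummary",
    "standardize",
    "fcm_fit",
    "validity_vote",
    "summarize_clusters",
    "group_average_trajectory",
]


@dataclass
class TemporalProfiles:
    """Standardized per-age profiles: genes x ages DataFrame plus exclusions."""

    profiles: pd.DataFrame  # index gene_id, columns ages (ascending)
    excluded: list[str] = field(default_factory=list)  # zero-variance genes

    @property
    def ages(self) -> list[float]:
        return list(self.profiles.columns)


def per_age_means(matrix: NormalizedMatrix, sheet: SampleSheet, genes=None) -> pd.DataFrame:
    """Mean expression per age group (replicates averaged), genes x ages."""
    vals = matrix.values if genes is None else matrix.values.loc[list(genes)]
    cols = {}
    for age in sheet.ages:
        cols[age] = vals[sheet.samples_at(age)].mean(axis=1)
    return pd.DataFrame(cols)


def standardize(matrix: NormalizedMatrix, sheet: SampleSheet, genes=None) -> TemporalProfiles:
    """Center each per-age mean profile to mean 0 and scale to variance 1.

    Genes whose per-age mean profile is constant carry no shape information
    and are excluded (listed in ``excluded``).
    """
    if genes is not None:
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    means = per_age_means(matrix, sheet, genes)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = list(means.index[~keep])
    prof = means.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return TemporalProfiles(profiles=prof, excluded=excluded)


# ---------------------------------------------------------------------------
# fuzzy c-means


@dataclass
class FuzzyClustering:
    """A fitted fuzzy c-means partition."""

    k: int
    m: float
    membership: pd.DataFrame  # genes x k, rows sum to 1
    centroids: np.ndarray  # k x n_ages
    objective: float
    objective_trace: np.ndarray  # per-iteration objective of the winning start
    n_iter: int

    @property
    def hard_labels(self) -> pd.Series:
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1),
            index=self.membership.index,
            name="cluster",
        )

    @property
    def cluster_order(self) -> np.ndarray:
        """Cluster indices sorted by hard-member count, descending (stable)."""
        counts = np.bincount(self.hard_labels.to_numpy(), minlength=self.k)
        return np.argsort(-counts, kind="stable")


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (points x k)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    # a point coinciding with a centroid gets full membership there
    zero = d2 <= 1e-300
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, np.argmax(zero[hit], axis=1)] = 1.0
    return u


def _fcm_single(X: np.ndarray, k: int, m: float, tol: float, max_iter: int, rng) -> tuple:
    n = X.shape[0]
    u = rng.dirichlet(np.ones(k), size=n)
    trace = []
    for it in range(max_iter):
        um = u**m
        v = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        u_new = _fcm_memberships(d2, m)
        shift = np.abs(u_new - u).max()
        u = u_new
        if shift < tol:
            break
    um = u**m
    v = (um.T @ X) / um.sum(axis=0)[:, None]
    d2 = ((X[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    obj = float((um * d2).sum())
    trace.append(obj)
    return u, v, obj, np.array(trace), it + 1


def fcm_fit(
    profiles: TemporalProfiles | pd.DataFrame,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 20,
    seed: int = 0,
) -> FuzzyClustering:
    """Fit fuzzy c-means, keeping the best of ``n_starts`` random initializations.

    Standard alternating updates: u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1)),
    v_i = sum_j u_ij^m x_j / sum_j u_ij^m; objective J = sum u^m d^2 with
    Euclidean d. Convergence when the max membership change drops below tol.
    """
    prof = profiles.profiles if isinstance(profiles, TemporalProfiles) else profiles
    X = prof.to_numpy(float)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be < number of profiles ({X.shape[0]})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        u, v, obj, trace, n_iter = _fcm_single(X, k, m, tol, max_iter, rng)
        if best is None or obj < best[2]:
            best = (u, v, obj, trace, n_iter)
    u, v, obj, trace, n_iter = best
    return FuzzyClustering(
        k=k,
        m=m,
        membership=pd.DataFrame(u, index=prof.index),
        centroids=v,
        objective=obj,
        objective_trace=trace,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# validity indices and the k vote

# direction of optimality per index
_INDEX_SENSE = {
    "partition_coefficient": "max",
    "partition_entropy": "min",
    "xie_beni": "min",
    "fukuyama_sugeno": "min",
    "fuzzy_silhouette": "max",
}


def validity_indices(fit: FuzzyClustering, profiles) -> dict[str, float]:
    """The five implemented cluster validity indices for one fitted partition."""
    prof = profiles.profiles if isinstance(profiles, TemporalProfiles) else profiles
    X = prof.to_numpy(float)
    u = fit.membership.to_numpy()
    v = fit.centroids
    n = X.shape[0]
    um = u**fit.m
    d2 = ((X[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)

    pc = float((u**2).sum() / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.where(u > 0, np.log(u), 0.0)
    pe = float(-(u * logu).sum() / n)

    sep = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    xb = float((um * d2).sum() / (n * min_sep)) if min_sep > 0 else np.inf

    vbar = v.mean(axis=0)
    fs = float((um * (d2 - ((v - vbar) ** 2).sum(axis=1)[None, :])).sum())

    labels = np.argmax(u, axis=1)
    if np.unique(labels).size < 2:
        fsil = -1.0
    else:
        s = silhouette_samples(X, labels)
        u_sorted = np.sort(u, axis=1)
        w = u_sorted[:, -1] - u_sorted[:, -2]  # first minus second membership
        fsil = float((w * s).sum() / w.sum()) if w.sum() > 0 else float(s.mean())

    return {
        "partition_coefficient": pc,
        "partition_entropy": pe,
        "xie_beni": xb,
        "fukuyama_sugeno": fs,
        "fuzzy_silhouette": fsil,
    }


def validity_vote(
    profiles: TemporalProfiles | pd.DataFrame,
    k_range=range(2, 11),
    m: float = 2.0,
    seed: int = 0,
    n_starts: int = 20,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, FuzzyClustering]]:
    """Fit FCM over ``k_range`` and let each validity index vote for its best k.

    Returns (chosen_k, validity table indexed by k, fitted clusterings per k).
    chosen_k is the modal vote; ties break toward smaller k.
    """
    ks = sorted(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain >= 2 candidate k")
    fits, rows = {}, {}
    for k in ks:
        fit = fcm_fit(profiles, k, m=m, seed=seed, n_starts=n_starts, **fit_kwargs)
        fits[k] = fit
        rows[k] = validity_indices(fit, profiles)
    table = pd.DataFrame(rows).T  # index k, columns indices
    votes = []
    for name, sense in _INDEX_SENSE.items():
        col = table[name]
        best_k = int(col.idxmax() if sense == "max" else col.idxmin())
        votes.append(best_k)
    counts = pd.Series(votes).value_counts()
    top = counts.max()
    chosen_k = int(min(k for k in counts.index if counts[k] == top))
    table["votes"] = [votes.count(k) for k in table.index]
    return chosen_k, table, fits


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ClusterSummary:
    """Size-ordered per-cluster profile summaries."""

    table: pd.DataFrame  # one row per cluster (size order)
    mean_profiles: pd.DataFrame  # cluster rank x ages
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame


def _monotonic_and_direction(mean_profile: np.ndarray) -> tuple[bool, str]:
    diffs = np.diff(mean_profile)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return True, "flat"
    monotonic = bool((nonzero > 0).all() or (nonzero < 0).all())
    return monotonic, "up" if nonzero[0] > 0 else "down"


def summarize_clusters(fit: FuzzyClustering, profiles: TemporalProfiles) -> ClusterSummary:
    """Mean profile, 95% CI envelope, size, monotonicity and initial direction
    per cluster, reported in decreasing size order."""
    prof = profiles.profiles
    ages = list(prof.columns)
    labels = fit.hard_labels
    order = fit.cluster_order
    rows, means, lows, highs = [], {}, {}, {}
    n_total = len(labels)
    for rank, ci in enumerate(order, start=1):
        members = prof.loc[labels == ci]
        n = len(members)
        if n == 0:
            rows.append(
                {"cluster": rank, "n_members": 0, "pct_members": 0.0,
                 "monotonic": None, "initial_direction": None}
            )
            means[rank] = pd.Series(np.nan, index=ages)
            lows[rank] = pd.Series(np.nan, index=ages)
            highs[rank] = pd.Series(np.nan, index=ages)
            continue
        mean = members.mean(axis=0)
        sd = members.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=ages)
        half = 1.96 * sd / np.sqrt(n)
        mono, direction = _monotonic_and_direction(mean.to_numpy())
        rows.append(
            {"cluster": rank, "n_members": n, "pct_members": 100.0 * n / n_total,
             "monotonic": mono, "initial_direction": direction}
        )
        means[rank], lows[rank], highs[rank] = mean, mean - half, mean + half
    table = pd.DataFrame(rows).set_index("cluster")
    return ClusterSummary(
        table=table,
        mean_profiles=pd.DataFrame(means).T,
        ci_low=pd.DataFrame(lows).T,
        ci_high=pd.DataFrame(highs).T,
    )


def monotonic_pct(summary: ClusterSummary) -> tuple[float, float]:
    """(pct of genes in monotonic clusters, pct in clusters with inversion)."""
    t = summary.table[summary.table["n_members"] > 0]
    total = t["n_members"].sum()
    mono = t.loc[t["monotonic"].astype(bool), "n_members"].sum()
    return 100.0 * mono / total, 100.0 * (total - mono) / total


def initial_direction_pct(summary: ClusterSummary) -> tuple[float, float]:
    """(pct of genes in initially-decreasing clusters, pct initially increasing)."""
    t = summary.table[summary.table["n_members"] > 0]
    total = t["n_members"].sum()
    down = t.loc[t["initial_direction"] == "down", "n_members"].sum()
    up = t.loc[t["initial_direction"] == "up", "n_members"].sum()
    return 100.0 * down / total, 100.0 * up / total


def group_average_trajectory(
    matrix: NormalizedMatrix, sheet: SampleSheet, genes
) -> tuple[pd.Series, pd.Series, float]:
    """Average standardized trajectory of a gene group, with sd envelope.

    Returns (mean standardized profile per age, sd per age, pct change of the
    unstandardized group-mean expression between first and last age).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    means = per_age_means(matrix, sheet, genes)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1).replace(0.0, np.nan)
    standardized = means.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    group_mean = standardized.mean(axis=0)
    group_sd = standardized.std(axis=0, ddof=1) if len(genes) > 1 else pd.Series(
        0.0, index=standardized.columns
    )
    raw_group = means.mean(axis=0)
    first, last = raw_group.iloc[0], raw_group.iloc[-1]
    pct_change = 100.0 * (last - first) / first
    return group_mean, group_sd, float(pct_change)
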