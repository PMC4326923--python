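"""Differential expression by a three-test intersection.

A gene is called differentially expressed when it passes, at FDR level
``alpha``, all three of a parametric count-model test, a nonparametric
rank-sum test and a label-permutation test on the log2 fold change — in at
least one of all pairwise comparisons between the age groups. No effect-size
cutoff is applied; the intersection of three methodologically independent
tests is itself conservative.

The count-model test is a Wald test on the difference of log group means
under a negative-binomial model with a method-of-moments common dispersion;
size factors are DESeq-style median-of-ratios. The rank test is the
Mann-Whitney U (exact when samples are small and untied, tie-corrected
normal approximation otherwise). The permutation test enumerates all label
reassignments exhaustively when the design is small enough and falls back to
seeded Monte Carlo sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

__all__ = [
    "PairwiseTestResult",
    "DEGResult",
    "benjamini_hochberg",
    "size_factors",
    "nb_wald_test",
    "rank_test",
    "perm_fc_test",
    "call_degs",
]

_DISP_FLOOR = 1e-8
_EXHAUSTIVE_LIMIT = 20_000  # max number of splits enumerated exactly


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values (q-values) with monotonicity enforced."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes positive in every sample.

    Falls back to relative column totals when no gene is all-positive.
    """
    vals = counts.to_numpy(float)
    positive = (vals > 0).all(axis=1)
    if positive.any():
        logs = np.log(vals[positive])
        ref = logs.mean(axis=1, keepdims=True)  # per-gene geometric mean
        sf = np.exp(np.median(logs - ref, axis=0))
    else:
        totals = vals.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial Wald test


def _mom_dispersion(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion alpha (var = mu + alpha*mu^2),
    pooled across the two groups; rows are genes."""
    ests = []
    for z in (za, zb):
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.where(m > 0, m, np.nan) ** 2
        ests.append(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = np.nanmean(np.column_stack(ests), axis=1)
    est = np.where(np.isfinite(est), est, _DISP_FLOOR)
    return np.maximum(est, _DISP_FLOOR)


def _nb_wald_vec(
    ya: np.ndarray,
    yb: np.ndarray,
    sfa: np.ndarray,
    sfb: np.ndarray,
    dispersion=None,
) -> np.ndarray:
    """Vectorized NB Wald p-values; ya, yb are genes x replicates count blocks."""
    Sa, Sb = sfa.sum(), sfb.sum()
    tot_a, tot_b = ya.sum(axis=1), yb.sum(axis=1)
    both_zero = (tot_a == 0) & (tot_b == 0)
    # group mean expression; half-count continuity floor keeps logs finite
    mu_a = np.maximum(tot_a, 0.5) / Sa
    mu_b = np.maximum(tot_b, 0.5) / Sb
    if dispersion is None:
        alpha = _mom_dispersion(ya / sfa[None, :], yb / sfb[None, :])
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, float), mu_a.shape)
    # delta method on log(mu_hat), mu_hat = sum(y)/sum(s)
    var_a = 1.0 / (mu_a * Sa) + alpha * (sfa**2).sum() / Sa**2
    var_b = 1.0 / (mu_b * Sb) + alpha * (sfb**2).sum() / Sb**2
    z = (np.log(mu_a) - np.log(mu_b)) / np.sqrt(var_a + var_b)
    df = ya.shape[1] + yb.shape[1] - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)
    p[both_zero] = 1.0
    return np.clip(p, 0.0, 1.0)


def nb_wald_test(counts_a, counts_b, sf_a, sf_b, dispersion: float | None = None) -> float:
    """NB Wald p-value for one gene; see module docstring for the model."""
    ya = np.asarray(counts_a, float)[None, :]
    yb = np.asarray(counts_b, float)[None, :]
    if ya.shape[1] < 2 or yb.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    return float(
        _nb_wald_vec(ya, yb, np.asarray(sf_a, float), np.asarray(sf_b, float), dispersion)[0]
    )


# ---------------------------------------------------------------------------
# rank-sum test


def _rank_vec(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p-values, rows are genes."""
    na, nb = xa.shape[1], xb.shape[1]
    pooled = np.concatenate([xa, xb], axis=1)
    constant = np.ptp(pooled, axis=1) == 0
    has_ties = np.array(
        [np.unique(row).size < row.size for row in pooled]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_asym = stats.mannwhitneyu(
            xa, xb, axis=1, method="asymptotic", alternative="two-sided"
        ).pvalue
        if na + nb <= 12:
            p_exact = stats.mannwhitneyu(
                xa, xb, axis=1, method="exact", alternative="two-sided"
            ).pvalue
            p = np.where(has_ties, p_asym, p_exact)
        else:
            p = p_asym
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def rank_test(values_a, values_b) -> float:
    """Two-sided rank-sum p-value for one gene.

    Exact enumeration when the pooled sample is untied and has <= 12
    observations; midrank/tie-corrected normal approximation otherwise.
    Constant pooled values give p = 1 by convention.
    """
    xa = np.asarray(values_a, float)[None, :]
    xb = np.asarray(values_b, float)[None, :]
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("need >= 2 values per group")
    return float(_rank_vec(xa, xb)[0])


# ---------------------------------------------------------------------------
# permutation test on log2 fold change


def _split_masks(n: int, na: int) -> np.ndarray:
    """All C(n, na) boolean group-a assignments, one row per split."""
    masks = np.zeros((0, n), bool)
    rows = []
    for idx in combinations(range(n), na):
        row = np.zeros(n, bool)
        row[list(idx)] = True
        rows.append(row)
    if rows:
        masks = np.array(rows)
    return masks


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float) -> np.ndarray:
    # expression means are non-negative by contract; clip guards float noise
    return np.log2(np.maximum(mean_a, 0.0) + pseudocount) - np.log2(
        np.maximum(mean_b, 0.0) + pseudocount
    )


def _perm_vec(
    xa: np.ndarray,
    xb: np.ndarray,
    n_perm: int,
    seed: int,
    pseudocount: float = 0.5,
    exhaustive: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation p-values and observed log2fc, rows are genes."""
    na, nb = xa.shape[1], xb.shape[1]
    pooled = np.concatenate([xa, xb], axis=1)
    n = na + nb
    obs = _log2fc(xa.mean(axis=1), xb.mean(axis=1), pseudocount)
    abs_obs = np.abs(obs) - 1e-12  # tolerance: ties count as exceeding
    from math import comb

    if exhaustive is None:
        exhaustive = comb(n, na) <= _EXHAUSTIVE_LIMIT
    if exhaustive:
        masks = _split_masks(n, na)  # n_splits x n
        ma = pooled @ masks.T.astype(float) / na
        mb = pooled @ (~masks).T.astype(float) / nb
        stat = np.abs(_log2fc(ma, mb, pseudocount))
        p = (stat >= abs_obs[:, None]).sum(axis=1) / masks.shape[0]
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(pooled.shape[0], dtype=np.int64)
        block = 1000
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)  # b random label orders
            ma = pooled[:, idx[:, :na]].mean(axis=2)
            mb = pooled[:, idx[:, na:]].mean(axis=2)
            stat = np.abs(_log2fc(ma, mb, pseudocount))
            exceed += (stat >= abs_obs[:, None]).sum(axis=1)
            done += b
        p = (1.0 + exceed) / (1.0 + n_perm)
    constant = np.ptp(pooled, axis=1) == 0
    p = np.where(constant, 1.0, p)
    return np.clip(p, 0.0, 1.0), obs


def perm_fc_test(
    values_a, values_b, n_perm: int = 10_000, seed: int = 0, exhaustive: bool | None = None
) -> float:
    """Permutation p-value for |log2 fold change| between two groups.

    All label reassignments are enumerated exhaustively when C(n, n_a) is
    small (or ``exhaustive=True``); otherwise ``n_perm`` seeded Monte Carlo
    permutations are drawn and the add-one estimator
    (1 + exceedances) / (1 + n_perm) is used.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    xa = np.asarray(values_a, float)[None, :]
    xb = np.asarray(values_b, float)[None, :]
    return float(_perm_vec(xa, xb, n_perm, seed, exhaustive=exhaustive)[0][0])


# ---------------------------------------------------------------------------
# genome-wide calling


@dataclass
class PairwiseTestResult:
    """Per-gene p/q-values of the three tests for one age-pair comparison."""

    comparison: tuple[float, float]
    table: pd.DataFrame  # index gene_id; p_nb, p_rank, p_perm, q_nb, q_rank, q_perm, log2fc


@dataclass
class DEGResult:
    """Genome-wide DEG calls plus the per-comparison test tables."""

    calls: pd.DataFrame  # index gene_id; is_deg, n_supporting, supporting_comparisons, ...
    pairwise: list[PairwiseTestResult]
    alpha: float
    dropped_genes: list[str]  # all-zero genes excluded before testing

    @property
    def deg_ids(self) -> list[str]:
        return list(self.calls.index[self.calls["is_deg"]])


def call_degs(
    matrix: CountMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DEGResult:
    """Run all pairwise age-group comparisons and intersect the three tests.

    BH adjustment is applied separately per test per comparison; a gene is a
    DEG iff some comparison has q < alpha for all three tests simultaneously.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    sheet.validate_against(matrix)
    n_reps = sheet.table.groupby("age_weeks")["sample_id"].count()
    if (n_reps < 2).any():
        raise ValueError("every age group needs >= 2 replicates")

    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    dropped = list(counts.index[~nonzero])
    counts = counts.loc[nonzero]
    genes = counts.index

    sf = size_factors(counts)
    vals = counts.to_numpy(float)
    norm = vals / sf.to_numpy()[None, :]  # size-factor-normalized counts
    col_of = {s: i for i, s in enumerate(counts.columns)}

    ages = sheet.ages
    results: list[PairwiseTestResult] = []
    support: dict[str, list[tuple[float, float]]] = {g: [] for g in genes}
    best = pd.DataFrame(
        index=genes,
        data={
            "best_q_max": np.inf,
            "best_comparison": "",
            "log2fc": np.nan,
            "q_nb": np.nan,
            "q_rank": np.nan,
            "q_perm": np.nan,
        },
    )

    for age_a, age_b in combinations(ages, 2):
        ia = [col_of[s] for s in sheet.samples_at(age_a)]
        ib = [col_of[s] for s in sheet.samples_at(age_b)]
        ya, yb = vals[:, ia], vals[:, ib]
        za, zb = norm[:, ia], norm[:, ib]
        sfa, sfb = sf.to_numpy()[ia], sf.to_numpy()[ib]

        disp = float(np.median(_mom_dispersion(za, zb)))
        disp = max(disp, _DISP_FLOOR)
        p_nb = _nb_wald_vec(ya, yb, sfa, sfb, dispersion=disp)
        p_rank = _rank_vec(za, zb)
        p_perm, log2fc = _perm_vec(za, zb, n_perm=n_perm, seed=seed)

        table = pd.DataFrame(
            {
                "p_nb": p_nb,
                "p_rank": p_rank,
                "p_perm": p_perm,
                "q_nb": benjamini_hochberg(p_nb),
                "q_rank": benjamini_hochberg(p_rank),
                "q_perm": benjamini_hochberg(p_perm),
                "log2fc": log2fc,
            },
            index=genes,
        )
        results.append(PairwiseTestResult(comparison=(age_a, age_b), table=table))

        qmax = table[["q_nb", "q_rank", "q_perm"]].max(axis=1)
        hit = qmax < alpha
        for g in genes[hit]:
            support[g].append((age_a, age_b))
        better = qmax.to_numpy() < best["best_q_max"].to_numpy()
        best.loc[better, "best_q_max"] = qmax[better]
        best.loc[better, "best_comparison"] = f"{age_a:g}v{age_b:g}"
        for col in ("log2fc", "q_nb", "q_rank", "q_perm"):
            best.loc[better, col] = table.loc[better, col]

    calls = pd.DataFrame(index=genes)
    calls["is_deg"] = [len(support[g]) > 0 for g in genes]
    calls["n_supporting"] = [len(support[g]) for g in genes]
    calls["supporting_comparisons"] = [
        ";".join(f"{a:g}v{b:g}" for a, b in support[g]) for g in genes
    ]
    for col in ("best_comparison", "log2fc", "q_nb", "q_rank", "q_perm"):
        calls[col] = best[col]
    calls.index.name = "gene_id"
    return DEGResult(calls=calls, pairwise=results, alpha=alpha, dropped_genes=dropped)
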