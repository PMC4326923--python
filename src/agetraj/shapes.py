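"""Quadratic trajectory classification: U and bell shapes, vertex ages.

Each gene's expression is regressed on age with an ordinary least-squares
quadratic, value = a*age^2 + b*age + c, fitted to every sample (one point per
sample, not per-age means, preserving residual degrees of freedom). A gene is
called U-shaped (a > 0, trough) or bell-shaped (a < 0, peak) when the
two-sided t-test on the quadratic coefficient is significant at ``alpha``;
the inversion age is the vertex -b/(2a). No multiplicity correction is
applied across genes for shape calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedMatrix, SampleSheet

__all__ = ["ShapeFits", "PeakSummary", "quadratic_fit", "fit_shapes", "summarize_peaks"]


@dataclass
class ShapeFits:
    """Per-gene quadratic fits: coefficients, p-values, vertices, labels."""

    table: pd.DataFrame  # index gene_id; a, b, c, p_quad, vertex_age, shape, in_range
    alpha: float
    age_range: tuple[float, float]


@dataclass
class PeakSummary:
    """Counts, medians and histograms of estimated inversion ages per shape."""

    n_u: int
    n_bell: int
    median_peak_u: float
    median_peak_bell: float
    bin_edges: np.ndarray
    hist_u: np.ndarray
    hist_bell: np.ndarray
    n_out_of_range: int


def _ols_quadratic(y: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS of rows of y on [1, age, age^2]; returns (coef, se_a, df).

    coef columns are (c, b, a); se_a is the standard error of the quadratic
    term. Solved through the pseudoinverse of the design.
    """
    n = ages.size
    X = np.column_stack([np.ones(n), ages, ages**2])
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T  # genes x 3
    resid = y - coef @ X.T
    df = n - 3
    sigma2 = (resid**2).sum(axis=1) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_a = np.sqrt(sigma2 * xtx_inv[2, 2])
    return coef, se_a, df


def quadratic_fit(values, ages, alpha: float = 0.05) -> pd.Series:
    """Quadratic fit for a single gene; returns a Series with a, b, c,
    p_quad, vertex_age, shape, in_range."""
    y = np.asarray(values, float)[None, :]
    ages = np.asarray(ages, float)
    fits = _fit_block(y, ages, pd.Index(["gene"]), alpha)
    return fits.table.iloc[0]


def _fit_block(y: np.ndarray, ages: np.ndarray, index: pd.Index, alpha: float) -> ShapeFits:
    if np.unique(ages).size < 3:
        raise ValueError("need >= 3 distinct ages for a quadratic fit")
    if ages.size < 6:
        raise ValueError("need >= 6 samples")
    coef, se_a, df = _ols_quadratic(y, ages)
    c, b, a = coef[:, 0], coef[:, 1], coef[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_a > 0, a / se_a, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    vertex = np.where(a != 0, -b / (2.0 * np.where(a != 0, a, 1.0)), np.nan)
    shape = np.where(p < alpha, np.where(a > 0, "u", "bell"), "none")
    shape = np.where(a == 0, "none", shape)
    lo, hi = float(ages.min()), float(ages.max())
    in_range = np.isfinite(vertex) & (vertex >= lo) & (vertex <= hi)
    table = pd.DataFrame(
        {"a": a, "b": b, "c": c, "p_quad": np.clip(p, 0, 1),
         "vertex_age": vertex, "shape": shape, "in_range": in_range},
        index=index,
    )
    table.index.name = "gene_id"
    return ShapeFits(table=table, alpha=alpha, age_range=(lo, hi))


def fit_shapes(
    matrix: NormalizedMatrix,
    sheet: SampleSheet,
    genes=None,
    alpha: float = 0.05,
) -> ShapeFits:
    """Quadratic fits for many genes against per-sample ages."""
    vals = matrix.values if genes is None else matrix.values.loc[list(genes)]
    ages = sheet.age_of().reindex(vals.columns).to_numpy(float)
    return _fit_block(vals.to_numpy(float), ages, vals.index, alpha)


def summarize_peaks(fits: ShapeFits, restrict_in_range: bool = True, bin_width: float = 2.0) -> PeakSummary:
    """Counts and median vertex ages per shape, with fixed-width age histograms.

    With ``restrict_in_range`` the medians and histograms cover vertices
    inside the sampled age range only; out-of-range vertices are counted
    separately either way.
    """
    t = fits.table
    sig = t[(t["shape"] != "none").astype(bool)]
    n_out = int((~sig["in_range"].astype(bool)).sum())
    use = sig[sig["in_range"].astype(bool)] if restrict_in_range else sig
    lo, hi = fits.age_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)

    def _stats(shape: str):
        v = use.loc[use["shape"] == shape, "vertex_age"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        med = float(np.median(v)) if v.size else float("nan")
        hist, _ = np.histogram(v[(v >= lo) & (v <= hi)], bins=edges)
        return v.size, med, hist

    n_u, med_u, hist_u = _stats("u")
    n_bell, med_bell, hist_bell = _stats("bell")
    return PeakSummary(
        n_u=int((sig["shape"] == "u").sum()),
        n_bell=int((sig["shape"] == "bell").sum()),
        median_peak_u=med_u,
        median_peak_bell=med_bell,
        bin_edges=edges,
        hist_u=hist_u,
        hist_bell=hist_bell,
        n_out_of_range=n_out,
    )
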