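"""Gene-set enrichment with term grouping and cross-dataset intersection.

Enrichment of a query gene list (a temporal cluster, an up- or down-regulated
DEG list) against an expressed-gene background uses the hypergeometric
upper-tail test with BH FDR across the tested sets and fold enrichment
(k/n)/(K/N). Redundant significant terms are grouped by Cohen's kappa
agreement of their gene-membership vectors over the background (single
linkage at a configurable threshold, ClueGO-style), each group annotated by
the member with the largest query overlap. Two analyses run against the same
collection can be intersected into a shared-term table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import benjamini_hochberg
from .io import GeneSetCollection

__all__ = [
    "EnrichmentTable",
    "TermGroup",
    "hypergeom_enrich",
    "fisher_2x2",
    "kappa_group",
    "intersect_term_lists",
]


@dataclass
class EnrichmentTable:
    """Per-set enrichment results (sorted by q), plus skipped empty sets."""

    table: pd.DataFrame  # index set_name; N, K, n, k, p, q, fold
    skipped: list[str]

    def significant(self, q_threshold: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] < q_threshold])


def hypergeom_enrich(query, sets: GeneSetCollection, background) -> EnrichmentTable:
    """Hypergeometric upper-tail enrichment of a query list over a background.

    Sets are intersected with the background before testing; sets emptied by
    the intersection are skipped and reported. The query must be a subset of
    the background.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background, e.g. {extra}")
    N, n = len(background), len(query)
    rows, skipped = [], []
    for name in sets:
        members = sets[name] & background
        K = len(members)
        if K == 0:
            skipped.append(name)
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append({"set_name": name, "N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0), "fold": fold})
    if not rows:
        raise ValueError("no testable sets after background intersection")
    table = pd.DataFrame(rows).set_index("set_name")
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table = table.sort_values(["q", "p"])
    return EnrichmentTable(table=table[["N", "K", "n", "k", "p", "q", "fold"]], skipped=skipped)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table; zero margin gives 1."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class TermGroup:
    """A single-linkage group of kappa-similar enriched terms."""

    members: list[str]
    representative: str  # member with the largest query overlap k


def _cohen_kappa_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two presence/absence vectors."""
    n = a.size
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_group(
    enriched: EnrichmentTable,
    sets: GeneSetCollection,
    background,
    q_threshold: float = 0.05,
    kappa_threshold: float = 0.4,
) -> tuple[list[TermGroup], pd.DataFrame]:
    """Group significant terms by kappa similarity of their membership vectors.

    Returns the single-linkage groups (kappa >= threshold edges) and the full
    pairwise kappa matrix over the significant terms. Groups are sorted by
    size then by representative name; each representative is the member with
    the largest overlap k in the enrichment table.
    """
    bg = sorted(set(background))
    sig = enriched.significant(q_threshold)
    if not sig:
        return [], pd.DataFrame()
    sig = sorted(sig)
    vecs = np.array([[g in sets[s] for g in bg] for s in sig], dtype=bool)
    m = len(sig)
    kap = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            kap[i, j] = kap[j, i] = _cohen_kappa_binary(vecs[i], vecs[j])
    kmat = pd.DataFrame(kap, index=sig, columns=sig)

    # single-linkage components over kappa >= threshold
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sig)
    for i in range(m):
        for j in range(i + 1, m):
            if kap[i, j] >= kappa_threshold:
                g.add_edge(sig[i], sig[j])
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = max(members, key=lambda s: (enriched.table.loc[s, "k"], s))
        groups.append(TermGroup(members=members, representative=rep))
    groups.sort(key=lambda tg: (-len(tg.members), tg.representative))
    return groups, kmat


def intersect_term_lists(
    results_a: EnrichmentTable,
    results_b: EnrichmentTable,
    q_threshold: float = 0.05,
    family_of=None,
) -> pd.DataFrame:
    """Intersect the significant term names of two analyses, per family.

    ``family_of`` maps a set name to a category family (default: one family,
    "all"). The reported percentage is the intersection as a share of B's
    significant terms. The two analyses must share set naming.
    """
    names_a = set(results_a.table.index)
    names_b = set(results_b.table.index)
    if not (names_a & names_b):
        raise ValueError("the two result lists share no set names")
    sig_a = set(results_a.significant(q_threshold))
    sig_b = set(results_b.significant(q_threshold))
    if family_of is None:
        family_of = lambda name: "all"  # noqa: E731
    families = sorted({family_of(s) for s in names_a | names_b})
    rows = []
    for fam in families:
        a = {s for s in sig_a if family_of(s) == fam}
        b = {s for s in sig_b if family_of(s) == fam}
        inter = a & b
        pct = 100.0 * len(inter) / len(b) if b else float("nan")
        rows.append(
            {"family": fam, "n_a": len(a), "n_b": len(b),
             "n_intersection": len(inter), "pct_of_b": pct}
        )
    return pd.DataFrame(rows).set_index("family")
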