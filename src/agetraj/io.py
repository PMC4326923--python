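"""Core data containers and text I/O.

The analysis operates on a gene-by-sample read-count matrix (with per-gene
transcript lengths), a sample sheet mapping samples to age groups and
replicates, gene-set collections (GMT), and thresholded coexpression graphs.
All files are plain text: UTF-8, Unix newlines, ``.`` decimal separator.

Normalization is RPKM (reads per kilobase of transcript per million mapped
reads) computed from the matrix's own column totals, optionally followed by a
``log2(x + pseudocount)`` transform for variance stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "NormalizedMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "rpkm",
    "log_transform",
    "read_gmt",
    "write_gmt",
    "write_graph",
    "read_graph",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-gene transcript lengths.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index is gene ids, columns are
        sample ids, both unique and order-preserving.
    gene_lengths
        Series of strictly positive transcript lengths (bases), indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("no genes")
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
                raise ValueError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
            raise ValueError(f"missing gene length for {missing!r}")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleSheet:
    """Sample metadata: one row per sample with age (weeks) and replicate index."""

    table: pd.DataFrame  # columns: sample_id, age_weeks, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "age_weeks", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        _check_unique(self.table["sample_id"], "sample")
        if (self.table["age_weeks"] <= 0).any():
            raise ValueError("age_weeks must be positive")
        if (self.table["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def ages(self) -> list[float]:
        """Distinct ages, ascending."""
        return sorted(self.table["age_weeks"].unique().tolist())

    def samples_at(self, age: float) -> list[str]:
        m = self.table["age_weeks"] == age
        return list(self.table.loc[m, "sample_id"])

    def age_of(self) -> pd.Series:
        """Series mapping sample_id -> age_weeks."""
        return self.table.set_index("sample_id")["age_weeks"]

    def validate_against(self, matrix: CountMatrix) -> None:
        """Check the sheet covers the matrix samples exactly, with a usable design."""
        sheet_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if sheet_ids != mat_ids:
            raise ValueError(
                f"sample sheet / matrix mismatch: only in sheet {sorted(sheet_ids - mat_ids)}, "
                f"only in matrix {sorted(mat_ids - sheet_ids)}"
            )
        counts = self.table.groupby("age_weeks")["sample_id"].count()
        if len(counts) < 2:
            raise ValueError("need >= 2 distinct age groups")
        if (counts < 2).any():
            bad = counts.index[counts < 2][0]
            raise ValueError(f"age group {bad} has fewer than 2 replicates")


@dataclass
class NormalizedMatrix:
    """Real-valued expression matrix (RPKM, or log2(RPKM + pseudocount))."""

    values: pd.DataFrame
    log_scale: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def add(self, name: str, members, description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        members = set(members)
        if not members:
            raise ValueError(f"empty gene set: {name!r}")
        self.sets[name] = members
        self.descriptions[name] = description

    def restricted_to(self, background) -> "GeneSetCollection":
        """Intersect every set with a background universe, dropping emptied sets."""
        bg = set(background)
        out = GeneSetCollection()
        for name, members in self.sets.items():
            kept = members & bg
            if kept:
                out.add(name, kept, self.descriptions.get(name, ""))
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> CountMatrix:
    """Read a count TSV: header of sample ids; columns gene_id, length, counts...."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if df.shape[0] == 0:
        raise ValueError("no genes")
    if df.shape[1] < 3:
        raise ValueError("count TSV needs gene_id, length and >= 1 sample column")
    gene_col, len_col = df.columns[0], df.columns[1]
    genes = df[gene_col].tolist()
    _check_unique(genes, "gene")
    _check_unique(df.columns[2:], "sample")
    lengths = pd.Series(df[len_col].to_numpy(float), index=genes, name="length")
    counts = df.iloc[:, 2:].copy()
    counts.index = genes
    for col in counts.columns:
        col_vals = pd.to_numeric(counts[col], errors="raise")
        rounded = np.round(col_vals)
        if not np.allclose(col_vals, rounded):
            bad = counts.index[~np.isclose(col_vals, rounded)][0]
            raise ValueError(f"non-integer count at gene {bad!r}, sample {col!r}")
        counts[col] = rounded.astype(np.int64)
    return CountMatrix(counts=counts, gene_lengths=lengths)


def write_counts(matrix: CountMatrix, path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length", matrix.gene_lengths.astype(object))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    return SampleSheet(table=df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def rpkm(matrix: CountMatrix) -> NormalizedMatrix:
    """Reads per kilobase per million mapped reads.

    value(g, s) = counts(g, s) * 1e9 / (length(g) * total_counts(s)); the
    library size is the column total of the input matrix itself.
    """
    totals = matrix.counts.sum(axis=0).to_numpy(float)
    if (totals == 0).any():
        bad = matrix.counts.columns[totals == 0][0]
        raise ValueError(f"zero library size for sample {bad!r}")
    lengths = matrix.gene_lengths.to_numpy(float)
    vals = matrix.counts.to_numpy(float) * 1e9 / (lengths[:, None] * totals[None, :])
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)
    )


def log_transform(norm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Elementwise log2(value + pseudocount); pseudocount must be positive."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return NormalizedMatrix(values=np.log2(norm.values + pseudocount), log_scale=True)


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"GMT line {line_no}: need name, description and >= 1 member"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"empty gene set: {name!r} (line {line_no})")
            coll.add(name, members, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in coll:
            desc = coll.descriptions.get(name, "")
            members = "\t".join(sorted(coll[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_graph(graph: nx.Graph, graphml_path=None, edge_tsv_path=None) -> None:
    """Export a weighted graph as GraphML and/or a 3-column TSV edge list."""
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edge_tsv_path is not None:
        with open(edge_tsv_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b in sorted((sorted(e) for e in graph.edges()), key=tuple):
                r = graph.edges[a, b].get("weight", float("nan"))
                fh.write(f"{a}\t{b}\t{r:.10g}\n")


def read_graph(edge_tsv_path) -> nx.Graph:
    df = pd.read_csv(edge_tsv_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, weight=float(row.r))
    return g
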