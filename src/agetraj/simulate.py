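"""Synthetic study generator.

Emulates a bulk RNA-seq time course over an aging brain: five age groups
(5, 12, 20, 27, 39 weeks by default) with five biological replicates each,
negative-binomial read counts, and genes drawn from six temporal archetypes —
flat, linear up, linear down, rapid decay to an asymptote, U-shape and
bell-shape with a vertex near median lifespan. Every simulated gene carries a
ground-truth label so that downstream detection, clustering and vertex
estimation can be scored against the generator.

The expected RPKM of a gene follows its archetype curve; expected counts are
obtained by inverting the RPKM formula for the drawn library size and
transcript length, so that re-normalizing the simulated counts recovers the
archetype curve on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, SampleSheet

__all__ = [
    "ARCHETYPES",
    "ProfileArchetype",
    "SimConfig",
    "TruthTable",
    "archetype_mean",
    "simulate",
    "simulate_gene_sets",
    "write_truth",
    "read_truth",
]

ARCHETYPES = ("flat", "linear_up", "linear_down", "rapid_decay", "u_shape", "bell_shape")


@dataclass(frozen=True)
class ProfileArchetype:
    """A temporal expression archetype.

    baseline is the expected RPKM at the reference point of the curve
    (the first age for monotone shapes, the vertex for U/bell); amplitude is
    the relative effect size; vertex_age (weeks) applies to U/bell only and
    decay_rate (per week) to rapid_decay only.
    """

    name: str
    baseline: float = 100.0
    amplitude: float = 0.8
    vertex_age: float | None = None
    decay_rate: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if abs(self.amplitude) > 5:
            raise ValueError("|amplitude| must be <= 5")
        if self.name in ("u_shape", "bell_shape") and self.vertex_age is None:
            raise ValueError(f"{self.name} requires vertex_age")
        if self.name == "rapid_decay" and self.decay_rate is None:
            raise ValueError("rapid_decay requires decay_rate")


def archetype_mean(archetype: ProfileArchetype, age: float, ages) -> float:
    """Expected RPKM of an archetype at a given age.

    ``ages`` supplies the design's age grid: curves are parameterized on the
    normalized age offset (age - a0) / (a_max - a0). Results are clamped at
    baseline * 1e-3 so expected intensities stay positive.
    """
    a0, amax = min(ages), max(ages)
    if not (a0 <= age <= amax):
        raise ValueError(f"age {age} outside design range [{a0}, {amax}]")
    span = amax - a0
    t = (age - a0) / span
    name, b, amp = archetype.name, archetype.baseline, archetype.amplitude
    if name == "flat":
        val = b
    elif name == "linear_up":
        val = b * (1 + amp * t)
    elif name == "linear_down":
        val = b * (1 - amp * t)
    elif name == "rapid_decay":
        val = b * ((1 - amp) + amp * np.exp(-archetype.decay_rate * (age - a0)))
    elif name == "u_shape":
        tau = (age - archetype.vertex_age) / span
        val = b * np.exp(amp * tau**2)
    elif name == "bell_shape":
        tau = (age - archetype.vertex_age) / span
        val = b * np.exp(-amp * tau**2)
    else:  # pragma: no cover
        raise AssertionError(name)
    return float(max(val, b * 1e-3))


def _default_archetypes() -> dict[str, ProfileArchetype]:
    return {
        "flat": ProfileArchetype("flat", amplitude=0.0),
        "linear_up": ProfileArchetype("linear_up"),
        "linear_down": ProfileArchetype("linear_down"),
        "rapid_decay": ProfileArchetype("rapid_decay", decay_rate=0.3),
        # U/bell amplitudes are on the exp(amp * tau^2) scale with |tau| <= ~0.65,
        # so amplitude 2 gives a ~2x peak-to-edge fold change, matching the
        # effect size of the linear archetypes (amplitude 0.8 ~ 1.8x over the span)
        "u_shape": ProfileArchetype("u_shape", amplitude=2.0, vertex_age=27.0),
        "bell_shape": ProfileArchetype("bell_shape", amplitude=2.0, vertex_age=25.0),
    }


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated design: ages (5, 12, 20, 27, 39) weeks,
    5 replicates per age, 200 genes per archetype, negative-binomial size 10
    (moderate bulk-RNA-seq overdispersion), library sizes uniform in
    [8e5, 1.2e6] reads and transcript lengths uniform in [500, 5000] bases.
    """

    ages: tuple[float, ...] = (5.0, 12.0, 20.0, 27.0, 39.0)
    replicates_per_age: int = 5
    genes_per_archetype: dict[str, int] = field(
        default_factory=lambda: {a: 200 for a in ARCHETYPES}
    )
    archetypes: dict[str, ProfileArchetype] = field(default_factory=_default_archetypes)
    nb_dispersion: float = 10.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    gene_length_range: tuple[int, int] = (500, 5000)
    baseline_log_sd: float = 0.5  # per-gene lognormal spread of baselines
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")
        if self.replicates_per_age < 1:
            raise ValueError("replicates_per_age must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for lo, hi in (self.library_size_range, self.gene_length_range):
            if lo <= 0 or lo > hi:
                raise ValueError("ranges must satisfy 0 < low <= high")
        for name, n in self.genes_per_archetype.items():
            if name not in self.archetypes:
                raise ValueError(f"no archetype parameters for {name!r}")
            if n < 0:
                raise ValueError("gene counts must be non-negative")


@dataclass
class TruthTable:
    """Ground truth per simulated gene: archetype, true vertex age, DEG flag."""

    table: pd.DataFrame  # index gene_id; columns archetype, vertex_age, is_deg

    def genes_of(self, archetype: str) -> list[str]:
        return list(self.table.index[self.table["archetype"] == archetype])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def simulate(config: SimConfig) -> tuple[CountMatrix, SampleSheet, TruthTable]:
    """Draw a synthetic count matrix, sample sheet and truth table.

    Counts are NegativeBinomial(mean = expected RPKM inverted through the
    RPKM formula, size = nb_dispersion). A single seeded generator stream
    drives every draw, so identical configs give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    ages = list(config.ages)
    n_samples = len(ages) * config.replicates_per_age

    sample_ids, sample_ages, sample_reps = [], [], []
    for age in ages:
        for rep in range(1, config.replicates_per_age + 1):
            sample_ids.append(f"w{age:g}_r{rep}")
            sample_ages.append(age)
            sample_reps.append(rep)

    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=n_samples).astype(float)

    gene_ids, gene_arch, gene_vertex = [], [], []
    for name in ARCHETYPES:
        n = config.genes_per_archetype.get(name, 0)
        arch = config.archetypes[name] if n else None
        for i in range(n):
            gene_ids.append(f"{name}_{i:04d}")
            gene_arch.append(name)
            gene_vertex.append(arch.vertex_age if name in ("u_shape", "bell_shape") else np.nan)
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise ValueError("no genes requested")

    len_lo, len_hi = config.gene_length_range
    lengths = rng.integers(len_lo, len_hi + 1, size=n_genes).astype(float)
    baseline_mult = np.exp(rng.normal(0.0, config.baseline_log_sd, size=n_genes))

    # expected RPKM per gene x sample from the archetype curves
    mean_rpkm = np.empty((n_genes, n_samples))
    for g, name in enumerate(gene_arch):
        arch = config.archetypes[name]
        per_age = {a: archetype_mean(arch, a, ages) * baseline_mult[g] for a in ages}
        mean_rpkm[g] = [per_age[a] for a in sample_ages]

    # invert the RPKM formula: counts = RPKM * length * libsize / 1e9
    mu = mean_rpkm * lengths[:, None] * lib_sizes[None, :] / 1e9
    size = config.nb_dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
    )
    sheet = SampleSheet(
        table=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age_weeks": sample_ages,
                "replicate": sample_reps,
                # nominal mapped-library size used to invert the RPKM formula;
                # column totals of the simulated matrix are smaller because only
                # the simulated genes contribute
                "library_size": lib_sizes.astype(int),
            }
        )
    )
    truth = TruthTable(
        table=pd.DataFrame(
            {
                "archetype": gene_arch,
                "vertex_age": gene_vertex,
                "is_deg": [a != "flat" for a in gene_arch],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return matrix, sheet, truth


def simulate_gene_sets(
    truth: TruthTable,
    n_random_sets: int = 0,
    seed: int = 0,
    member_fraction: float = 0.8,
    contamination: float = 0.05,
    random_set_size: int = 50,
) -> GeneSetCollection:
    """Gene sets aligned with the simulated archetypes, plus null sets.

    One set per archetype holds ``member_fraction`` of that archetype's genes
    plus ``contamination`` (relative to the set size) random other genes;
    ``n_random_sets`` further sets are uniform draws from all genes and carry
    no signal.
    """
    if truth.table.shape[0] == 0:
        raise ValueError("empty truth table")
    rng = np.random.default_rng(seed)
    all_genes = np.array(truth.gene_ids)
    coll = GeneSetCollection()
    for name in ARCHETYPES:
        members = np.array(truth.genes_of(name))
        if members.size == 0:
            continue
        n_core = max(1, int(round(member_fraction * members.size)))
        core = rng.choice(members, size=n_core, replace=False)
        others = np.array(sorted(set(all_genes) - set(members)))
        n_cont = min(int(round(contamination * n_core)), others.size)
        cont = rng.choice(others, size=n_cont, replace=False) if n_cont else np.array([])
        coll.add(f"SET_{name}", set(core) | set(cont), f"genes enriched for {name}")
    for i in range(n_random_sets):
        size = min(random_set_size, all_genes.size)
        members = rng.choice(all_genes, size=size, replace=False)
        coll.add(f"RANDOM_{i:03d}", set(members), "uniform random gene set")
    return coll


def simulate_planted_hub(
    n_followers: int = 50,
    n_background: int = 200,
    n_samples: int = 25,
    follower_noise_sd: float = 0.3,
    seed: int = 0,
):
    """Expression values with one planted driver gene and correlated followers.

    The driver is a standard-normal sample vector; each follower is the
    driver plus independent noise, so driver-follower correlation is
    ~1/sqrt(1 + sd^2) while follower-follower correlation is the weaker
    ~1/(1 + sd^2). Background genes are independent noise. Returns
    (NormalizedMatrix, driver gene id). Network-recovery scaffold.
    """
    from .io import NormalizedMatrix

    rng = np.random.default_rng(seed)
    driver = rng.standard_normal(n_samples)
    followers = driver[None, :] + follower_noise_sd * rng.standard_normal(
        (n_followers, n_samples)
    )
    background = rng.standard_normal((n_background, n_samples))
    genes = (
        ["driver"]
        + [f"follower_{i:03d}" for i in range(n_followers)]
        + [f"bg_{i:03d}" for i in range(n_background)]
    )
    vals = np.vstack([driver[None, :], followers, background])
    df = pd.DataFrame(vals, index=genes, columns=[f"s{i:02d}" for i in range(n_samples)])
    return NormalizedMatrix(values=df, log_scale=True), "driver"


def simulate_planted_blocks(
    n_per_block: int = 25,
    ages: tuple[float, ...] = (5.0, 12.0, 20.0, 27.0, 39.0),
    replicates_per_age: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Two gene blocks that decouple at the last age. Network-recovery scaffold.

    At every age but the last, all genes follow one shared per-sample latent;
    at the last age the two blocks follow independent latents. Within-block
    correlations therefore stay near 1 in every stratum, while cross-block
    correlations in the last stratum are those of two independent latent
    vectors. Returns (NormalizedMatrix, SampleSheet, block label Series).
    """
    from .io import NormalizedMatrix, SampleSheet

    rng = np.random.default_rng(seed)
    sample_ids, sample_ages, sample_reps = [], [], []
    for age in ages:
        for rep in range(1, replicates_per_age + 1):
            sample_ids.append(f"w{age:g}_r{rep}")
            sample_ages.append(age)
            sample_reps.append(rep)
    n_samples = len(sample_ids)
    last = max(ages)
    is_last = np.array([a == last for a in sample_ages])

    latent_shared = rng.standard_normal(n_samples)
    latent_b_last = rng.standard_normal(int(is_last.sum()))
    latent_a = latent_shared.copy()
    latent_b = latent_shared.copy()
    latent_b[is_last] = latent_b_last

    genes, rows, labels = [], [], []
    for block, latent in (("A", latent_a), ("B", latent_b)):
        for i in range(n_per_block):
            genes.append(f"block{block}_{i:03d}")
            labels.append(block)
            rows.append(latent + noise_sd * rng.standard_normal(n_samples))
    df = pd.DataFrame(np.array(rows), index=genes, columns=sample_ids)
    sheet = SampleSheet(
        table=pd.DataFrame(
            {"sample_id": sample_ids, "age_weeks": sample_ages, "replicate": sample_reps}
        )
    )
    return (
        NormalizedMatrix(values=df, log_scale=True),
        sheet,
        pd.Series(labels, index=genes, name="block"),
    )


def write_truth(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", lineterminator="\n")


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["is_deg"] = df["is_deg"].astype(bool)
    return TruthTable(table=df)
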