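"""Planted-structure simulator for stage-comparative expression profiling.

The generator emulates a four-population microarray design — germ (G) and
Sertoli (S) cells at two developmental stages (9 and 22 days post partum),
three biological replicates each — at the probe level: every gene carries a
fixed number of probes with gene-specific probe affinities, log-normal
measurement noise, and additive (in log2) planted effects:

    intensity = 2 ** (baseline + gene_effect + block_effects(condition)
                      + probe_affinity + noise)

Planted structure, all recorded in an emitted ground-truth table:

* condition-selective blocks — genes elevated in exactly one condition
  (the "-sel" sets a concordance caller should recover);
* a shared block elevated jointly in the two pre-pubertal populations,
  mimicking the common mitotic program of germ and Sertoli cells at 9 dpp;
* absent genes, emitted near a background intensity in every sample — the
  task of the Present/Absent detection caller;
* annotation categories with a known enriched fraction drawn from one
  block, plus null categories drawn uniformly.

A single integer seed drives one numpy Generator; the draw order is fixed
(gene effects, probe affinities, noise, category sampling, named-member
placement is deterministic), so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SampleSheet

__all__ = [
    "PlantedBlock",
    "CategorySpec",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate",
    "truth_confusion",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A gene block elevated in a set of conditions by a log2 effect."""

    name: str
    conditions: tuple[str, ...]
    n_genes: int
    log2_effect: float

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("block gene count must be >= 0")
        if self.log2_effect < 1.0:
            raise ValueError("planted log2 effects below 1.0 (2-fold) are not supported")


@dataclass(frozen=True)
class CategorySpec:
    name: str
    size: int
    enriched_block: str | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 1000
    probes_per_gene: int = 11
    conditions: tuple[str, ...] = ("G9", "S9", "G22", "S22")
    replicates_per_condition: int = 3
    baseline_log2_mean: float = 7.0
    gene_sd_log2: float = 1.0
    probe_affinity_sd_log2: float = 0.5
    noise_sd_log2: float = 0.35
    planted_blocks: tuple[PlantedBlock, ...] = ()
    absent_fraction: float = 0.1
    background_level: float = 16.0
    categories: tuple[CategorySpec, ...] = ()
    category_enrichment_fraction: float = 0.5
    named_members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("n_genes and probes_per_gene must be positive")
        if not 0.0 <= self.absent_fraction <= 1.0:
            raise ValueError("absent_fraction must lie in [0, 1]")
        if self.noise_sd_log2 < 0 or self.background_level < 0:
            raise ValueError("noise_sd_log2 and background_level must be >= 0")
        names = [b.name for b in self.planted_blocks]
        if len(set(names)) != len(names):
            raise ValueError("planted block names must be unique")
        for b in self.planted_blocks:
            unknown = set(b.conditions) - set(self.conditions)
            if unknown:
                raise ValueError(f"block {b.name!r} targets unknown conditions {unknown}")
        if self.n_planted + self.n_absent > self.n_genes:
            raise ValueError(
                f"infeasible spec: {self.n_planted} planted + {self.n_absent} absent "
                f"genes exceed n_genes={self.n_genes}"
            )
        for c in self.categories:
            if c.enriched_block is not None and c.enriched_block not in names:
                raise ValueError(f"category {c.name!r} references unknown block")
        for block, members in self.named_members.items():
            if block not in names:
                raise ValueError(f"named_members references unknown block {block!r}")
            sizes = {b.name: b.n_genes for b in self.planted_blocks}
            if len(members) > sizes[block]:
                raise ValueError(f"too many named members for block {block!r}")

    @property
    def n_planted(self) -> int:
        return sum(b.n_genes for b in self.planted_blocks)

    @property
    def n_absent(self) -> int:
        return round(self.absent_fraction * self.n_genes)


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reference study design: 1000 genes, 4 conditions x 3 replicates,
    11 probes per gene, one 50-gene selective block per condition at a
    4-fold (2.0 log2) effect, a 60-gene shared pre-pubertal block at 1.5
    log2, 10% absent genes, and one planted-enrichment category per
    selective block alongside 20 null categories."""
    blocks = tuple(
        PlantedBlock(f"{c}_sel", (c,), 50, 2.0) for c in ("G9", "S9", "G22", "S22")
    ) + (PlantedBlock("mitotic_shared", ("G9", "S9"), 60, 1.5),)
    cats = tuple(
        CategorySpec(f"cat_{c}", 40, f"{c}_sel") for c in ("G9", "S9", "G22", "S22")
    ) + tuple(CategorySpec(f"null_{i:02d}", 40, None) for i in range(1, 21))
    named = {
        "G9_sel": ("vegfc", "edn1", "bdnf"),  # stem-cell ligands
        "S9_sel": ("kdr", "ednrb", "ntrk1"),  # niche receptors
    }
    base = dict(planted_blocks=blocks, categories=cats, named_members=named, seed=seed)
    base.update(overrides)
    return SyntheticSpec(**base)


@dataclass
class GroundTruth:
    """Per-gene truth table plus the category -> enriched-block map."""

    genes: pd.DataFrame  # gene_id, blocks, selective_condition, absent
    category_blocks: dict[str, str | None]

    def selective_genes(self, condition: str) -> frozenset[str]:
        sel = self.genes[self.genes["selective_condition"] == condition]
        return frozenset(sel["gene_id"])

    def absent_genes(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["absent"], "gene_id"])

    def block_genes(self, block: str) -> frozenset[str]:
        mask = self.genes["blocks"].str.split(";").apply(lambda bs: block in bs)
        return frozenset(self.genes.loc[mask, "gene_id"])


def _gene_labels(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes - 1)))
    labels = [f"g{i:0{width}d}" for i in range(spec.n_genes)]
    # deterministic renaming of the leading genes of a block (demo markers)
    offset = 0
    for block in spec.planted_blocks:
        for j, name in enumerate(spec.named_members.get(block.name, ())):
            labels[offset + j] = name
        offset += block.n_genes
    return labels


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, GroundTruth, GeneSetCollection]:
    """Draw one probe-level expression matrix with its ground truth.

    Gene layout is deterministic: planted blocks occupy the leading gene
    indices in declaration order, absent genes the trailing indices; only
    effect sizes, affinities, noise and category fillers are random.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_genes, spec.probes_per_gene
    conds = [c for c in spec.conditions for _ in range(spec.replicates_per_condition)]
    reps = list(range(1, spec.replicates_per_condition + 1)) * len(spec.conditions)
    sheet = SampleSheet(
        sample_ids=tuple(f"{c}_r{r}" for c, r in zip(conds, reps)),
        conditions=tuple(conds),
        replicates=tuple(reps),
    )
    n_samples = len(sheet.sample_ids)

    labels = _gene_labels(spec)
    block_of: list[list[str]] = [[] for _ in range(n)]
    offset = 0
    for block in spec.planted_blocks:
        for i in range(offset, offset + block.n_genes):
            block_of[i].append(block.name)
        offset += block.n_genes
    absent = np.zeros(n, dtype=bool)
    absent[n - spec.n_absent :] = True

    # log2 effect of each gene in each sample's condition
    cond_effect = np.zeros((n, n_samples))
    offset = 0
    for block in spec.planted_blocks:
        in_cond = np.array([c in block.conditions for c in conds], dtype=float)
        cond_effect[offset : offset + block.n_genes] += block.log2_effect * in_cond
        offset += block.n_genes

    gene_effect = rng.normal(0.0, spec.gene_sd_log2, size=n)
    affinity = rng.normal(0.0, spec.probe_affinity_sd_log2, size=(n, p))
    noise = rng.normal(0.0, spec.noise_sd_log2, size=(n, p, n_samples))

    log2_mean = (
        spec.baseline_log2_mean
        + gene_effect[:, None, None]
        + cond_effect[:, None, :]
        + affinity[:, :, None]
    )
    if spec.background_level > 0:
        bg = np.log2(spec.background_level)
    else:
        bg = -np.inf
    # absent genes sit at background with the same noise (no planted or
    # probe structure), so detection operates at its nominal level there
    log2_mean[absent] = bg
    values = np.exp2(log2_mean + noise)
    values = np.maximum(values, 0.0).reshape(n * p, n_samples)

    feature_ids = np.repeat(np.asarray(labels, dtype=object), p)
    probe_index = np.tile(np.arange(1, p + 1), n)
    matrix = ExpressionMatrix(
        feature_ids=feature_ids, values=values, samples=sheet, probe_index=probe_index
    )

    selective = []
    for blocks in block_of:
        single = [
            b.name
            for b in spec.planted_blocks
            if b.name in blocks and len(b.conditions) == 1
        ]
        if len(single) == 1:
            cond = next(
                b.conditions[0] for b in spec.planted_blocks if b.name == single[0]
            )
            selective.append(cond)
        else:
            selective.append("")
    truth_frame = pd.DataFrame(
        {
            "gene_id": labels,
            "blocks": [";".join(b) for b in block_of],
            "selective_condition": selective,
            "absent": absent,
        }
    )

    # categories: enriched ones take round(f*s) members from their block,
    # the remainder (and null categories entirely) uniformly at random
    all_genes = np.asarray(labels, dtype=object)
    by_block = {
        b.name: all_genes[
            [i for i in range(n) if b.name in block_of[i]]
        ]
        for b in spec.planted_blocks
    }
    cat_sets: dict[str, frozenset[str]] = {}
    cat_blocks: dict[str, str | None] = {}
    for cat in spec.categories:
        if cat.enriched_block is not None:
            pool = by_block[cat.enriched_block]
            k = round(spec.category_enrichment_fraction * cat.size)
            if k > pool.size:
                raise ValueError(f"category {cat.name!r} larger than its block affords")
            core = rng.choice(pool, size=k, replace=False)
            rest_pool = np.asarray(sorted(set(labels) - set(core) - set(pool)), dtype=object)
            filler = rng.choice(rest_pool, size=cat.size - k, replace=False)
            members = frozenset(core) | frozenset(filler)
        else:
            members = frozenset(rng.choice(all_genes, size=cat.size, replace=False))
        cat_sets[cat.name] = members
        cat_blocks[cat.name] = cat.enriched_block
    categories = GeneSetCollection(sets=cat_sets, universe=frozenset(labels))

    truth = GroundTruth(genes=truth_frame, category_blocks=cat_blocks)
    return matrix, truth, categories


def truth_confusion(truth: GroundTruth, called: GeneSetCollection) -> pd.DataFrame:
    """Sensitivity and false-discovery proportion of called selective sets.

    Called sets are named by condition (an optional ``_sel``/``-sel``
    suffix is accepted).  Sensitivity = recovered planted / planted; FDP =
    non-planted called / called, defined as 0.0 for an empty called set.
    """
    known = set(truth.genes["selective_condition"]) - {""}
    records = []
    for name in called.names():
        cond = name.removesuffix("_sel").removesuffix("-sel")
        if cond not in known:
            raise KeyError(f"called set {name!r} matches no planted condition")
        planted = truth.selective_genes(cond)
        got = called[name]
        tp = len(got & planted)
        sens = tp / len(planted) if planted else 0.0
        fdp = (len(got) - tp) / len(got) if got else 0.0
        records.append(
            {
                "set_name": name,
                "condition": cond,
                "n_planted": len(planted),
                "n_called": len(got),
                "n_recovered": tp,
                "sensitivity": sens,
                "fdp": fdp,
            }
        )
    return pd.DataFrame.from_records(records)
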