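"""Synthetic DrugBank-like worlds with known ground truth.

The generator emulates the study's input universe: a sparse bipartite
drug–target interaction matrix produced by low-rank latent factors with a
logistic observation link, modulator category labels, binary fingerprints
correlated with the latent drug profiles, and pathway-style gene-set
collections with optional planted category-specific enrichment. Every
artifact is a pure function of (config, seed): the master seed is split
into independent named sub-streams (factors, categories, fingerprints,
interactions, pathways) so stages can be re-sampled independently.

Default sizes mirror the study's curated input: 225 modulators in
proportions 174/31/20, 993 targets, and edge density 1831/(225*993)
(~0.8% of pairs), with 294 pathway-style sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import (
    CATEGORIES,
    DrugCatalog,
    DrugRecord,
    GeneSetCollection,
    InteractionSet,
    TargetCatalog,
    TargetRecord,
    write_drug_catalog,
    write_gene_sets,
    write_id_list,
    write_interactions,
    write_target_catalog,
)

_STREAMS = ("factors", "categories", "fingerprints", "interactions", "pathways")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class WorldConfig:
    """Study-condition knobs for one synthetic world.

    density is the expected fraction of drug–target pairs observed as known
    positives. planted entries are (pathway_index, category, odds_multiplier):
    targets reached by that category have their membership probability in
    that pathway multiplied by odds_multiplier.
    """

    n_drugs: int = 225
    n_targets: int = 993
    latent_dim: int = 5
    density: float = 1831 / (225 * 993)
    category_proportions: tuple[float, float, float] = (174 / 225, 31 / 225, 20 / 225)
    n_pathways: int = 294
    planted: tuple[tuple[int, str, float], ...] = ()
    fingerprint_length: int = 256
    noise_sd: float = 0.3
    link_offset: float = -6.0
    link_sharpness: float = 3.0
    pathway_base_prob: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 2 or self.n_targets < 2:
            raise ValueError("world needs at least 2 drugs and 2 targets")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0.0 < self.density < 0.5):
            raise ValueError("density must lie in (0, 0.5)")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category_proportions must sum to 1")
        if min(self.category_proportions) < 0:
            raise ValueError("category_proportions must be non-negative")
        if self.link_sharpness <= 0:
            raise ValueError("link_sharpness must be positive")
        if not (0.0 < self.pathway_base_prob <= 1.0):
            raise ValueError("pathway_base_prob must lie in (0, 1]")
        for index, category, mult in self.planted:
            if not (0 <= index < self.n_pathways):
                raise ValueError(f"planted pathway index {index} out of range")
            if category not in CATEGORIES:
                raise ValueError(f"planted category {category!r} unknown")
            if mult <= 0:
                raise ValueError("odds_multiplier must be positive")
            if self.pathway_base_prob * mult > 1.0:
                raise ValueError(
                    f"infeasible plant: base probability {self.pathway_base_prob} x "
                    f"odds_multiplier {mult} exceeds 1"
                )


@dataclass
class GroundTruth:
    """A generated world plus everything needed to score recovery."""

    config: WorldConfig
    u_true: np.ndarray  # D x N
    v_true: np.ndarray  # D x M
    propensity: np.ndarray  # N x M inclusion propensity sigma(u.v + noise)
    catalog: DrugCatalog
    targets: TargetCatalog
    interactions: InteractionSet  # realized known edges at config.density
    pathway_collection: GeneSetCollection
    planted_sets: dict[str, tuple[str, float]]  # set_id -> (category, multiplier)


def _stream(config: WorldConfig, name: str) -> np.random.Generator:
    index = _STREAMS.index(name)
    return np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[index]
    )


def _category_labels(config: WorldConfig, rng: np.random.Generator) -> list[str]:
    # Largest-remainder apportionment, then a random permutation: category
    # counts track the stated proportions exactly (225 -> 174/31/20).
    n = config.n_drugs
    raw = np.array(config.category_proportions) * n
    counts = np.floor(raw).astype(int)
    for _ in range(n - counts.sum()):
        counts[int(np.argmax(raw - counts))] += 1
    labels = np.repeat(np.array(CATEGORIES), counts)
    return list(labels[rng.permutation(n)])


def _edge_probabilities(propensity: np.ndarray, density: float) -> np.ndarray:
    """Per-pair inclusion probabilities proportional to propensity.

    The scale is adjusted iteratively (probabilities saturate at 1) so the
    expected edge count equals density * N * M whenever feasible.
    """
    n, m = propensity.shape
    target = density * n * m
    scale = target / propensity.sum()
    for _ in range(100):
        prob = np.minimum(scale * propensity, 1.0)
        gap = target - prob.sum()
        free = propensity[scale * propensity < 1.0].sum()
        if abs(gap) < 1e-9 or free == 0:
            break
        scale += gap / free
    return np.minimum(scale * propensity, 1.0)


def _sample_edges(
    propensity: np.ndarray,
    density: float,
    rng: np.random.Generator,
    drug_ids: Sequence[str],
    target_ids: Sequence[str],
) -> InteractionSet:
    if density <= 0:
        raise ValueError("density must be positive")
    prob = _edge_probabilities(propensity, density)
    if prob.sum() < 10:
        raise ValueError("degenerate world: expected interaction count < 10")
    hit = rng.random(prob.shape) < prob
    rows, cols = np.nonzero(hit)
    pairs = [(drug_ids[i], target_ids[j]) for i, j in zip(rows, cols)]
    return InteractionSet.from_pairs(pairs, provenance="known", confidence=1.0)


def generate_world(config: WorldConfig) -> GroundTruth:
    """Draw one complete world from the generative model.

    Latent factors are i.i.d. standard normal; the pair (i, j) propensity is
    a logistic of the factor inner product plus Gaussian noise of scale
    noise_sd; fingerprints share more bits between drugs with similar latent
    vectors (bit b of drug i fires with probability sigma(w_b . u_i) for
    fixed random projections w_b); pathway membership is Bernoulli at
    pathway_base_prob, multiplied by the plant's odds_multiplier for targets
    interacting with drugs of the planted category.
    """
    config.validate()

    rng_f = _stream(config, "factors")
    d, n, m = config.latent_dim, config.n_drugs, config.n_targets
    u_true = rng_f.standard_normal((d, n))
    v_true = rng_f.standard_normal((d, m))
    # Binding is rare and near-deterministic: the negative offset makes high
    # propensity the exception, the sharpness pushes pairs toward clearly
    # interacting or clearly not. Both are needed for the planted low-rank
    # structure to be recoverable from a sparse positive-only sample.
    noise = config.noise_sd * rng_f.standard_normal((n, m))
    propensity = _sigmoid(
        config.link_sharpness * (u_true.T @ v_true + noise + config.link_offset)
    )

    drug_ids = [f"D{i:04d}" for i in range(1, n + 1)]
    target_ids = [f"T{j:04d}" for j in range(1, m + 1)]

    labels = _category_labels(config, _stream(config, "categories"))

    rng_fp = _stream(config, "fingerprints")
    f = config.fingerprint_length
    projections = rng_fp.standard_normal((f, d)) / np.sqrt(d)
    bit_prob = _sigmoid(projections @ u_true)  # F x N
    bits = (rng_fp.random((f, n)) < bit_prob).astype(np.uint8)
    # Tanimoto needs at least one set bit per drug; force the likeliest bit on
    # in the (vanishingly rare) all-zero column.
    empty = bits.sum(axis=0) == 0
    if empty.any():
        bits[np.argmax(bit_prob[:, empty], axis=0), np.nonzero(empty)[0]] = 1

    catalog = DrugCatalog(
        [
            DrugRecord(drug_ids[i], f"drug-{i + 1}", labels[i], fingerprint=bits[:, i])
            for i in range(n)
        ]
    )
    targets = TargetCatalog([TargetRecord(t) for t in target_ids])

    interactions = _sample_edges(
        propensity, config.density, _stream(config, "interactions"), drug_ids, target_ids
    )

    # Per-category realized target sets drive the plants.
    by_category: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for drug, target in zip(
        interactions.edges["drug_id"], interactions.edges["target_id"]
    ):
        by_category[catalog.category_of(drug)].add(target)

    rng_pw = _stream(config, "pathways")
    target_array = np.array(target_ids)
    member_prob = np.full((config.n_pathways, m), config.pathway_base_prob)
    planted_sets: dict[str, tuple[str, float]] = {}
    width = max(4, len(str(config.n_pathways)))
    set_ids = [f"PW{k:0{width}d}" for k in range(1, config.n_pathways + 1)]
    for index, category, mult in config.planted:
        hit = np.isin(target_array, sorted(by_category[category]))
        member_prob[index, hit] = config.pathway_base_prob * mult
        planted_sets[set_ids[index]] = (category, mult)

    draws = rng_pw.random((config.n_pathways, m)) < member_prob
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for k, set_id in enumerate(set_ids):
        members = frozenset(target_array[draws[k]])
        if not members:  # keep the declared set count: give it one member
            members = frozenset([target_array[int(rng_pw.integers(m))]])
        sets[set_id] = (f"synthetic pathway {k + 1}", members)
    collection = GeneSetCollection(sets, frozenset(target_ids))

    return GroundTruth(
        config=config,
        u_true=u_true,
        v_true=v_true,
        propensity=propensity,
        catalog=catalog,
        targets=targets,
        interactions=interactions,
        pathway_collection=collection,
        planted_sets=planted_sets,
    )


def sample_observed_interactions(
    truth: GroundTruth, density: float | None = None, seed: int | None = None
) -> InteractionSet:
    """Sample a known-positive edge set from the world's propensities.

    Pair (i, j) is included with probability proportional to its logistic
    propensity, rescaled so the expected edge count is density*N*M. With the
    default density and seed this reproduces exactly the edge set stored on
    the world.
    """
    config = truth.config
    if density is None:
        density = config.density
    if density is not None and density <= 0:
        raise ValueError("density must be positive")
    rng = (
        _stream(config, "interactions")
        if seed is None
        else np.random.default_rng(seed)
    )
    return _sample_edges(
        truth.propensity,
        density,
        rng,
        [r.drug_id for r in truth.catalog],
        [t.target_id for t in truth.targets],
    )


def write_world(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Serialize a world to the standard pipeline input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": outdir / "drugs.tsv",
        "targets": outdir / "targets.tsv",
        "edges": outdir / "edges.tsv",
        "gene_sets": outdir / "pathways.gmt",
        "universe": outdir / "universe.txt",
    }
    write_drug_catalog(truth.catalog, paths["drugs"])
    write_target_catalog(truth.targets, paths["targets"])
    write_interactions(truth.interactions, paths["edges"])
    write_gene_sets(truth.pathway_collection, paths["gene_sets"])
    write_id_list(sorted(truth.pathway_collection.universe), paths["universe"])
    return paths


def load_world_config(path: str | Path) -> WorldConfig:
    """Read a key=value config file; '#' comments and blank lines ignored.

    planted is a comma-separated list of index:category:multiplier triples,
    e.g. ``planted = 3:activator:4.0,7:inhibitor:3.0``.
    """
    values: dict[str, object] = {}
    casts = {
        "n_drugs": int, "n_targets": int, "latent_dim": int, "n_pathways": int,
        "fingerprint_length": int, "seed": int, "density": float,
        "noise_sd": float, "pathway_base_prob": float,
    }
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {line_number}: expected key = value")
            key, _, text = line.partition("=")
            key, text = key.strip(), text.strip()
            if key in casts:
                values[key] = casts[key](text)
            elif key == "category_proportions":
                values[key] = tuple(float(x) for x in text.split(","))
            elif key == "planted":
                plants = []
                for chunk in filter(None, (c.strip() for c in text.split(","))):
                    index, category, mult = chunk.split(":")
                    plants.append((int(index), category, float(mult)))
                values[key] = tuple(plants)
            else:
                raise ValueError(f"{path}: line {line_number}: unknown key {key!r}")
    config = WorldConfig(**values)  # type: ignore[arg-type]
    config.validate()
    return config
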