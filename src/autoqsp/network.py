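"""Bipartite-network summaries and top-level pipeline orchestration.

The drug–target relation is viewed as a bipartite network. The degree of
a modulator — its number of targets — measures its promiscuity; targets
hit by at least ``min_modulators`` known modulators (default 5) are the
"frequent targets"; and the three category target sets partition into
seven disjoint overlap regions (the Venn regions of activator, inhibitor
and dual-modulator target sets).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_data, enrichment, pmf, similarity
from .core_data import (
    CATEGORIES,
    DrugCatalog,
    InteractionSet,
    TargetCatalog,
    build_matrix,
)

logger = logging.getLogger("autoqsp")

DEFAULT_MIN_MODULATORS = 5
#: Degree bins of the promiscuity histogram: 1, 2-4, 5-9, >= 10 targets.
DEFAULT_DEGREE_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 1),
    (2, 4),
    (5, 9),
    (10, None),
)


# ---------------------------------------------------------------------------
# Degrees and promiscuity
# ---------------------------------------------------------------------------

def modulator_degrees(interactions: InteractionSet, catalog: DrugCatalog) -> pd.DataFrame:
    """Per-drug known/predicted/total target counts, category attached.

    Drugs without any edge appear with degree 0.
    """
    edges = interactions.edges
    counts = (
        edges.groupby(["drug_id", "provenance"]).size().unstack(fill_value=0)
        if len(edges)
        else pd.DataFrame()
    )
    rows = []
    for rec in catalog:
        known = int(counts.at[rec.drug_id, "known"]) if (
            len(counts) and rec.drug_id in counts.index and "known" in counts
        ) else 0
        predicted = int(counts.at[rec.drug_id, "predicted"]) if (
            len(counts) and rec.drug_id in counts.index and "predicted" in counts
        ) else 0
        rows.append((rec.drug_id, rec.category, known, predicted, known + predicted))
    return pd.DataFrame(
        rows,
        columns=["drug_id", "category", "known_degree", "predicted_degree", "total_degree"],
    )


def target_degrees(interactions: InteractionSet, targets: TargetCatalog) -> pd.DataFrame:
    """Per-target known/predicted/total modulator counts."""
    edges = interactions.edges
    counts = (
        edges.groupby(["target_id", "provenance"]).size().unstack(fill_value=0)
        if len(edges)
        else pd.DataFrame()
    )
    rows = []
    for rec in targets:
        known = int(counts.at[rec.target_id, "known"]) if (
            len(counts) and rec.target_id in counts.index and "known" in counts
        ) else 0
        predicted = int(counts.at[rec.target_id, "predicted"]) if (
            len(counts) and rec.target_id in counts.index and "predicted" in counts
        ) else 0
        rows.append((rec.target_id, known, predicted, known + predicted))
    return pd.DataFrame(
        rows, columns=["target_id", "known_degree", "predicted_degree", "total_degree"]
    )


def mean_degrees(
    degrees: pd.DataFrame, column: str = "known_degree", exclude: tuple[str, ...] = ()
) -> dict[str, float]:
    """Mean degree per category, to 1 decimal place (the reporting precision).

    ``exclude`` removes named drugs (e.g. a single extreme outlier) before
    averaging.
    """
    sub = degrees[~degrees["drug_id"].isin(exclude)]
    out = {}
    for category, group in sub.groupby("category"):
        out[category] = round(float(group[column].mean()), 1)
    return out


def promiscuity_histogram(
    degrees: pd.DataFrame,
    bins: tuple[tuple[int, int | None], ...] = DEFAULT_DEGREE_BINS,
    column: str = "known_degree",
) -> pd.DataFrame:
    """Binned degree counts and percentages per category.

    Degree-0 drugs fall outside every bin and are excluded from the
    percentages; percentages sum to 100 per non-empty category.
    """
    rows = []
    for category in CATEGORIES:
        sub = degrees[degrees["category"] == category]
        in_bins = []
        for lo, hi in bins:
            mask = sub[column] >= lo
            if hi is not None:
                mask &= sub[column] <= hi
            in_bins.append(int(mask.sum()))
        total = sum(in_bins)
        for (lo, hi), count in zip(bins, in_bins):
            label = f"{lo}" if hi == lo else (f"{lo}+" if hi is None else f"{lo}-{hi}")
            pct = 100.0 * count / total if total else 0.0
            rows.append((category, label, count, pct))
    return pd.DataFrame(rows, columns=["category", "bin", "count", "percent"])


# ---------------------------------------------------------------------------
# Frequent targets and category overlap
# ---------------------------------------------------------------------------

def frequent_targets(
    interactions: InteractionSet,
    catalog: DrugCatalog,
    min_modulators: int = DEFAULT_MIN_MODULATORS,
) -> pd.DataFrame:
    """Targets hit by >= min_modulators known modulators.

    Known counts decide inclusion; predicted-edge counts are annotated
    separately. One row per frequent target with the per-category split.
    """
    edges = interactions.edges
    known = edges[edges["provenance"] == "known"].copy()
    predicted = edges[edges["provenance"] == "predicted"]
    if len(known):
        known["category"] = [catalog.category_of(d) for d in known["drug_id"]]
    pred_counts = predicted.groupby("target_id").size() if len(predicted) else pd.Series(dtype=int)
    rows = []
    grouped = known.groupby("target_id") if len(known) else ()
    for target_id, group in grouped:
        n_known = len(group)
        if n_known < min_modulators:
            continue
        by_cat = group["category"].value_counts()
        rows.append(
            (
                target_id,
                n_known,
                int(by_cat.get("activator", 0)),
                int(by_cat.get("inhibitor", 0)),
                int(by_cat.get("dual", 0)),
                int(pred_counts.get(target_id, 0)),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "n_known_modulators",
            "activator",
            "inhibitor",
            "dual",
            "n_predicted_modulators",
        ],
    )
    return frame.sort_values(
        ["n_known_modulators", "target_id"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class OverlapPartition:
    """The seven disjoint Venn regions of the three category target sets."""

    activator_only: int
    inhibitor_only: int
    dual_only: int
    activator_inhibitor: int
    activator_dual: int
    inhibitor_dual: int
    all_three: int
    union_size: int

    def regions(self) -> dict[str, int]:
        return {
            "activator_only": self.activator_only,
            "inhibitor_only": self.inhibitor_only,
            "dual_only": self.dual_only,
            "activator_inhibitor": self.activator_inhibitor,
            "activator_dual": self.activator_dual,
            "inhibitor_dual": self.inhibitor_dual,
            "all_three": self.all_three,
        }

    def __post_init__(self) -> None:
        regions = self.regions()
        if min(regions.values()) < 0 or sum(regions.values()) != self.union_size:
            raise ValueError("overlap regions must be non-negative and sum to the union")


def category_overlap(
    interactions: InteractionSet,
    catalog: DrugCatalog,
    include_predicted: bool = False,
) -> OverlapPartition:
    """Partition the targets by which categories reach them."""
    sets = enrichment.category_target_sets(catalog, interactions, include_predicted)
    a, i, d = sets["activator"], sets["inhibitor"], sets["dual"]
    return OverlapPartition(
        activator_only=len(a - i - d),
        inhibitor_only=len(i - a - d),
        dual_only=len(d - a - i),
        activator_inhibitor=len((a & i) - d),
        activator_dual=len((a & d) - i),
        inhibitor_dual=len((i & d) - a),
        all_three=len(a & i & d),
        union_size=len(a | i | d),
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs, hyperparameters and thresholds for one full run."""

    drugs: str | Path
    edges: str | Path
    gene_sets: str | Path
    outdir: str | Path
    universe: str | Path | None = None
    latent_dim: int = pmf.DEFAULT_LATENT_DIM
    lambda_u: float = 0.05
    lambda_v: float = 0.05
    epochs: int = 200
    learning_rate: float = 0.01
    neg_ratio: float = 1.0
    threshold: float = pmf.DEFAULT_THRESHOLD
    top_k: int = pmf.DEFAULT_TOP_K
    min_modulators: int = DEFAULT_MIN_MODULATORS
    alpha: float = enrichment.DEFAULT_ALPHA
    seed: int = 0
    predict: bool = True
    structural_similarity: bool = True


@dataclass
class PipelineResult:
    catalog: DrugCatalog
    targets: TargetCatalog
    known: InteractionSet
    combined: InteractionSet
    predictions: pmf.PredictionList | None
    outputs: dict[str, Path]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """load -> factorize -> predict -> similarity -> enrichment -> summaries.

    Every output is a TSV under config.outdir plus a plain-text manifest
    of inputs, hyperparameters, seed and thresholds. A failure in any
    stage aborts with the stage name. Two runs with identical config and
    seed produce byte-identical output bundles.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        logger.info("stage %s", stage)
        catalog = core_data.load_drug_catalog(config.drugs)
        frame = core_data._read_tsv(config.edges, ("drug_id", "target_id"))
        target_ids = sorted(set(frame["target_id"]))
        targets = TargetCatalog([core_data.TargetRecord(t) for t in target_ids])
        known = core_data.load_interactions(config.edges, catalog, targets)
        universe = (
            core_data.load_id_list(config.universe) if config.universe else None
        )
        collection = core_data.load_gene_sets(config.gene_sets, universe)

        predictions = None
        combined = known
        if config.predict:
            stage = "predict"
            logger.info("stage %s", stage)
            matrix = build_matrix(known, catalog, targets)
            model = pmf.fit_pmf(
                matrix,
                latent_dim=config.latent_dim,
                lambda_u=config.lambda_u,
                lambda_v=config.lambda_v,
                epochs=config.epochs,
                learning_rate=config.learning_rate,
                neg_ratio=config.neg_ratio,
                seed=config.seed,
            )
            confidences = pmf.score_pairs(model)
            predictions = pmf.select_predictions(
                confidences,
                matrix.row_index,
                matrix.col_index,
                known,
                threshold=config.threshold,
                top_k=config.top_k,
            )
            combined = known.merged_with(predictions.as_interactions())
            outputs["predictions"] = outdir / "predictions.tsv"
            _write_tsv(predictions.frame, outputs["predictions"])

        stage = "similarity"
        logger.info("stage %s", stage)
        functional = similarity.similarity_matrix(catalog, known, "functional_cosine")
        outputs["similarity_functional"] = outdir / "similarity_functional.tsv"
        _write_similarity(functional, outputs["similarity_functional"])
        has_structures = any(
            r.fingerprint is not None or r.smiles for r in catalog
        )
        if config.structural_similarity and has_structures:
            structural = similarity.similarity_matrix(catalog, None, "structural_tanimoto")
            outputs["similarity_structural"] = outdir / "similarity_structural.tsv"
            _write_similarity(structural, outputs["similarity_structural"])

        stage = "enrichment"
        logger.info("stage %s", stage)
        for label, edge_set in [("known", known), ("combined", combined)]:
            if label == "combined" and not config.predict:
                continue
            per_category = enrichment.enrich_by_category(
                catalog, edge_set, collection, include_predicted=(label == "combined")
            )
            for category, results in per_category.items():
                key = f"enrichment_{label}_{category}"
                outputs[key] = outdir / f"{key}.tsv"
                _write_tsv(enrichment.results_frame(results), outputs[key])

        stage = "summaries"
        logger.info("stage %s", stage)
        degrees = modulator_degrees(combined, catalog)
        outputs["degrees_drugs"] = outdir / "degrees_drugs.tsv"
        _write_tsv(degrees, outputs["degrees_drugs"])
        outputs["degrees_targets"] = outdir / "degrees_targets.tsv"
        _write_tsv(target_degrees(combined, targets), outputs["degrees_targets"])
        outputs["promiscuity_histogram"] = outdir / "promiscuity_histogram.tsv"
        _write_tsv(promiscuity_histogram(degrees), outputs["promiscuity_histogram"])
        outputs["frequent_targets"] = outdir / "frequent_targets.tsv"
        _write_tsv(
            frequent_targets(combined, catalog, config.min_modulators),
            outputs["frequent_targets"],
        )
        overlap = category_overlap(combined, catalog)
        outputs["category_overlap"] = outdir / "category_overlap.tsv"
        regions = overlap.regions() | {"union": overlap.union_size}
        _write_tsv(
            pd.DataFrame(regions.items(), columns=["region", "count"]),
            outputs["category_overlap"],
        )

        stage = "manifest"
        outputs["manifest"] = outdir / "manifest.txt"
        _write_manifest(config, known, combined, outputs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(catalog, targets, known, combined, predictions, outputs)


def _write_similarity(matrix: similarity.SimilarityMatrix, path: Path) -> None:
    frame = pd.DataFrame(matrix.values, index=list(matrix.index), columns=list(matrix.index))
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n", index_label="drug_id")


def _write_manifest(
    config: PipelineConfig,
    known: InteractionSet,
    combined: InteractionSet,
    outputs: dict[str, Path],
) -> None:
    lines = ["[inputs]"]
    for key in ("drugs", "edges", "gene_sets", "universe"):
        lines.append(f"{key} = {getattr(config, key)}")
    lines.append("[hyperparameters]")
    for key in (
        "latent_dim", "lambda_u", "lambda_v", "epochs", "learning_rate",
        "neg_ratio", "seed",
    ):
        lines.append(f"{key} = {getattr(config, key)}")
    lines.append("[thresholds]")
    for key in ("threshold", "top_k", "min_modulators", "alpha"):
        lines.append(f"{key} = {getattr(config, key)}")
    lines.append("[counts]")
    lines.append(f"known_edges = {len(known)}")
    lines.append(f"predicted_edges = {len(combined) - len(known)}")
    lines.append("[outputs]")
    for key in sorted(k for k in outputs if k != "manifest"):
        lines.append(f"{key} = {outputs[key].name}")
    outputs["manifest"].write_text("\n".join(lines) + "\n", encoding="utf-8")


def bundle_digest(outputs: dict[str, Path]) -> str:
    """SHA-256 over the concatenated bytes of every output, in key order."""
    digest = hashlib.sha256()
    for key in sorted(outputs):
        digest.update(key.encode())
        digest.update(outputs[key].read_bytes())
    return digest.hexdigest()
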