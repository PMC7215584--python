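"""Structural and functional drug–drug similarity.

Structural similarity is the Tanimoto coefficient |a AND b| / |a OR b|
between binary 2D fingerprints (precomputed bit vectors take precedence;
drugs carrying only SMILES get a 2048-bit radius-2 circular fingerprint).
Functional similarity compares interaction patterns: each drug i is the
0/1 vector d_i of its known targets, and the cosine distance
1 - (d_i . d_j)/(|d_i| |d_j|) is reported as similarity = 1 - distance
for heatmap comparability. Drugs without the required input (no
structure, or no known target) are excluded, not imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .core_data import DrugCatalog, InteractionSet

logger = logging.getLogger("autoqsp")

KINDS = ("structural_tanimoto", "functional_cosine")


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if not np.isin(arr, (0, 1, False, True)).all():
        raise ValueError(f"{name} must be binary")
    return arr.astype(np.uint8)


def tanimoto_similarity(fp_a, fp_b) -> float:
    """|a AND b| / |a OR b| for equal-length binary fingerprints."""
    a = _as_binary(fp_a, "fp_a")
    b = _as_binary(fp_b, "fp_b")
    if a.size != b.size:
        raise ValueError("fingerprints have different lengths")
    union = int(np.sum(a | b))
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("Tanimoto undefined for an all-zero fingerprint")
    return float(np.sum(a & b) / union)


def tanimoto_distance(fp_a, fp_b) -> float:
    return 1.0 - tanimoto_similarity(fp_a, fp_b)


def interaction_cosine_distance(d_i, d_j) -> float:
    """1 - (d_i . d_j)/(|d_i| |d_j|); in [0, 1] for binary vectors."""
    a = _as_binary(d_i, "d_i").astype(float)
    b = _as_binary(d_j, "d_j").astype(float)
    if a.size != b.size:
        raise ValueError("interaction vectors have different lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a drug with no targets")
    return float(1.0 - (a @ b) / (na * nb))


@dataclass
class SimilarityMatrix:
    """Symmetric drug–drug similarity with unit diagonal."""

    values: np.ndarray
    kind: str
    index: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.index), len(self.index)):
            raise ValueError("matrix shape does not match index length")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("similarity matrix is not symmetric")
        if len(self.index) and (
            np.abs(np.diag(v) - 1.0).max() > 1e-12 or v.min() < -1e-12 or v.max() > 1 + 1e-12
        ):
            raise ValueError("similarity values must lie in [0, 1] with unit diagonal")
        self.values = v


def _fingerprint_block(catalog: DrugCatalog) -> tuple[np.ndarray, list[str]]:
    """Stack available fingerprints, computing them from SMILES if needed."""
    rows, ids = [], []
    width = catalog.fingerprint_length or 2048
    for rec in catalog:
        fp = rec.fingerprint
        if fp is None and rec.smiles:
            fp = _fingerprint_from_smiles(rec.smiles, width)
        if fp is None or fp.sum() == 0:
            continue
        rows.append(fp.astype(np.int64))
        ids.append(rec.drug_id)
    if len(ids) < len(catalog):
        logger.info(
            "structural similarity: excluded %d drugs without usable structures",
            len(catalog) - len(ids),
        )
    return (np.array(rows) if rows else np.empty((0, width), dtype=np.int64)), ids


def _fingerprint_from_smiles(smiles: str, n_bits: int) -> np.ndarray | None:
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ImportError("rdkit is required to fingerprint SMILES input") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=np.uint8)


def similarity_matrix(
    catalog: DrugCatalog,
    interactions: InteractionSet | None = None,
    kind: str = "structural_tanimoto",
) -> SimilarityMatrix:
    """Full symmetric similarity matrix over the eligible drugs."""
    if kind == "structural_tanimoto":
        block, ids = _fingerprint_block(catalog)
        if len(ids) < 2:
            raise ValueError("structural similarity needs >= 2 drugs with structures")
        inter = block @ block.T
        counts = block.sum(axis=1)
        union = counts[:, None] + counts[None, :] - inter
        values = inter / union
    elif kind == "functional_cosine":
        if interactions is None:
            raise ValueError("functional similarity requires an interaction set")
        known = interactions.known()
        targets = sorted(known.target_ids())
        t_pos = {t: j for j, t in enumerate(targets)}
        ids, rows = [], []
        by_drug: dict[str, set[str]] = {}
        for d, t in known.pairs():
            by_drug.setdefault(d, set()).add(t)
        for rec in catalog:
            hit = by_drug.get(rec.drug_id)
            if not hit:
                continue
            vec = np.zeros(len(targets))
            vec[[t_pos[t] for t in hit]] = 1.0
            rows.append(vec)
            ids.append(rec.drug_id)
        skipped = len(catalog) - len(ids)
        if skipped:
            logger.info(
                "functional similarity: excluded %d drugs with no known targets", skipped
            )
        if len(ids) < 2:
            raise ValueError("functional similarity needs >= 2 drugs with known targets")
        block = np.array(rows)
        norms = np.linalg.norm(block, axis=1)
        values = (block @ block.T) / np.outer(norms, norms)
    else:
        raise ValueError(f"unknown similarity kind {kind!r}")

    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, kind, tuple(ids))


def heatmap_order(matrix: SimilarityMatrix) -> list[str]:
    """Leaf order of average-linkage clustering on 1 - similarity.

    Reproduces the clustered-heatmap presentation at the ordering level;
    deterministic for a given matrix.
    """
    n = len(matrix.index)
    if n <= 1:
        return list(matrix.index)
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    order = leaves_list(linkage(condensed, method="average"))
    return [matrix.index[i] for i in order]
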