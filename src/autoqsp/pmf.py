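"""Probabilistic matrix factorization for drug–target interaction prediction.

The sparse 0/1 interaction matrix R (N drugs x M targets) is decomposed as
R ~ U^T V with D latent variables per drug and per target. Training
minimises the regularised squared reconstruction error

    sum_observed (R_ij - U_i . V_j)^2 + lambda_u ||U||^2 + lambda_v ||V||^2

by stochastic gradient descent. Because the data are positive-only, the
observed set each epoch is the known positives (value 1) plus
``neg_ratio`` x |positives| unobserved pairs freshly sampled as soft
negatives (value 0); resampling avoids committing to any fixed set of
presumed non-interactions. The reconstruction U^T V, clamped to [0, 1],
is the confidence score of an unobserved pair; candidate interactions are
kept when their confidence strictly exceeds a threshold (default 0.6)
within each drug's top-k (default 40) ranked unknown pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from scipy.stats import rankdata

from .core_data import BinaryMatrix, InteractionSet

#: Defaults mirroring the published selection rule.
DEFAULT_THRESHOLD = 0.6
DEFAULT_TOP_K = 40
DEFAULT_LATENT_DIM = 50


@dataclass
class LatentModel:
    """Fitted factor matrices plus the training trace."""

    u: np.ndarray  # D x N
    v: np.ndarray  # D x M
    latent_dim: int
    lambda_u: float
    lambda_v: float
    training_log: list[float]
    seed: int
    row_index: tuple[str, ...]
    col_index: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("latent factors contain non-finite entries")
        if not self.training_log:
            raise ValueError("training_log is empty: model was not fitted")

    def raw_scores(self) -> np.ndarray:
        """Unclamped reconstruction U^T V."""
        return self.u.T @ self.v


def _sample_unobserved(
    rng: np.random.Generator, n: int, m: int, forbidden: np.ndarray, count: int
) -> np.ndarray:
    """Sample `count` linear pair codes outside the sorted `forbidden` codes."""
    total = n * m
    if count > total - forbidden.size:
        count = total - forbidden.size
    out = np.empty(0, dtype=np.int64)
    while out.size < count:
        draw = rng.integers(0, total, size=int((count - out.size) * 1.4) + 8)
        fresh = draw[
            forbidden[np.searchsorted(forbidden, draw).clip(max=forbidden.size - 1)] != draw
        ]
        out = np.concatenate([out, fresh])
    return out[:count]


def fit_pmf(
    matrix: BinaryMatrix,
    latent_dim: int = DEFAULT_LATENT_DIM,
    lambda_u: float = 0.05,
    lambda_v: float = 0.05,
    epochs: int = 200,
    learning_rate: float = 0.01,
    neg_ratio: float = 1.0,
    seed: int = 0,
    tol: float = 1e-5,
    patience: int = 10,
    init: str = "svd",
) -> LatentModel:
    """Fit the factor model by SGD with per-epoch resampled soft negatives.

    The training log records, per epoch, the objective on a fixed
    evaluation set (all positives, the explicitly observed zeros, and one
    seed-fixed negative sample) so that convergence is monitored on a
    stationary quantity; training stops early once the relative change of
    that objective stays below ``tol`` for ``patience`` epochs. Identical
    inputs and seed give an identical model.
    """
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    n, m = matrix.shape
    pos_i, pos_j = np.nonzero(matrix.mask & (matrix.values == 1))
    if pos_i.size == 0:
        raise ValueError("matrix has no positive entries")
    zero_i, zero_j = np.nonzero(matrix.mask & (matrix.values == 0))
    observed_codes = np.sort(
        np.concatenate([pos_i * m + pos_j, zero_i * m + zero_j]).astype(np.int64)
    )
    n_neg = int(round(neg_ratio * pos_i.size))

    rng = np.random.default_rng(seed)
    if init == "svd" and latent_dim < min(n, m):
        # Truncated-SVD warm start of the observed 0/1 matrix (zeros where
        # unobserved); SGD then refines against the resampled negatives.
        # The start vector is seeded so the factorization is reproducible.
        left, sing, right = svds(
            matrix.values.astype(float),
            k=latent_dim,
            v0=rng.standard_normal(min(n, m)),
        )
        u = np.ascontiguousarray((left * np.sqrt(sing)).T)
        v = np.ascontiguousarray(np.sqrt(sing)[:, None] * right)
    elif init in ("svd", "random"):
        u = 0.1 * rng.standard_normal((latent_dim, n))
        v = 0.1 * rng.standard_normal((latent_dim, m))
    else:
        raise ValueError(f"unknown init {init!r}")

    eval_codes = _sample_unobserved(rng, n, m, observed_codes, n_neg)
    eval_i = np.concatenate([pos_i, zero_i, eval_codes // m])
    eval_j = np.concatenate([pos_j, zero_j, eval_codes % m])
    eval_val = np.concatenate(
        [np.ones(pos_i.size), np.zeros(zero_i.size + eval_codes.size)]
    )

    def objective() -> float:
        pred = np.einsum("di,di->i", u[:, eval_i], v[:, eval_j])
        return float(
            np.sum((eval_val - pred) ** 2)
            + lambda_u * np.sum(u**2)
            + lambda_v * np.sum(v**2)
        )

    lr = learning_rate
    log: list[float] = []
    for _epoch in range(epochs):
        neg_codes = _sample_unobserved(rng, n, m, observed_codes, n_neg)
        rows = np.concatenate([pos_i, zero_i, neg_codes // m])
        cols = np.concatenate([pos_j, zero_j, neg_codes % m])
        vals = np.concatenate(
            [np.ones(pos_i.size), np.zeros(zero_i.size + neg_codes.size)]
        )
        order = rng.permutation(rows.size)
        for k in order:
            i, j, r = rows[k], cols[k], vals[k]
            ui = u[:, i]
            vj = v[:, j]
            err = r - ui @ vj
            u[:, i] = ui + lr * (err * vj - lambda_u * ui)
            v[:, j] = vj + lr * (err * ui - lambda_v * vj)
        current = objective()
        if not np.isfinite(current):
            raise ValueError(
                "training objective diverged; try a smaller learning_rate"
            )
        log.append(current)
        if len(log) > patience:
            past = log[-patience - 1]
            if abs(past - current) <= tol * max(abs(past), 1e-12):
                break

    return LatentModel(
        u=u,
        v=v,
        latent_dim=latent_dim,
        lambda_u=lambda_u,
        lambda_v=lambda_v,
        training_log=log,
        seed=seed,
        row_index=matrix.row_index,
        col_index=matrix.col_index,
    )


def score_pairs(model: LatentModel, link: str = "clamp") -> np.ndarray:
    """Confidence matrix for every (drug, target) pair.

    The default maps the raw reconstruction into [0, 1] by clamping;
    ``link="logistic"`` applies a logistic squashing instead.
    """
    raw = model.raw_scores()
    if link == "clamp":
        return np.clip(raw, 0.0, 1.0)
    if link == "logistic":
        return 1.0 / (1.0 + np.exp(-raw))
    raise ValueError(f"unknown link {link!r}")


@dataclass
class PredictionList:
    """Novel-interaction candidates: per drug, ranked by confidence."""

    frame: pd.DataFrame  # columns drug_id, target_id, confidence, rank

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["drug_id"], self.frame["target_id"]))

    def as_interactions(self) -> InteractionSet:
        return InteractionSet.from_pairs(
            zip(self.frame["drug_id"], self.frame["target_id"]),
            provenance="predicted",
            confidence=list(self.frame["confidence"]),
        )


def select_predictions(
    confidences: np.ndarray,
    row_index: Sequence[str],
    col_index: Sequence[str],
    known: InteractionSet,
    threshold: float = DEFAULT_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
) -> PredictionList:
    """Keep, per drug, the unknown pairs ranked in the top_k by confidence
    whose confidence strictly exceeds the threshold.

    Known pairs are never re-emitted. Ties are broken by target id
    (lexicographic) so the ranking is deterministic.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    confidences = np.asarray(confidences, dtype=float)
    col_array = np.array(col_index)
    col_order = np.argsort(col_array, kind="stable")  # lexicographic tiebreak
    known_pairs = known.pairs()
    rows = []
    for i, drug in enumerate(row_index):
        conf_row = confidences[i, col_order]
        # stable sort on -confidence over lexicographically pre-sorted targets
        order = np.argsort(-conf_row, kind="stable")
        kept = 0
        for pos in order:
            if kept >= top_k:
                break
            target = col_array[col_order[pos]]
            if (drug, target) in known_pairs:
                continue
            kept += 1
            conf = conf_row[pos]
            if conf > threshold:
                rows.append((drug, target, float(conf), kept))
    frame = pd.DataFrame(rows, columns=["drug_id", "target_id", "confidence", "rank"])
    return PredictionList(frame)


def evaluate_holdout(
    model: LatentModel,
    held_out_positives: Iterable[tuple[str, str]],
    sampled_negatives: Iterable[tuple[str, str]],
) -> float:
    """Rank-based AUC of confidences, positives vs negatives; ties score 0.5."""
    conf = score_pairs(model)
    row_pos = {d: i for i, d in enumerate(model.row_index)}
    col_pos = {t: j for j, t in enumerate(model.col_index)}

    def scores(pairs: Iterable[tuple[str, str]]) -> np.ndarray:
        return np.array([conf[row_pos[d], col_pos[t]] for d, t in pairs], dtype=float)

    pos = scores(held_out_positives)
    neg = scores(sampled_negatives)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative evaluation pairs are required")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2)
        / (pos.size * neg.size)
    )


# ---------------------------------------------------------------------------
# Evaluation plumbing: hold-out splits and negative sampling
# ---------------------------------------------------------------------------

def holdout_split(
    interactions: InteractionSet, fraction: float = 0.1, seed: int = 0
) -> tuple[InteractionSet, list[tuple[str, str]]]:
    """Split known edges into a training set and held-out positive pairs."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    known = interactions.known()
    edges = known.edges.sort_values(["drug_id", "target_id"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n_held = max(1, int(round(fraction * len(edges))))
    held_idx = rng.choice(len(edges), size=n_held, replace=False)
    held_mask = np.zeros(len(edges), dtype=bool)
    held_mask[held_idx] = True
    train = InteractionSet(edges[~held_mask])
    held = list(zip(edges.loc[held_mask, "drug_id"], edges.loc[held_mask, "target_id"]))
    if len(train) == 0:
        raise ValueError("hold-out fraction leaves no training edges")
    return train, held


def sample_negative_pairs(
    interactions: InteractionSet,
    row_index: Sequence[str],
    col_index: Sequence[str],
    count: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniformly sample pairs that are not edges (any provenance)."""
    rng = np.random.default_rng(seed)
    m = len(col_index)
    row_lookup = {d: i for i, d in enumerate(row_index)}
    col_lookup = {t: j for j, t in enumerate(col_index)}
    codes = np.sort(
        np.array(
            [
                row_lookup[d] * m + col_lookup[t]
                for d, t in interactions.pairs()
                if d in row_lookup and t in col_lookup
            ],
            dtype=np.int64,
        )
    )
    if codes.size == 0:
        codes = np.array([-1], dtype=np.int64)
    drawn = _sample_unobserved(rng, len(row_index), m, codes, count)
    return [(row_index[c // m], col_index[c % m]) for c in drawn]
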