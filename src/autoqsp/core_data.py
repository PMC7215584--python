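"""Domain types and file I/O for the drug–target analysis pipeline.

All tabular inputs are tab-separated UTF-8 with a required header row;
lines starting with ``#`` are ignored. Gene-set collections use the
standard GMT dialect (set id, description, members). Identifiers are
opaque case-sensitive strings — no symbol normalisation is attempted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("autoqsp")

#: The three modulator classes. "dual" is itself a class, not a pair of
#: memberships: a drug belongs to exactly one category.
CATEGORIES: tuple[str, ...] = ("activator", "inhibitor", "dual")

#: Default fingerprint width when structures are folded to bit vectors.
DEFAULT_FINGERPRINT_LENGTH = 2048


# ---------------------------------------------------------------------------
# Records and catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugRecord:
    """One modulator: id, display name, category, optional structure.

    ``fingerprint`` is a 0/1 ``uint8`` vector; when present its length must
    match every other fingerprint in the catalog.
    """

    drug_id: str
    name: str
    category: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for drug {self.drug_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if fp.ndim != 1 or not np.isin(fp, (0, 1)).all():
                raise ValueError(f"fingerprint of {self.drug_id!r} is not a 0/1 vector")
            object.__setattr__(self, "fingerprint", fp)


@dataclass(frozen=True)
class TargetRecord:
    """One target protein; ``family`` is pass-through annotation."""

    target_id: str
    family: str | None = None


class _Catalog:
    """Ordered, uniquely keyed collection of records."""

    _key: str

    def __init__(self, records: Iterable) -> None:
        self.records = list(records)
        index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            key = getattr(rec, self._key)
            if key in index:
                raise ValueError(f"duplicate {self._key} {key!r}")
            index[key] = pos
        self._index = index

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def __getitem__(self, key: str):
        return self.records[self._index[key]]

    def position(self, key: str) -> int:
        return self._index[key]

    def __eq__(self, other) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return _records_equal(self.records, other.records)


def _records_equal(a: Sequence, b: Sequence) -> bool:
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        for f in x.__dataclass_fields__:
            u, v = getattr(x, f), getattr(y, f)
            if isinstance(u, np.ndarray) or isinstance(v, np.ndarray):
                if u is None or v is None or not np.array_equal(u, v):
                    return False
            elif u != v:
                return False
    return True


class DrugCatalog(_Catalog):
    """All modulators of a study, in stable input order."""

    _key = "drug_id"

    def __init__(self, records: Iterable[DrugRecord]) -> None:
        super().__init__(records)
        lengths = {len(r.fingerprint) for r in self.records if r.fingerprint is not None}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent fingerprint lengths in catalog: {sorted(lengths)}")
        self.fingerprint_length: int | None = lengths.pop() if lengths else None

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for rec in self.records:
            counts[rec.category] += 1
        return counts

    def category_of(self, drug_id: str) -> str:
        return self[drug_id].category


class TargetCatalog(_Catalog):
    _key = "target_id"


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

PROVENANCES = ("known", "predicted")


class InteractionSet:
    """Bipartite drug–target edges, each flagged known or predicted.

    Known edges carry confidence 1.0; predicted edges carry the model's
    confidence in [0, 1]. (drug_id, target_id) pairs are unique across
    both provenances.
    """

    COLUMNS = ("drug_id", "target_id", "provenance", "confidence")

    def __init__(self, edges: pd.DataFrame) -> None:
        frame = pd.DataFrame(edges, columns=list(self.COLUMNS)).reset_index(drop=True)
        if len(frame):
            bad_prov = set(frame["provenance"]) - set(PROVENANCES)
            if bad_prov:
                raise ValueError(f"unknown provenance values: {sorted(bad_prov)}")
            conf = frame["confidence"].to_numpy(dtype=float)
            if ((conf < 0) | (conf > 1)).any() or not np.isfinite(conf).all():
                raise ValueError("confidence values must lie in [0, 1]")
            dup = frame.duplicated(subset=["drug_id", "target_id"])
            if dup.any():
                raise ValueError(
                    f"{int(dup.sum())} duplicate (drug_id, target_id) pairs in edge set"
                )
        self.edges = frame

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        provenance: str = "known",
        confidence: float | Iterable[float] = 1.0,
    ) -> "InteractionSet":
        pairs = list(pairs)
        conf = (
            [confidence] * len(pairs)
            if np.isscalar(confidence)
            else list(confidence)
        )
        frame = pd.DataFrame(
            {
                "drug_id": [p[0] for p in pairs],
                "target_id": [p[1] for p in pairs],
                "provenance": provenance,
                "confidence": conf,
            },
            columns=list(cls.COLUMNS),
        )
        return cls(frame)

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        a = self.edges.sort_values(["drug_id", "target_id"]).reset_index(drop=True)
        b = other.edges.sort_values(["drug_id", "target_id"]).reset_index(drop=True)
        return a.equals(b)

    def known(self) -> "InteractionSet":
        return InteractionSet(self.edges[self.edges["provenance"] == "known"])

    def predicted(self) -> "InteractionSet":
        return InteractionSet(self.edges[self.edges["provenance"] == "predicted"])

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["drug_id"], self.edges["target_id"]))

    def target_ids(self) -> set[str]:
        return set(self.edges["target_id"])

    def drug_ids(self) -> set[str]:
        return set(self.edges["drug_id"])

    def merged_with(self, other: "InteractionSet") -> "InteractionSet":
        """Union of edge sets; pairs already present keep their first record."""
        combined = pd.concat([self.edges, other.edges], ignore_index=True)
        combined = combined.drop_duplicates(subset=["drug_id", "target_id"], keep="first")
        return InteractionSet(combined)

    def resolve(self, drugs: DrugCatalog, targets: TargetCatalog) -> None:
        """Raise if any edge references an id absent from the catalogs."""
        bad_d = sorted(self.drug_ids() - set(drugs.ids))
        bad_t = sorted(self.target_ids() - set(targets.ids))
        if bad_d or bad_t:
            raise ValueError(
                f"unresolvable ids in edge list: drugs={bad_d[:10]} targets={bad_t[:10]}"
            )


@dataclass
class BinaryMatrix:
    """Dense 0/1 interaction matrix with an observation mask.

    ``mask[i, j]`` is True where the entry is treated as observed during
    factorization: all known positives, plus any explicitly supplied
    negative pairs (value 0). Everything else is unobserved.
    """

    values: np.ndarray
    mask: np.ndarray
    row_index: tuple[str, ...]
    col_index: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("index lengths do not match matrix dimensions")
        observed = self.values[self.mask]
        if not np.isin(observed, (0, 1)).all():
            raise ValueError("observed entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_positive(self) -> int:
        return int(self.values[self.mask].sum())


def build_matrix(
    interactions: InteractionSet,
    drugs: DrugCatalog,
    targets: TargetCatalog,
    negatives: Iterable[tuple[str, str]] | None = None,
) -> BinaryMatrix:
    """Lay the known edges out as an N×M 0/1 matrix R.

    The observation mask covers the known positives plus any explicitly
    supplied negative pairs; by default only positives are observed and
    the factorization model samples its own soft negatives.
    """
    known = interactions.known()
    if len(known) == 0:
        raise ValueError("no known interactions: nothing to factorize")
    known.resolve(drugs, targets)
    n, m = len(drugs), len(targets)
    values = np.zeros((n, m), dtype=np.int8)
    mask = np.zeros((n, m), dtype=bool)
    for d, t in zip(known.edges["drug_id"], known.edges["target_id"]):
        i, j = drugs.position(d), targets.position(t)
        values[i, j] = 1
        mask[i, j] = True
    for d, t in negatives or ():
        i, j = drugs.position(d), targets.position(t)
        if values[i, j] == 1:
            raise ValueError(f"pair ({d}, {t}) supplied as negative but is a known positive")
        mask[i, j] = True
    return BinaryMatrix(values, mask, tuple(drugs.ids), tuple(targets.ids))


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named sets of target ids over an explicit universe.

    Pathways, GO terms and protein families are all carried by this one
    container; the enrichment engine treats them identically.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("gene-set universe is empty")
        for set_id, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {set_id!r} has {len(stray)} members outside the universe"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def load_drug_catalog(path: str | Path) -> DrugCatalog:
    """Read a modulator catalog from TSV.

    Required columns: drug_id, name, category; optional: smiles,
    fingerprint (a 0/1 bitstring). Unknown categories and duplicate ids
    are hard errors naming the offending data row.
    """
    frame = _read_tsv(path, ("drug_id", "name", "category"))
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        category = row.category
        if category not in CATEGORIES:
            raise ValueError(
                f"{path}: row {row_number}: unknown category {category!r} "
                f"(expected one of {CATEGORIES})"
            )
        smiles = getattr(row, "smiles", "") or None
        fp_text = getattr(row, "fingerprint", "")
        fingerprint = None
        if fp_text:
            if set(fp_text) - {"0", "1"}:
                raise ValueError(f"{path}: row {row_number}: fingerprint is not a 0/1 string")
            fingerprint = np.frombuffer(fp_text.encode(), dtype=np.uint8) - ord("0")
        records.append(
            DrugRecord(row.drug_id, row.name, category, smiles=smiles, fingerprint=fingerprint)
        )
    return DrugCatalog(records)


def load_target_catalog(path: str | Path) -> TargetCatalog:
    frame = _read_tsv(path, ("target_id",))
    records = [
        TargetRecord(row.target_id, getattr(row, "family", "") or None)
        for row in frame.itertuples(index=False)
    ]
    return TargetCatalog(records)


def load_interactions(
    path: str | Path, drugs: DrugCatalog, targets: TargetCatalog
) -> InteractionSet:
    """Read a known-edge list (columns drug_id, target_id), deduplicated."""
    frame = _read_tsv(path, ("drug_id", "target_id"))
    before = len(frame)
    frame = frame.drop_duplicates(subset=["drug_id", "target_id"])
    dropped = before - len(frame)
    if dropped:
        logger.info("load_interactions: dropped %d duplicate edges", dropped)
    interactions = InteractionSet.from_pairs(
        zip(frame["drug_id"], frame["target_id"]), provenance="known", confidence=1.0
    )
    interactions.resolve(drugs, targets)
    return interactions


def load_gene_sets(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (set_id <TAB> description <TAB> member...).

    Members outside a declared universe are dropped (count logged); with
    no declared universe, the universe is the union of all members.
    Lines with fewer than two fields are hard errors.
    """
    declared = frozenset(universe) if universe is not None else None
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    dropped = 0
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {line_number}: malformed GMT line (<2 fields)")
            set_id, description, *members = fields
            members = [m for m in members if m]
            if set_id in sets:
                raise ValueError(f"{path}: line {line_number}: duplicate set id {set_id!r}")
            kept = frozenset(members)
            if declared is not None:
                inside = kept & declared
                dropped += len(kept) - len(inside)
                kept = inside
            if not kept:
                logger.info("load_gene_sets: set %r empty after universe filter; skipped", set_id)
                continue
            sets[set_id] = (description, kept)
    if dropped:
        logger.info("load_gene_sets: dropped %d members outside the declared universe", dropped)
    if declared is None:
        declared = frozenset().union(*(m for _d, m in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets, declared)


def load_id_list(path: str | Path) -> list[str]:
    """One id per line; '#' comments and blanks ignored."""
    out = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip companions of the readers)
# ---------------------------------------------------------------------------

def write_drug_catalog(catalog: DrugCatalog, path: str | Path) -> None:
    rows = []
    for rec in catalog:
        fp = "" if rec.fingerprint is None else "".join(map(str, rec.fingerprint.tolist()))
        rows.append((rec.drug_id, rec.name, rec.category, rec.smiles or "", fp))
    frame = pd.DataFrame(rows, columns=["drug_id", "name", "category", "smiles", "fingerprint"])
    frame.to_csv(path, sep="\t", index=False)


def write_target_catalog(targets: TargetCatalog, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(t.target_id, t.family or "") for t in targets], columns=["target_id", "family"]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    interactions.edges[["drug_id", "target_id"]].to_csv(path, sep="\t", index=False)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for set_id, (description, members) in collection.sets.items():
            handle.write("\t".join([set_id, description, *sorted(members)]) + "\n")


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for one in ids:
            handle.write(f"{one}\n")
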