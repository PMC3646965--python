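"""Reading and writing drug-target interaction network data.

The on-disk dialect follows the Yamanishi gold-standard benchmark files:
tab-delimited labeled matrices (header row of column identifiers, leading
column of row identifiers, UTF-8). Three matrices make a dataset:

* a drug-drug chemical similarity matrix ``D`` (SIMCOMP scores),
* a protein-protein sequence similarity matrix ``P`` (normalized
  Smith-Waterman scores),
* a binary drug-protein interaction adjacency ``a``.

Similarity files distributed through mirrors occasionally carry small
numerical asymmetries or values slightly outside [0, 1]; loaders repair
these (average-symmetrization, clipping, diagonal reset) and log counts
rather than failing, since the propagation stage depends on a symmetric
operator with unit self-similarity. Missing cells are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DatasetConsistencyError,
    MatrixFormatError,
    MatrixParseError,
    MatrixValueError,
)

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square, symmetric pairwise-similarity matrix with entity labels.

    Invariants (enforced by :func:`load_similarity` / :meth:`validate`):
    values in [0, 1], symmetric to 1e-12, unit diagonal, dimension equal to
    the number of identifiers.
    """

    entity_ids: list[str]
    values: np.ndarray
    repairs: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def validate(self) -> None:
        v = self.values
        if v.shape != (self.n, self.n):
            raise MatrixFormatError(
                f"similarity matrix shape {v.shape} does not match "
                f"{self.n} identifiers"
            )
        if not np.isfinite(v).all():
            raise MatrixValueError("similarity matrix contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise MatrixValueError("similarity values outside [0, 1]")
        if np.abs(v - v.T).max() > _SYMMETRY_TOL:
            raise MatrixValueError("similarity matrix is not symmetric")
        if np.abs(np.diag(v) - 1.0).max() > 0:
            raise MatrixValueError("similarity diagonal is not all ones")

    def reindex(self, ids: list[str]) -> "SimilarityMatrix":
        """Return a copy restricted/permuted to ``ids`` (all must be present)."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DatasetConsistencyError(
                f"identifiers missing from similarity matrix: {missing[:5]}"
            )
        idx = np.array([pos[i] for i in ids])
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)].copy())


@dataclass
class InteractionMatrix:
    """Binary n x m adjacency of known drug -> protein interactions."""

    drug_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.drug_ids), len(self.protein_ids))

    def validate(self) -> None:
        if self.values.shape != self.shape:
            raise MatrixFormatError(
                f"interaction matrix shape {self.values.shape} does not match "
                f"{self.shape} identifiers"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MatrixValueError(
                f"interaction entry at ({self.drug_ids[r]}, {self.protein_ids[c]}) "
                f"is {self.values[r, c]!r}, expected 0 or 1"
            )


@dataclass
class DTIDataset:
    """Aligned triple (drug similarity, protein similarity, interactions)."""

    drug_sim: SimilarityMatrix
    protein_sim: SimilarityMatrix
    interactions: InteractionMatrix

    @property
    def drug_ids(self) -> list[str]:
        return self.interactions.drug_ids

    @property
    def protein_ids(self) -> list[str]:
        return self.interactions.protein_ids

    def validate(self) -> None:
        self.drug_sim.validate()
        self.protein_sim.validate()
        self.interactions.validate()
        if self.drug_sim.entity_ids != self.interactions.drug_ids:
            raise DatasetConsistencyError("drug id order mismatch")
        if self.protein_sim.entity_ids != self.interactions.protein_ids:
            raise DatasetConsistencyError("protein id order mismatch")


def _read_labeled_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise MatrixFormatError(f"{path}: file is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no data rows/columns")
    return df


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    # cell-wise float(): correctly-rounded parsing (pandas' fast parser can
    # be 1 ulp off, which breaks exact write/load round trips)
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if pd.isna(cell):
                raise MatrixParseError(
                    f"{path}: missing cell at row {df.index[i]!r}, column {col!r}"
                )
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return out


def load_similarity(path, kind: str = "drug") -> SimilarityMatrix:
    """Load a labeled tab-delimited similarity matrix, repairing as needed.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file: header row of ids, leading column of ids.
    kind : {"drug", "protein"}
        Only used in log messages.

    Repairs applied (each counted and logged): off-diagonal asymmetry
    averaged as (S + S^T)/2, values clipped into [0, 1], diagonal forced
    to 1. Raises on non-square files or non-numeric cells.
    """
    df = _read_labeled_matrix(path)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(
            f"{path}: similarity matrix must be square, got "
            f"{df.shape[0]} rows x {df.shape[1]} columns"
        )
    ids = [str(i) for i in df.index]
    values = _to_float(df, path)

    repairs: dict[str, int] = {}
    asym = np.abs(values - values.T) > _SYMMETRY_TOL
    if asym.any():
        repairs["symmetrized"] = int(np.triu(asym, 1).sum())
        values = (values + values.T) / 2.0
    clipped = (values < 0.0) | (values > 1.0)
    if clipped.any():
        repairs["clipped"] = int(clipped.sum())
        values = np.clip(values, 0.0, 1.0)
    off_diag = np.abs(np.diag(values) - 1.0) > 0
    if off_diag.any():
        repairs["diagonal_reset"] = int(off_diag.sum())
        np.fill_diagonal(values, 1.0)
    if repairs:
        logger.warning("%s similarity %s: repairs applied %s", kind, path, repairs)

    sim = SimilarityMatrix(ids, values, repairs)
    sim.validate()
    return sim


def load_interactions(path, dialect: str = "matrix") -> InteractionMatrix:
    """Load known interactions from a labeled 0/1 matrix or a pair list.

    ``matrix`` dialect: labeled matrix as for similarities, entries 0/1.
    ``pairs`` dialect: two-column TSV of (drug id, protein id); identifiers
    collected in first-appearance order, duplicates accepted idempotently.
    """
    if dialect == "matrix":
        df = _read_labeled_matrix(path)
        drug_ids = [str(i) for i in df.index]
        protein_ids = [str(c) for c in df.columns]
        values = _to_float(df, path)
        inter = InteractionMatrix(drug_ids, protein_ids, values)
        inter.validate()
        inter.values = values.astype(np.int8)
        return inter
    if dialect == "pairs":
        pairs = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if pairs.shape[1] < 2:
            raise MatrixFormatError(f"{path}: pairs file needs two columns")
        drug_ids: list[str] = []
        protein_ids: list[str] = []
        dpos: dict[str, int] = {}
        ppos: dict[str, int] = {}
        seen: set[tuple[str, str]] = set()
        edges = []
        for d, p in pairs.iloc[:, :2].itertuples(index=False):
            d, p = str(d), str(p)
            if (d, p) in seen:
                logger.warning("duplicate pair (%s, %s) ignored", d, p)
                continue
            seen.add((d, p))
            if d not in dpos:
                dpos[d] = len(drug_ids)
                drug_ids.append(d)
            if p not in ppos:
                ppos[p] = len(protein_ids)
                protein_ids.append(p)
            edges.append((dpos[d], ppos[p]))
        values = np.zeros((len(drug_ids), len(protein_ids)), dtype=np.int8)
        for i, j in edges:
            values[i, j] = 1
        return InteractionMatrix(drug_ids, protein_ids, values)
    raise ValueError(f"unknown dialect {dialect!r}; use 'matrix' or 'pairs'")


def assemble_dataset(
    drug_sim: SimilarityMatrix,
    protein_sim: SimilarityMatrix,
    inter: InteractionMatrix,
) -> DTIDataset:
    """Align the three matrices into one dataset.

    Similarity matrices are permuted to interaction order; entities present
    in a similarity matrix but absent from the interactions are dropped
    (logged). An interaction id missing from its similarity matrix is an
    error.
    """
    dropped_drugs = len(drug_sim.entity_ids) - len(inter.drug_ids)
    dropped_prots = len(protein_sim.entity_ids) - len(inter.protein_ids)
    ds = DTIDataset(
        drug_sim=drug_sim.reindex(inter.drug_ids),
        protein_sim=protein_sim.reindex(inter.protein_ids),
        interactions=InteractionMatrix(
            list(inter.drug_ids), list(inter.protein_ids), inter.values.copy()
        ),
    )
    if dropped_drugs > 0:
        logger.warning("%d drugs without interaction data dropped", dropped_drugs)
    if dropped_prots > 0:
        logger.warning("%d proteins without interaction data dropped", dropped_prots)
    ds.validate()
    return ds


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Write a similarity matrix in the labeled TSV dialect (17 sig digits)."""
    df = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_interactions(inter: InteractionMatrix, path) -> None:
    df = pd.DataFrame(
        inter.values.astype(int), index=inter.drug_ids, columns=inter.protein_ids
    )
    df.to_csv(path, sep="\t")


def write_predictions(rankings, path, config: dict | None = None) -> None:
    """Serialize prediction rankings as a TSV table.

    Columns: query_drug, protein, score, rank; sorted by query drug then
    rank. Byte-deterministic for identical input. ``config``, if given, is
    embedded as ``#``-prefixed header comment lines for provenance.

    ``rankings`` is a non-empty list of objects with ``query_drug`` and
    ``entries`` (protein, score, rank) attributes, or of
    (drug, protein, score, rank) tuples.
    """
    if not rankings:
        raise ValueError("rankings must be non-empty")
    rows = []
    for r in rankings:
        if hasattr(r, "entries"):
            for protein, score, rank in r.entries:
                rows.append((r.query_drug, protein, score, rank))
        else:
            rows.append(tuple(r))
    rows.sort(key=lambda t: (t[0], t[3]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config:
            import json

            fh.write("# config: " + json.dumps(config, sort_keys=True) + "\n")
        fh.write("query_drug\tprotein\tscore\trank\n")
        for drug, protein, score, rank in rows:
            fh.write(f"{drug}\t{protein}\t{score:.12g}\t{rank}\n")
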