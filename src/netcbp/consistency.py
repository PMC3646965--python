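"""Network-consistency scoring of drug-protein pairs.

A candidate pair (d, p) is scored by how coherently the known interaction
network connects drugs relevant to ``d`` with proteins relevant to ``p``.
Both entities are propagated through their own similarity network
(:mod:`netcbp.propagation`), giving relevance vectors ``f_d`` over drugs and
``f_p`` over proteins; the interaction matrix ``A`` projects one side onto
the other and a Pearson correlation measures rank coherence:

* drug_side:    r(f_d, A f_p)   - do drugs relevant to the query interact
  with proteins relevant to the candidate?
* protein_side: r(f_p, A^T f_d) - the mirror-image projection.

The better-performing side can be chosen automatically by internal
cross-validation (``variant="auto"``). The protein with the highest score
is the predicted target; a full ranking over all candidates is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import DTIDataset
from .errors import DegenerateTrainingError, UnknownEntityError
from .propagation import (
    DEFAULT_ALPHA,
    normalize_similarity,
    propagation_kernel,
)

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.2


@dataclass(frozen=True)
class ConsistencyConfig:
    """Scoring configuration: diffusion weights, variant and normalization."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    variant: str = "drug_side"  # "drug_side" | "protein_side" | "auto"
    normalization: str = "symmetric"  # "symmetric" | "column"
    zero_diagonal: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.variant not in ("drug_side", "protein_side", "auto"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "variant": self.variant,
            "normalization": self.normalization,
            "zero_diagonal": self.zero_diagonal,
        }


@dataclass
class PredictionRanking:
    """Full ranking of candidate proteins for one query drug.

    ``entries`` are (protein id, score, rank) sorted by score descending;
    ranks are 1-based ordinal, ties broken by ascending protein identifier.
    """

    query_drug: str
    entries: list[tuple[str, float, int]] = field(default_factory=list)

    def rank_of(self, protein_id: str) -> int:
        for pid, _, rank in self.entries:
            if pid == protein_id:
                return rank
        raise UnknownEntityError(f"protein {protein_id!r} not in ranking")

    def scores_by_protein(self) -> dict[str, float]:
        return {pid: score for pid, score, _ in self.entries}


def pearson(x, y) -> float:
    """Pearson correlation with the zero-variance convention r = 0.

    Degenerate inputs (either vector constant) return 0 rather than NaN:
    an uninformative projection should not outrank an informative one, and
    0 is the null-correlation value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-d vectors")
    if x.size < 2:
        raise ValueError("pearson requires length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _pearson_columns(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of vector ``x`` against every column of ``M`` (0 on ties)."""
    xc = x - x.mean()
    Mc = M - M.mean(axis=0, keepdims=True)
    xnorm = np.sqrt(xc @ xc)
    cnorm = np.sqrt((Mc * Mc).sum(axis=0))
    denom = xnorm * cnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Mc) / denom
    r[denom == 0.0] = 0.0
    return np.clip(r, -1.0, 1.0)


def consistency_score(f_d, f_p, A, variant: str = "drug_side") -> float:
    """Score one pair of relevance vectors across the interaction network.

    drug_side correlates the drug relevances with the interaction image of
    the protein relevances (A f_p); protein_side correlates the protein
    relevances with A^T f_d.
    """
    fd = np.asarray(getattr(f_d, "values", f_d), dtype=float)
    fp = np.asarray(getattr(f_p, "values", f_p), dtype=float)
    Av = np.asarray(getattr(A, "values", A), dtype=float)
    if Av.shape != (fd.size, fp.size):
        raise ValueError(
            f"interaction matrix shape {Av.shape} does not match "
            f"relevance lengths ({fd.size}, {fp.size})"
        )
    if variant == "drug_side":
        return pearson(fd, Av @ fp)
    if variant == "protein_side":
        return pearson(fp, Av.T @ fd)
    raise ValueError(f"unknown variant {variant!r}")


class ScoringModel:
    """Precomputed propagation kernels for one dataset and configuration.

    Holds the drug-side kernel K_d = (1-alpha)(I - alpha W_d)^{-1} and the
    protein-side kernel K_p (same with beta and the protein network), so
    that repeated queries (cross-validation, all-pairs ranking) reuse one
    factorization. Column j of a kernel is the relevance vector of entity
    j's indicator, so per-entity propagation semantics are preserved.
    """

    def __init__(self, dataset: DTIDataset, config: ConsistencyConfig):
        if config.variant == "auto":
            raise ValueError("resolve variant before building a ScoringModel")
        self.dataset = dataset
        self.config = config
        W_d = normalize_similarity(
            dataset.drug_sim, config.normalization, config.zero_diagonal
        )
        W_p = normalize_similarity(
            dataset.protein_sim, config.normalization, config.zero_diagonal
        )
        self.K_d = propagation_kernel(W_d, config.alpha)
        self.K_p = propagation_kernel(W_p, config.beta)
        self._drug_index = {d: i for i, d in enumerate(dataset.drug_ids)}

    def score_proteins(self, query_drug: str, A: np.ndarray) -> np.ndarray:
        """Consistency score of every protein for one query drug.

        ``A`` is the working interaction matrix (possibly with rows masked
        for held-out drugs).
        """
        try:
            qi = self._drug_index[query_drug]
        except KeyError:
            raise UnknownEntityError(f"unknown drug id {query_drug!r}") from None
        f_d = self.K_d[:, qi]
        if self.config.variant == "drug_side":
            # column j of A @ K_p is A f_p for protein j's indicator
            return _pearson_columns(f_d, A @ self.K_p)
        y = A.T @ f_d
        return _pearson_columns(y, self.K_p)


def _ranking_from_scores(
    query_drug: str, protein_ids: list[str], scores: np.ndarray
) -> PredictionRanking:
    order = sorted(range(len(protein_ids)), key=lambda j: (-scores[j], protein_ids[j]))
    entries = [
        (protein_ids[j], float(scores[j]), rank)
        for rank, j in enumerate(order, start=1)
    ]
    return PredictionRanking(query_drug, entries)


def rank_targets(
    dataset: DTIDataset,
    query_drug: str,
    config: ConsistencyConfig = ConsistencyConfig(),
    mask_query_row: bool = True,
    _model: ScoringModel | None = None,
) -> PredictionRanking:
    """Rank every candidate protein for one query drug.

    The query drug's relevance vector is propagated once; each protein's
    indicator is propagated and scored by network consistency. With
    ``mask_query_row`` (the new-drug setting) the query's known interactions
    are removed from the working copy of the interaction matrix before
    scoring, so the prediction cannot see its own answers.
    """
    if config.variant == "auto":
        config = replace(config, variant=select_variant(dataset, config))
    model = _model or ScoringModel(dataset, config)
    if query_drug not in model._drug_index:
        raise UnknownEntityError(f"unknown drug id {query_drug!r}")
    A = dataset.interactions.values.astype(float)
    if mask_query_row:
        A = A.copy()
        A[model._drug_index[query_drug], :] = 0.0
    scores = model.score_proteins(query_drug, A)
    return _ranking_from_scores(query_drug, dataset.protein_ids, scores)


def rank_all_pairs(
    dataset: DTIDataset,
    config: ConsistencyConfig = ConsistencyConfig(),
    top_k: int = 100,
) -> list[tuple[str, str, float, int]]:
    """Globally rank non-interacting pairs, trained on all known interactions.

    Every pair with a_ij = 0 is scored with the full, unmasked interaction
    matrix; the global top_k by score are returned with 1-based ranks.
    Known interactions never appear. Ties broken by (drug id, protein id).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if config.variant == "auto":
        config = replace(config, variant=select_variant(dataset, config))
    model = ScoringModel(dataset, config)
    A = dataset.interactions.values.astype(float)
    candidates: list[tuple[str, str, float]] = []
    for i, drug in enumerate(dataset.drug_ids):
        scores = model.score_proteins(drug, A)
        for j in np.flatnonzero(dataset.interactions.values[i] == 0):
            candidates.append((drug, dataset.protein_ids[j], float(scores[j])))
    if top_k > len(candidates):
        logger.warning(
            "top_k=%d exceeds %d non-interacting pairs; output truncated",
            top_k,
            len(candidates),
        )
        top_k = len(candidates)
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    return [
        (d, p, s, rank) for rank, (d, p, s) in enumerate(candidates[:top_k], start=1)
    ]


def select_variant(train: DTIDataset, config: ConsistencyConfig) -> str:
    """Choose the better-performing projection side by internal CV.

    Runs a drug-wise cross-validation on the training data for both
    variants and returns the one with the higher mean AUC; ties go to
    drug_side.
    """
    from .evaluation import CVConfig, cross_validate  # circular at import time

    n_with_targets = int((train.interactions.values.sum(axis=1) >= 1).sum())
    if len(train.drug_ids) < 2 or n_with_targets < 2:
        raise DegenerateTrainingError(
            "variant selection needs >= 2 drugs with >= 1 interaction; "
            "choose drug_side or protein_side explicitly"
        )
    folds = min(5, n_with_targets)
    results = {}
    for variant in ("drug_side", "protein_side"):
        cv = CVConfig(
            folds=folds,
            repeats=1,
            seed=0,
            consistency=replace(config, variant=variant),
        )
        results[variant] = cross_validate(train, cv).mean_auc
    logger.info("variant selection AUCs: %s", results)
    if results["protein_side"] > results["drug_side"]:
        return "protein_side"
    return "drug_side"
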