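"""Accuracy metrics and the leave-one-out verification protocol.

The headline metric, reported here under its original name "PCC", is

    PCC = 1 - sum_i (e_i - p_i)^2 / sum_i (e_i - mean(e))^2,

i.e. one minus SSE over SST — a coefficient-of-determination (R^2-type)
statistic rather than the product-moment correlation, despite the name.  A
perfect predictor gives PCC = 1; predicting the mean gives 0; it can be
negative.  The true Pearson r is computed alongside as a diagnostic and
clearly labeled.  RMSE is the usual root mean squared error.

Leave-one-out verification holds out each motif in turn, relevance-samples
a training set from the remaining same-terminal records, fits that query's
dynamic model and predicts; metrics are then computed per terminal over all
held-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aa_tables import CategoryTable, NormalizedPropertyTable
from .feature_extraction import featurize_library
from .peptide_library import AffinityRecord, PeptideMotif
from .regression import RunConfig, fit_elastic_net, predict_matrix, select_hyperparameters
from .relevance_sampling import is_relevant

logger = logging.getLogger(__name__)

#: Below this many same-terminal records, cross-validated LOO is infeasible.
MIN_LOOCV_RECORDS = 20


@dataclass(frozen=True)
class EvaluationResult:
    """Per-terminal accuracy summary."""

    pcc: float          # 1 - SSE/SST (R^2-type, the original "PCC")
    rmse: float
    pearson_r: float    # standard product-moment correlation, diagnostic
    n: int

    def __post_init__(self) -> None:
        if self.pcc > 1 + 1e-12:
            raise ValueError("PCC cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("RMSE cannot be negative")
        if self.n < 2:
            raise ValueError("need at least two evaluated motifs")


def pcc(e, p) -> float:
    """1 - SSE/SST of predictions ``p`` against experimental values ``e``."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if e.shape != p.shape or e.ndim != 1 or len(e) < 2:
        raise ValueError("e and p must be equal-length 1-D with at least 2 values")
    sst = float(((e - e.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("experimental values are constant; PCC undefined")
    sse = float(((e - p) ** 2).sum())
    return 1.0 - sse / sst


def rmse(e, p) -> float:
    """Root mean squared error of predictions against experimental values."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if e.shape != p.shape or e.ndim != 1 or len(e) == 0:
        raise ValueError("e and p must be equal-length non-empty 1-D")
    return float(np.sqrt(((e - p) ** 2).mean()))


def evaluate(e, p) -> EvaluationResult:
    """All metrics at once for one set of predictions."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.std() == 0.0 or e.std() == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(e, p)[0, 1])
    return EvaluationResult(pcc=pcc(e, p), rmse=rmse(e, p), pearson_r=r, n=len(e))


def precision_recall(
    predicted: set[PeptideMotif], reference: set[PeptideMotif]
) -> tuple[float, float]:
    """Fraction of predicted motifs that are real, and of real ones found."""
    if not reference:
        raise ValueError("reference set must be non-empty")
    if not predicted:
        raise ValueError("predicted set is empty; precision undefined")
    hits = len(set(predicted) & set(reference))
    return hits / len(predicted), hits / len(reference)


def loocv_evaluate(
    records: list[AffinityRecord],
    categories: CategoryTable,
    norm: NormalizedPropertyTable,
    config: RunConfig | None = None,
) -> dict[str, EvaluationResult]:
    """Leave-one-out verification, one result per terminal present.

    For each held-out motif the training pool is every *other* same-terminal
    record; relevance sampling, hyperparameter selection and fitting are
    redone per query.  ``config.n_queries`` evaluates a seeded random subset
    of queries per terminal (training pools are unaffected).
    """
    if config is None:
        config = RunConfig()
    results: dict[str, EvaluationResult] = {}
    for terminal in ("N", "C"):
        group = [rec for rec in records if rec.motif.terminal == terminal]
        if not group:
            continue
        if len(group) < MIN_LOOCV_RECORDS:
            raise ValueError(
                f"{len(group)} {terminal}-terminal records is below the "
                f"LOO-CV feasibility floor of {MIN_LOOCV_RECORDS}"
            )
        for rec in group:
            if rec.affinity is None:
                raise ValueError("all records must carry an affinity for LOO-CV")

        motifs = [rec.motif for rec in group]
        X = featurize_library(motifs, norm)
        y = np.array([rec.affinity for rec in group], dtype=float)

        query_idx = np.arange(len(group))
        if config.n_queries is not None and config.n_queries < len(group):
            rng = np.random.default_rng(config.seed)
            query_idx = np.sort(rng.choice(len(group), config.n_queries, replace=False))

        e_vals, p_vals = [], []
        for qi in query_idx:
            mask = np.array(
                [
                    j != qi and is_relevant(motifs[qi], motifs[j], categories)
                    for j in range(len(group))
                ]
            )
            if mask.sum() < config.folds:
                if config.relevance_fallback:
                    mask = np.arange(len(group)) != qi
                else:
                    raise ValueError(
                        f"only {int(mask.sum())} relevant motifs for query "
                        f"{motifs[qi].encode()}"
                    )
            Xtr, ytr = X[mask], y[mask]
            alpha, lam = select_hyperparameters(
                Xtr,
                ytr,
                alpha_grid=config.alpha_grid,
                folds=config.folds,
                seed=config.seed,
                n_lambdas=config.n_lambdas,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            model = fit_elastic_net(Xtr, ytr, alpha, lam)
            pred = float(predict_matrix(model, X[qi : qi + 1])[0])
            if config.clip_negative:
                pred = max(pred, 0.0)
            e_vals.append(y[qi])
            p_vals.append(pred)
            logger.debug(
                "loocv %s query=%s n_relevant=%d alpha=%.1f lambda=%.4g",
                terminal, motifs[qi].encode(), int(mask.sum()), alpha, lam,
            )
        results[terminal] = evaluate(e_vals, p_vals)
    return results
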