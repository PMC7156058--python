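"""Repeated-split evaluation of the predictor and its simulated null.

The evaluation loop mirrors the study design: repeatedly (default 10,000
times) split participants 70/30, select the most MAL-correlated probes and
fit the model on the training participants only, predict the held-out
participants, and pool every test prediction across repetitions.  Reported
statistics:

* ``r2`` — squared Pearson correlation of pooled predicted vs measured MAL
  (the coefficient of determination of the pooled scatter); the
  ``1 - SSE/SST`` variance-explained variant is computed alongside.
* ``rmsd`` — root mean squared pooled prediction error, in repeat units.
* an empirical p-value for ``r2`` against the R² distribution of a random
  predictor, realised as the full pipeline (selection inside the loop)
  rerun on phenotype values permuted across participants, re-drawn per null
  replicate; ``p = (1 + #{null >= observed}) / (n_null + 1)`` so it is
  never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .predictor import PredictorConfig, fit, predict, select_probes
from .preprocess import participant_columns

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """Pooled predictions and summary statistics of one evaluation."""

    participant_ids: list
    measured: np.ndarray  # pooled, one entry per test prediction
    predicted: np.ndarray
    repetition: np.ndarray
    participant_index: np.ndarray  # into participant_ids
    r2: float
    r2_variance_explained: float
    rmsd: float
    n_repetitions: int
    n_skipped: int
    null_r2: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float = float("nan")

    def records(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [self.participant_ids[i] for i in self.participant_index],
                "measured_mal": self.measured,
                "predicted_mal": self.predicted,
                "repetition": self.repetition,
            }
        )


def pooled_r2(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side is constant."""
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        return 0.0
    r = np.corrcoef(measured, predicted)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r * r)


def variance_explained(measured: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SST of the pooled predictions (may be negative)."""
    sst = float(np.sum((measured - measured.mean()) ** 2))
    if sst == 0:
        return 0.0
    sse = float(np.sum((measured - predicted) ** 2))
    return 1.0 - sse / sst


def _prepare_arrays(table: pd.DataFrame, mal: pd.Series,
                    cfg: PredictorConfig) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Restrict to the gene set and participants with a measured MAL.

    Returns (X participants x probes, y, participant_ids, probe_ids).
    """
    if cfg.gene_set is not None:
        mask = table["gene_name"].isin(list(cfg.gene_set))
        table = table.loc[mask]
    if len(table) == 0:
        raise ValueError("no probes remain after gene-set restriction")
    cols = [c for c in participant_columns(table) if c in mal.index]
    mal = mal.loc[cols]
    keep = mal.notna()
    cols = [c for c, k in zip(cols, keep) if k]
    if len(cols) < 5:
        raise ValueError(
            f"need >= 5 participants with measured MAL, got {len(cols)}"
        )
    X = table[cols].to_numpy(dtype=float).T
    y = mal.loc[cols].to_numpy(dtype=float)
    return X, y, cols, list(table.index)


def _evaluate_arrays(X: np.ndarray, y: np.ndarray, cfg: PredictorConfig,
                     rng: np.random.Generator):
    """The raw repetition loop on numpy arrays (hot path).

    The default configuration (PLSR, unscaled features, Pearson selection)
    takes a fused path that inlines centring, selection and the fit —
    semantically identical to select_probes/fit/predict but without
    per-repetition object construction.  When ``k_probes`` covers every
    probe, selection is skipped outright: the PLSR fit is invariant to
    probe order and selection then retains all probes anyway.
    """
    from .predictor import _fit_pls1

    n, p = X.shape
    n_train = int(np.floor(cfg.train_fraction * n))
    fast = (
        cfg.model_kind == "plsr"
        and not cfg.scale_features
        and cfg.selection_metric == "pearson"
    )
    select_all = cfg.k_probes >= p
    preds, meas, reps, pidx = [], [], [], []
    skipped = 0
    indices = np.arange(n)
    for rep in range(cfg.n_repetitions):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        y_tr = y[tr]
        if np.ptp(y_tr) == 0:
            skipped += 1
            continue
        if fast:
            X_tr = X[tr]
            X_te = X[te]
            if not select_all:
                sel = select_probes(X_tr, y_tr, cfg.k_probes)
                X_tr = X_tr[:, sel]
                X_te = X_te[:, sel]
            x_mean = X_tr.mean(axis=0)
            y_mean = y_tr.mean()
            coef, *_ = _fit_pls1(X_tr - x_mean, y_tr - y_mean, cfg.n_components)
            yhat = (X_te - x_mean) @ coef + y_mean
        else:
            sel = select_probes(X[tr], y_tr, cfg.k_probes, cfg.selection_metric)
            model = fit(X[tr][:, sel], y_tr, cfg, probe_ids=sel, rng=rng)
            yhat = predict(model, X[te][:, sel])
        preds.append(yhat)
        meas.append(y[te])
        reps.append(np.full(len(te), rep))
        pidx.append(indices[te])
    if skipped > 0.1 * cfg.n_repetitions:
        raise RuntimeError(
            f"{skipped}/{cfg.n_repetitions} repetitions had a constant "
            "training response"
        )
    if skipped:
        logger.warning("skipped %d repetitions with constant training MAL", skipped)
    predicted = np.concatenate(preds)
    measured = np.concatenate(meas)
    return predicted, measured, np.concatenate(reps), np.concatenate(pidx), skipped


def run_evaluation(table: pd.DataFrame, mal: pd.Series,
                   cfg: PredictorConfig, rng=None) -> EvaluationResult:
    """Run the full repeated-split evaluation on a ProbeTable.

    ``mal`` is indexed by participant id; participants missing from the
    table or without a measured MAL are excluded before splitting.
    Fully reproducible from ``cfg.seed`` (or an explicit generator).
    """
    X, y, ids, probe_ids = _prepare_arrays(table, mal, cfg)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0B5]))
    predicted, measured, reps, pidx, skipped = _evaluate_arrays(X, y, cfg, rng)
    return EvaluationResult(
        participant_ids=ids,
        measured=measured,
        predicted=predicted,
        repetition=reps,
        participant_index=pidx,
        r2=pooled_r2(measured, predicted),
        r2_variance_explained=variance_explained(measured, predicted),
        rmsd=float(np.sqrt(np.mean((predicted - measured) ** 2))),
        n_repetitions=cfg.n_repetitions,
        n_skipped=skipped,
    )


def null_r2_distribution(table: pd.DataFrame, mal: pd.Series,
                         cfg: PredictorConfig, n_null: int,
                         rng=None) -> np.ndarray:
    """R² distribution of a random predictor.

    Each null replicate permutes the measured MAL across participants and
    reruns the full evaluation loop — probe selection included — so the
    null captures every opportunity for optimistic bias the real pipeline
    has.
    """
    if n_null < 1:
        raise ValueError("need at least one null replicate")
    X, y, _, _ = _prepare_arrays(table, mal, cfg)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0C1]))
    out = np.empty(n_null)
    for i in range(n_null):
        y_perm = y[rng.permutation(len(y))]
        predicted, measured, *_ = _evaluate_arrays(X, y_perm, cfg, rng)
        out[i] = pooled_r2(measured, predicted)
    return out


def empirical_pvalue(observed_r2: float, null_r2: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= obs}) / (N + 1)."""
    null_r2 = np.asarray(null_r2, dtype=float)
    if null_r2.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null_r2 >= observed_r2)) / (null_r2.size + 1))


def evaluate_with_null(table: pd.DataFrame, mal: pd.Series,
                       cfg: PredictorConfig, n_null: int | None = None,
                       rng=None) -> EvaluationResult:
    """Evaluation plus null distribution plus empirical p-value."""
    if n_null is None:
        n_null = cfg.n_null
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0D1]))
    result = run_evaluation(table, mal, cfg, rng=rng)
    result.null_r2 = null_r2_distribution(table, mal, cfg, n_null, rng=rng)
    result.p_value = empirical_pvalue(result.r2, result.null_r2)
    return result
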