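"""Probe selection and effective-repeat-length predictors.

The predictor maps probe-level log2 intensities to the modal CTG-repeat
allele length (MAL).  Training follows the many-features/few-samples recipe:
restrict to a candidate gene set, keep the (up to) ``k`` probes most
correlated with MAL on the training participants, and fit a 2-component
partial least squares regression (PLSR).  Lasso, ordinary linear regression
and random-forest comparators are available behind the same interface.

The PLSR fit is the standard univariate-response NIPALS solution.  For a
single response the NIPALS weight vector has the closed form
``w_a = X_a' y_a / ||X_a' y_a||`` (no inner iteration), so each component
costs a handful of matrix-vector products — important because the
evaluation stage refits the model tens of thousands of times.  Features and
response are centred; unit-variance feature scaling is off by default and
configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MODEL_KINDS = ("plsr", "lasso", "linear", "random_forest")

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class PredictorConfig:
    """Training-loop settings.

    ``gene_set`` is a collection of gene symbols (e.g. an alternative-
    splicing or alternative-polyadenylation biomarker panel, a single gene,
    or every gene); ``None`` means no gene restriction.
    """

    gene_set: tuple | None = None
    k_probes: int = 500
    n_components: int = 2
    train_fraction: float = 0.7
    n_repetitions: int = 10_000
    n_null: int = 1000
    model_kind: str = "plsr"
    scale_features: bool = False
    selection_metric: str = "pearson"  # or "spearman"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_probes < 1:
            raise ValueError("k_probes must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.selection_metric not in ("pearson", "spearman"):
            raise ValueError("selection_metric must be 'pearson' or 'spearman'")


@dataclass
class PredictorModel:
    """A fitted predictor.

    For linear kinds (``plsr``, ``lasso``, ``linear``) the model is the
    affine map ``X @ coef + intercept`` on the selected probes; for PLSR the
    latent structure (weights, loadings, score norms) is retained as well.
    ``estimator`` holds the fitted scikit-learn object for the
    random-forest kind.
    """

    model_kind: str
    selected_probe_ids: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coef: np.ndarray | None = None
    weights: np.ndarray | None = None  # PLSR W, features x components
    loadings: np.ndarray | None = None  # PLSR P
    y_loadings: np.ndarray | None = None  # PLSR q
    estimator: object = None
    n_components_used: int = 0

    @property
    def intercept(self) -> float:
        if self.coef is None:
            raise ValueError(f"{self.model_kind} model has no linear coefficients")
        return float(self.y_mean - (self.x_mean / self.x_scale) @ self.coef)

    def to_json(self) -> str:
        """Versioned portable serialisation (linear model kinds only)."""
        if self.coef is None:
            raise ValueError("only linear model kinds serialise to JSON")
        payload = {
            "format": "splicerail-predictor",
            "version": SERIALIZATION_VERSION,
            "model_kind": self.model_kind,
            "selected_probe_ids": list(map(str, self.selected_probe_ids)),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
            "n_components_used": self.n_components_used,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PredictorModel":
        payload = json.loads(text)
        if payload.get("format") != "splicerail-predictor":
            raise ValueError("not a serialised predictor model")
        if payload["version"] > SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model version {payload['version']}")
        return cls(
            model_kind=payload["model_kind"],
            selected_probe_ids=payload["selected_probe_ids"],
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_scale=np.asarray(payload["x_scale"], dtype=float),
            y_mean=float(payload["y_mean"]),
            coef=np.asarray(payload["coef"], dtype=float),
            n_components_used=int(payload["n_components_used"]),
        )


def split_participants(participant_ids, train_fraction: float, rng) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test split.

    Train size is ``floor(train_fraction * n)`` — 27 participants at 0.7
    give an 18/9 split.  Deterministic given the generator state.
    """
    ids = list(participant_ids)
    n = len(ids)
    n_train = int(np.floor(train_fraction * n))
    if n < 3 or n_train < 1 or n_train >= n:
        raise ValueError(
            f"cannot split {n} participants into non-empty train/test at "
            f"fraction {train_fraction}"
        )
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def correlation_scores(X: np.ndarray, y: np.ndarray, metric: str = "pearson") -> np.ndarray:
    """|metric| correlation of every probe (column of X) with y.

    Zero-variance probes score 0.  ``y`` constant is an error: correlation
    with the response is undefined for every probe.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; probe correlations undefined")
    if metric == "spearman":
        X = stats.rankdata(X, axis=0)
        y = stats.rankdata(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sy = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    return r


def select_probes(X_train: np.ndarray, y_train: np.ndarray, k: int,
                  metric: str = "pearson") -> np.ndarray:
    """Indices of the min(k, n_probes) probes most correlated with y.

    Descending |r|; ties broken by column index so runs are reproducible.
    """
    r = correlation_scores(X_train, y_train, metric)
    order = np.lexsort((np.arange(len(r)), -np.abs(r)))
    return order[: min(k, len(r))]


def _fit_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Univariate-response NIPALS PLSR on centred data.

    Returns (coef, W, P, q, n_used).  Components stop early (with a logged
    warning) when the residual covariance X'y vanishes, i.e. when
    ``n_components`` exceeds the informative rank.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    X_res = Xc.copy()
    y_res = yc.copy()
    used = 0
    for a in range(n_components):
        w = X_res.T @ y_res
        norm = np.linalg.norm(w)
        if norm <= np.finfo(float).eps * max(n, p):
            logger.warning(
                "PLSR component %d: residual covariance vanished; using %d "
                "component(s) instead of %d", a + 1, used, n_components
            )
            break
        w /= norm
        t = X_res @ w
        tt = t @ t
        if tt <= np.finfo(float).tiny:
            break
        p_a = X_res.T @ t / tt
        q_a = (y_res @ t) / tt
        X_res -= t[:, None] * p_a
        y_res = y_res - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        used = a + 1
    if used == 0:
        return np.zeros(p), W[:, :0], P[:, :0], q[:0], 0
    W, P, q = W[:, :used], P[:, :used], q[:used]
    # regression coefficients in the original (centred) feature space
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, W, P, q, used


def fit(X_train: np.ndarray, y_train: np.ndarray, cfg: PredictorConfig,
        probe_ids=None, rng=None) -> PredictorModel:
    """Fit the configured model on (already selected) training features."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    if probe_ids is None:
        probe_ids = list(range(p))
    x_mean = X.mean(axis=0)
    x_scale = np.ones(p)
    if cfg.scale_features:
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    if cfg.model_kind == "plsr":
        if n <= cfg.n_components:
            raise ValueError(
                f"need more than n_components={cfg.n_components} training "
                f"participants, got {n}"
            )
        coef, W, P, q, used = _fit_pls1(Xs, yc, cfg.n_components)
        return PredictorModel(
            model_kind="plsr", selected_probe_ids=list(probe_ids),
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, coef=coef,
            weights=W, loadings=P, y_loadings=q, n_components_used=used,
        )
    if cfg.model_kind == "linear":
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return PredictorModel(
            model_kind="linear", selected_probe_ids=list(probe_ids),
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, coef=coef,
        )
    if cfg.model_kind == "lasso":
        from sklearn.linear_model import LassoCV

        if np.ptp(y) == 0:
            coef = np.zeros(p)
        else:
            est = LassoCV(cv=min(5, n), random_state=cfg.seed, max_iter=5000)
            est.fit(Xs, yc)
            coef = est.coef_
        return PredictorModel(
            model_kind="lasso", selected_probe_ids=list(probe_ids),
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, coef=coef,
        )
    if cfg.model_kind == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        seed = cfg.seed if rng is None else int(rng.integers(0, 2**31 - 1))
        est = RandomForestRegressor(n_estimators=500, random_state=seed)
        est.fit(Xs, y)
        return PredictorModel(
            model_kind="random_forest", selected_probe_ids=list(probe_ids),
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, estimator=est,
        )
    raise ValueError(f"unknown model kind {cfg.model_kind!r}")


def predict(model: PredictorModel, X_new: np.ndarray,
            probe_ids=None) -> np.ndarray:
    """Predicted MAL ("effective repeat length") per participant.

    If ``probe_ids`` is given, columns of ``X_new`` are matched to the
    model's selected probes; missing probes raise an error listing them.
    """
    X = np.asarray(X_new, dtype=float)
    if probe_ids is not None:
        lookup = {pid: i for i, pid in enumerate(probe_ids)}
        missing = [p for p in model.selected_probe_ids if p not in lookup]
        if missing:
            raise KeyError(f"X_new lacks selected probes: {missing}")
        X = X[:, [lookup[p] for p in model.selected_probe_ids]]
    if X.shape[1] != len(model.selected_probe_ids):
        raise ValueError(
            f"X_new has {X.shape[1]} probes, model expects "
            f"{len(model.selected_probe_ids)}"
        )
    Xs = (X - model.x_mean) / model.x_scale
    if model.estimator is not None:
        return np.asarray(model.estimator.predict(Xs), dtype=float)
    return Xs @ model.coef + model.y_mean


def read_gene_set(path) -> tuple:
    """Read a gene-set file: one gene symbol per line, '#' comments allowed."""
    genes = []
    for line in open(path, encoding="utf-8"):
        name = line.split("#", 1)[0].strip()
        if name:
            genes.append(name)
    return tuple(genes)
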