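"""One-class logistic regression (OCLR) stemness index.

The stemness signature is a weight vector ``w`` fitted on stem-cell
expression profiles only, by minimising the one-class logistic loss

    L(w) = (1/n) * sum_i -log sigma(w' x_i) + (lambda/2) * ||w||^2

where ``x_i`` is the log2, feature-centered profile of stem sample ``i`` and
``sigma`` the logistic function. The problem is convex, so zero
initialisation and a deterministic quasi-Newton solver give a reproducible
optimum.

Centering matters: if features are centered by the stem-sample means
themselves, the loss gradient vanishes at w = 0 and ridge makes w = 0 the
global minimum — the signature degenerates. Centering is therefore computed
over the full reference cohort (stem and non-stem samples) while the
one-class fit itself sees only the stem-labeled columns.

Cohorts are scored by the Spearman correlation between ``w`` and each
sample's profile over shared features (rank correlation makes the score
invariant to monotone platform effects), then min-max scaled to the mRNAsi in
[0, 1]. Under the default ``stem_low`` orientation the scale is flipped so
that more stem-like samples receive a LOWER mRNAsi, and the most stem-like
decile (lowest mRNAsi) forms the TSC stratum, the least stem-like decile the
USC stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import rankdata

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

_GTOL = 1e-6
_MAX_ITER = 10_000


class ConvergenceError(RuntimeError):
    pass


@dataclass
class StemnessModel:
    """Trained OCLR stemness signature."""

    feature_ids: pd.Index
    w: np.ndarray
    lambda_: float
    center: np.ndarray
    orientation: str = "stem_low"
    scale_min: float | None = None
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.w) or len(self.w) != len(self.center):
            raise ValueError("feature_ids, w and center must have equal length")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.orientation not in ("stem_low", "stem_high"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def to_frames(self) -> tuple[pd.DataFrame, dict]:
        weights = pd.DataFrame(
            {"feature_id": self.feature_ids, "weight": self.w, "center": self.center}
        ).set_index("feature_id")
        meta = {
            "lambda": self.lambda_,
            "orientation": self.orientation,
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
        }
        return weights, meta

    @classmethod
    def from_frames(cls, weights: pd.DataFrame, meta: dict) -> "StemnessModel":
        return cls(
            feature_ids=weights.index,
            w=weights["weight"].to_numpy(float),
            lambda_=float(meta["lambda"]),
            center=weights["center"].to_numpy(float),
            orientation=str(meta["orientation"]),
            scale_min=None if meta.get("scale_min") is None else float(meta["scale_min"]),
            scale_max=None if meta.get("scale_max") is None else float(meta["scale_max"]),
        )


@dataclass
class StemnessScores:
    """Per-sample raw rank-correlation score, scaled mRNAsi and stratum."""

    sample_ids: pd.Index
    raw: np.ndarray
    mrnasi: np.ndarray
    stratum: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"raw": self.raw, "mrnasi": self.mrnasi}, index=self.sample_ids)
        df.index.name = "sample_id"
        df["stratum"] = self.stratum if self.stratum is not None else ""
        return df


def oclr_objective(w: np.ndarray, X: np.ndarray, lambda_: float) -> tuple[float, np.ndarray]:
    """One-class logistic loss and gradient.

    ``X`` is samples x features, already centered by the model's stored
    means. Returns ``(loss, gradient)`` with
    loss = (1/n) sum -log sigma(Xw) + lambda/2 ||w||^2 and
    gradient = (1/n) X'(sigma(Xw) - 1) + lambda * w.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: X is {X.shape}, w has {w.shape[0]} features")
    n = X.shape[0]
    z = X @ w
    loss = float(np.mean(np.logaddexp(0.0, -z)) + 0.5 * lambda_ * (w @ w))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = X.T @ (sig - 1.0) / n + lambda_ * w
    return loss, grad


def _prepare_features(expr: ExpressionMatrix, features) -> pd.DataFrame:
    log2x = expr.log2p()
    if features is not None:
        features = pd.Index(features)
        present = features[features.isin(log2x.index)]
        if len(present) < 2:
            raise ValueError("fewer than 2 requested features present in matrix")
        log2x = log2x.loc[present]
    return log2x


def train_oclr(
    expr: ExpressionMatrix,
    stem_sample_ids,
    lambda_: float | None = None,
    features=None,
    l1: float = 0.0,
    orientation: str = "stem_low",
) -> StemnessModel:
    """Fit the OCLR signature.

    Parameters
    ----------
    expr
        Reference cohort expression (linear or log). All samples are used to
        compute per-feature centering means; only ``stem_sample_ids`` columns
        enter the one-class fit.
    stem_sample_ids
        Columns of ``expr`` labeled as stem; at least 2 required.
    lambda_
        Ridge penalty; defaults to 1 / n_features.
    features
        Optional feature restriction (e.g. genes harboring filter-surviving
        splice events in the target cohort).
    l1
        Optional elastic-net L1 penalty (default 0: pure ridge); solved by
        proximal gradient when positive.
    """
    stem_sample_ids = pd.Index(stem_sample_ids)
    if len(stem_sample_ids) < 2:
        raise ValueError("need at least 2 stem samples")
    missing = stem_sample_ids.difference(expr.sample_ids)
    if len(missing):
        raise KeyError(f"stem samples not in matrix: {list(missing[:3])}")
    log2x = _prepare_features(expr, features)
    center = log2x.mean(axis=1).to_numpy(float)
    X = (log2x[stem_sample_ids].to_numpy(float) - center[:, None]).T
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values after log transform/centering")
    p = X.shape[1]
    lam = 1.0 / p if lambda_ is None else float(lambda_)
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    if l1 > 0:
        w = _fista(X, lam, l1)
    else:
        res = optimize.minimize(
            oclr_objective,
            np.zeros(p),
            args=(X, lam),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": _MAX_ITER, "gtol": 1e-9, "ftol": 0.0},
        )
        w = res.x
        gnorm = float(np.max(np.abs(oclr_objective(w, X, lam)[1])))
        if gnorm > _GTOL:
            raise ConvergenceError(
                f"OCLR did not converge: gradient infinity-norm {gnorm:.2e} > {_GTOL:.0e}"
            )
    return StemnessModel(
        feature_ids=log2x.index, w=w, lambda_=lam, center=center, orientation=orientation
    )


def _fista(X: np.ndarray, lam: float, l1: float, max_iter: int = _MAX_ITER) -> np.ndarray:
    """Proximal gradient (FISTA) for the elastic-net variant."""
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / (4.0 * n) + lam  # Lipschitz bound of smooth part
    w = np.zeros(p)
    y, t = w.copy(), 1.0
    for _ in range(max_iter):
        _, g = oclr_objective(y, X, lam)
        w_new = np.sign(y - g / L) * np.maximum(np.abs(y - g / L) - l1 / L, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = w_new + (t - 1.0) / t_new * (w_new - w)
        if np.max(np.abs(w_new - w)) < 1e-10:
            return w_new
        w, t = w_new, t_new
    return w


def score_samples(model: StemnessModel, expr: ExpressionMatrix) -> StemnessScores:
    """Score a cohort against the signature.

    The raw score of a sample is the Spearman correlation between the model
    weights and the sample's feature values over shared features. The mRNAsi
    is the raw score min-max scaled over the scored cohort (anchors are
    frozen into the model on first use so later cohorts stay comparable),
    flipped to ``1 - x`` under the ``stem_low`` orientation so that stem-like
    samples score low.
    """
    shared = model.feature_ids.intersection(expr.gene_ids)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} features shared between model and cohort")
    pos = model.feature_ids.get_indexer(shared)
    w = model.w[pos]
    Y = expr.log2p().loc[shared].to_numpy(float)
    n_samples = Y.shape[1]
    w_rank = rankdata(w)
    w_rank = (w_rank - w_rank.mean()) / w_rank.std()
    raw = np.full(n_samples, np.nan)
    for j in range(n_samples):
        col = Y[:, j]
        if np.nanstd(col) == 0 or np.isnan(col).all():
            warnings.warn(f"constant profile for sample {expr.sample_ids[j]!r}; score missing")
            continue
        r = rankdata(col)
        raw[j] = float(w_rank @ ((r - r.mean()) / r.std()) / len(r))
    finite = raw[np.isfinite(raw)]
    if model.scale_min is None or model.scale_max is None:
        lo, hi = float(finite.min()), float(finite.max())
        if hi <= lo:
            raise ValueError("degenerate score range; cannot anchor the mRNAsi scale")
        model.scale_min, model.scale_max = lo, hi
    scaled = (raw - model.scale_min) / (model.scale_max - model.scale_min)
    if np.nanmin(scaled) < -1e-9 or np.nanmax(scaled) > 1 + 1e-9:
        warnings.warn("raw scores outside the frozen anchors; mRNAsi clipped to [0, 1]")
    scaled = np.clip(scaled, 0.0, 1.0)
    mrnasi = 1.0 - scaled if model.orientation == "stem_low" else scaled
    return StemnessScores(sample_ids=expr.sample_ids, raw=raw, mrnasi=mrnasi)


def evaluate_separation(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of ``scores`` for positive vs negative
    ``labels``; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    r = rankdata(scores)
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def stratify_by_stemness(scores: StemnessScores, frac: float = 0.10,
                         orientation: str = "stem_low") -> StemnessScores:
    """Assign TSC / MID / USC strata by mRNAsi deciles.

    The ``floor(frac * n)`` most stem-like samples (lowest mRNAsi under the
    default ``stem_low`` orientation) become TSC, the same number of least
    stem-like samples USC, the remainder MID. Ties break deterministically by
    (score, sample id).
    """
    ok = np.isfinite(scores.mrnasi)
    n = int(ok.sum())
    k = int(np.floor(frac * n))
    if k < 1:
        raise ValueError(f"cohort of {n} scored samples too small for frac={frac}")
    if 2 * k > n:
        raise ValueError(f"TSC and USC would overlap: 2*{k} > {n} samples")
    order = sorted(
        (float(scores.mrnasi[i]), str(scores.sample_ids[i]))
        for i in range(len(scores.sample_ids))
        if ok[i]
    )
    ordered_ids = [sid for _, sid in order]
    stem_end = ordered_ids[:k] if orientation == "stem_low" else ordered_ids[-k:]
    other_end = ordered_ids[-k:] if orientation == "stem_low" else ordered_ids[:k]
    stratum = pd.Series("MID", index=scores.sample_ids, name="stratum")
    stratum[~ok] = ""
    stratum[stem_end] = "TSC"
    stratum[other_end] = "USC"
    return StemnessScores(
        sample_ids=scores.sample_ids, raw=scores.raw, mrnasi=scores.mrnasi, stratum=stratum
    )
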