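"""PLS1 regression (NIPALS), PCA, cross-validation and validation metrics.

Calibration models map mean-centered spectra to a single composition trait
(glucose or xylose, percent dry weight) by partial least squares with a
small number of latent factors — 4 for glucose and 5 for xylose by default.
The NIPALS recursion extracts, per factor, a unit-norm weight vector
``w = X'y/||X'y||``, scores ``t = Xw``, x-loadings ``p = X't/(t't)`` and a
y-loading ``q = y't/(t't)``, then deflates ``X <- X - t p'`` and
``y <- y - t q``. The composite coefficient vector ``b = W (P'W)^{-1} q``
gives predictions ``y_mean + (x - x_mean)'b``.

Validation reports follow common chemometric practice: R-squared is the
squared Pearson correlation between measured and predicted values (so R2
and PCC are mutually consistent), RMSE is in trait units, and per-sample
relative errors are percentages of the measured value.

Spectra are mean-centered but not variance-scaled: all channels share one
intensity unit, so unit-variance scaling would only amplify noise channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateResponseError,
    InconsistentNormalizationError,
    InvalidFoldsError,
    RankDeficientError,
)
from .spectra import MZ_CHANNELS, SpectrumMatrix

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model: per-factor loadings plus composite coefficients."""

    n_factors: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    weights: np.ndarray  # (p, A) unit-norm columns w_a
    x_loadings: np.ndarray  # (p, A) columns p_a
    y_loadings: np.ndarray  # (A,) q_a
    coef: np.ndarray  # (p,) composite b
    training_sample_ids: list[str] = field(default_factory=list)
    normalization_state: str | None = None
    trait: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.y_mean + (X - self.x_mean) @ self.coef

    def to_json(self, path, **provenance) -> None:
        payload = {
            "trait": self.trait,
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "training_sample_ids": self.training_sample_ids,
            "normalization_state": self.normalization_state,
            "provenance": provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_factors=d["n_factors"],
            x_mean=np.asarray(d["x_mean"]),
            y_mean=d["y_mean"],
            weights=np.asarray(d["weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            coef=np.asarray(d["coef"]),
            training_sample_ids=d.get("training_sample_ids", []),
            normalization_state=d.get("normalization_state"),
            trait=d.get("trait", ""),
        )


def _as_xy(X, y):
    if isinstance(X, SpectrumMatrix):
        X = X.matrix
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    return X, y


def fit_pls1(
    X,
    y,
    n_factors: int,
    sample_ids: list[str] | None = None,
    trait: str = "",
) -> PLSModel:
    """Fit a single-response PLS model by NIPALS.

    Raises ``DegenerateResponseError`` for a constant y and
    ``RankDeficientError`` (carrying the achieved factor count) when
    deflation exhausts the rank of X before ``n_factors``.
    """
    norm_state = X.normalization_state if isinstance(X, SpectrumMatrix) else None
    if isinstance(X, SpectrumMatrix) and sample_ids is None:
        sample_ids = list(X.sample_ids)
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if np.std(y) == 0:
        raise DegenerateResponseError("response y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.linalg.norm(Xc)) * float(np.linalg.norm(yc)), _RANK_TOL)

    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    for a in range(n_factors):
        cov = Xc.T @ yc
        cov_norm = np.linalg.norm(cov)
        if cov_norm <= _RANK_TOL * scale:
            raise RankDeficientError(
                f"rank exhausted after {a} factors (requested {n_factors})", achieved=a
            )
        w = cov / cov_norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * scale:
            raise RankDeficientError(
                f"rank exhausted after {a} factors (requested {n_factors})", achieved=a
            )
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - t * qa
        W[:, a], P[:, a], q[a] = w, pvec, qa

    # composite coefficients: b = W (P'W)^{-1} q
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=b,
        training_sample_ids=sample_ids or [],
        normalization_state=norm_state,
        trait=trait,
    )


def predict_pls(model: PLSModel, X) -> np.ndarray:
    """Predict the trait for each spectrum row."""
    if isinstance(X, SpectrumMatrix):
        if (
            model.normalization_state is not None
            and X.normalization_state != model.normalization_state
        ):
            raise InconsistentNormalizationError(
                f"model trained on {model.normalization_state}-normalized spectra, "
                f"given {X.normalization_state}"
            )
        X = X.matrix
    return model.predict(X)


def cross_validate(
    X,
    y,
    max_factors: int,
    scheme: str = "loo",
    k: int = 10,
    seed: int = 0,
    _fit_counter: list | None = None,
) -> np.ndarray:
    """Out-of-fold RMSE (RMSECV) for each factor count 1..max_factors.

    ``scheme`` is "loo" (leave-one-out) or "kfold" (k random segments,
    deterministic given ``seed``).
    """
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        if k > n:
            raise InvalidFoldsError(f"k={k} folds but only n={n} samples")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = [perm[i::k] for i in range(k)]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    sq_err = np.zeros(max_factors)
    counts = np.zeros(max_factors)
    for test_idx in folds:
        mask = np.ones(n, bool)
        mask[test_idx] = False
        try:
            model = fit_pls1(X[mask], y[mask], max_factors)
            achieved = max_factors
        except RankDeficientError as exc:
            if exc.achieved == 0:
                raise
            achieved = exc.achieved
            model = fit_pls1(X[mask], y[mask], achieved)
        if _fit_counter is not None:
            _fit_counter.append(1)
        for a in range(1, max_factors + 1):
            aa = min(a, achieved)
            sub = PLSModel(
                n_factors=aa,
                x_mean=model.x_mean,
                y_mean=model.y_mean,
                weights=model.weights[:, :aa],
                x_loadings=model.x_loadings[:, :aa],
                y_loadings=model.y_loadings[:aa],
                coef=model.weights[:, :aa]
                @ np.linalg.solve(
                    model.x_loadings[:, :aa].T @ model.weights[:, :aa],
                    model.y_loadings[:aa],
                ),
            )
            pred = sub.predict(X[test_idx])
            sq_err[a - 1] += float(np.sum((pred - y[test_idx]) ** 2))
            counts[a - 1] += len(test_idx)
    return np.sqrt(sq_err / counts)


def default_cv_scheme(n: int) -> tuple[str, int]:
    """Leave-one-out up to n=150, then 10 random segments."""
    return ("loo", 0) if n <= 150 else ("kfold", 10)


@dataclass
class ValidationReport:
    """Measured-vs-predicted agreement statistics."""

    n: int
    r2: float
    pcc: float
    rmse: float
    err_min_pct: float
    err_max_pct: float
    err_mean_abs_pct: float
    err_sd_pct: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def validation_metrics(measured, predicted) -> ValidationReport:
    """Compute R2 (= PCC squared), PCC, RMSE and relative-error statistics.

    Samples with a zero measured value are excluded from the relative-error
    statistics (they stay in RMSE/PCC). A constant measured or predicted
    vector makes the correlation undefined; it is reported as 0 with the
    ``degenerate`` flag set.
    """
    measured = np.asarray(measured, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if measured.shape != predicted.shape or measured.size < 3:
        raise ValueError("measured and predicted must be equal-length, n >= 3")
    n = measured.size
    resid = predicted - measured
    rmse = float(np.sqrt(np.mean(resid**2)))
    degenerate = np.std(measured) == 0 or np.std(predicted) == 0
    if degenerate:
        pcc = 0.0
    else:
        pcc = float(np.corrcoef(measured, predicted)[0, 1])
    nz = measured != 0
    rel = resid[nz] / measured[nz] * 100.0
    if rel.size == 0:
        err = dict(err_min_pct=0.0, err_max_pct=0.0, err_mean_abs_pct=0.0, err_sd_pct=0.0)
    else:
        err = dict(
            err_min_pct=float(rel.min()),
            err_max_pct=float(rel.max()),
            err_mean_abs_pct=float(np.mean(np.abs(rel))),
            err_sd_pct=float(np.std(rel, ddof=1)) if rel.size > 1 else 0.0,
        )
    return ValidationReport(
        n=n, r2=pcc**2, pcc=pcc, rmse=rmse, degenerate=bool(degenerate), **err
    )


def factor1_loadings(model: PLSModel) -> np.ndarray:
    """Factor-1 x-loading profile, sign-fixed so the factor-1 y-loading is
    positive (channels positively associated with the trait read positive)."""
    p1 = model.x_loadings[:, 0].copy()
    if model.y_loadings[0] < 0:
        p1 = -p1
    return p1


def loading_table(model: PLSModel):
    """Factor-1 loadings keyed by m/z, for reporting/plotting."""
    import pandas as pd

    return pd.Series(factor1_loadings(model), index=MZ_CHANNELS, name="factor1_loading")


def select_calibration_ids(sample_ids, values, n: int) -> list[str]:
    """Pick a calibration subset spanning the trait range.

    Sorts samples by the trait and takes evenly spaced order statistics, the
    usual way a range-representative calibration set is chosen.
    """
    sample_ids = list(sample_ids)
    values = np.asarray(values, float)
    if n > len(sample_ids):
        raise ValueError("calibration subset larger than the sample set")
    order = np.argsort(values, kind="stable")
    pick = np.unique(np.linspace(0, len(sample_ids) - 1, n).round().astype(int))
    return [sample_ids[order[i]] for i in pick]


@dataclass
class PCAResult:
    loadings: np.ndarray  # (p, n_components) columns are component loadings
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n, n_components)


def fit_pca(X, n_components: int | None = None) -> PCAResult:
    """Mean-centered PCA via SVD.

    Explained-variance fractions are the normalized covariance eigenvalues;
    each loading vector's sign is fixed so its largest-magnitude element is
    positive.
    """
    if isinstance(X, SpectrumMatrix):
        X = X.matrix
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    k = n_components or len(s)
    loadings = Vt[:k].T.copy()
    scores = (U[:, :k] * s[:k]).copy()
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PCAResult(loadings=loadings, explained_variance_ratio=frac[:k], scores=scores)


@dataclass
class CorrelationProfile:
    """Per-channel Pearson correlation of intensity with a trait."""

    mz: np.ndarray
    r: np.ndarray
    constant_channel: np.ndarray  # bool flags for zero-variance channels

    def at(self, mz: int) -> float:
        return float(self.r[int(np.searchsorted(self.mz, mz))])


def correlation_profile(X, trait) -> CorrelationProfile:
    """Pearson r between each m/z channel and the trait across samples.

    Constant channels get r = 0 with a flag rather than NaN.
    """
    if isinstance(X, SpectrumMatrix):
        X = X.matrix
    X = np.asarray(X, float)
    t = np.asarray(trait, float).ravel()
    if np.std(t) == 0:
        raise DegenerateResponseError("trait is constant; correlations undefined")
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    constant = sx == 0
    denom = np.where(constant, 1.0, sx * st)
    r = (Xc.T @ tc) / denom
    r[constant] = 0.0
    mz = MZ_CHANNELS if X.shape[1] == len(MZ_CHANNELS) else np.arange(X.shape[1])
    return CorrelationProfile(mz=np.asarray(mz), r=r, constant_channel=constant)
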