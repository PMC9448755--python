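"""Univariate quantile penalized-spline models with h-block ensembles.

The smoother estimates a conditional τ-quantile curve f_τ of log10 population
density against a single climatic predictor by minimising

    Σ_i ρ_τ(y_i − f(x_i)) + λ ‖Δ² c‖²

where ρ_τ(u) = u·(τ − 1{u<0}) is the pinball (check) loss, f = Σ c_j B_j a
cubic B-spline expansion on equally spaced knots (a P-spline), and Δ² the
second-difference matrix on the coefficients.  The penalty null space
contains straight lines, so λ → ∞ recovers linear τ-quantile regression.

Fitting replaces ρ_τ by an ε-smoothed version and runs asymmetric
iteratively-reweighted least squares: at each step the weights are
w_i = |τ − 1{r_i<0}| / max(|r_i|, ε), which makes the weighted quadratic
objective agree with the pinball loss away from ε and turns each iteration
into one banded least-squares solve.  ε defaults to 1e-6·sd(y) and is
configurable; it is a smoothing device, not a trimming rule.

λ is selected by k-fold random cross-validation of the held-out pinball
loss over a log-spaced grid.

Spatial leakage is handled by h-block cross-validation: each of the fold
train/test splits drops from the training set every record within ``h`` km
of a test record ("buffered" strategy) or greedily thins the training set to
a pairwise-≥h subset ("literal" strategy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

from .ethnography import DEFAULT_H_KM, EthnographicRecord, pairwise_great_circle_km

logger = logging.getLogger(__name__)

DEFAULT_TAUS = (0.1, 0.5, 0.9)
DEFAULT_BASIS_SIZE = 10
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 4, 20))
_DEGREE = 3


# ---------------------------------------------------------------------------
# basis and loss primitives
# ---------------------------------------------------------------------------

def pspline_knots(xmin: float, xmax: float, basis_size: int) -> np.ndarray:
    """Equally spaced (unclamped) cubic B-spline knot vector.

    ``basis_size`` functions need basis_size + degree + 1 knots; interior
    spacing is uniform and the vector extends ``degree`` knots beyond the
    data range on each side, so Greville abscissae are uniform and the
    second-difference penalty exactly annihilates straight lines.
    """
    if basis_size < 4:
        raise ValueError("basis_size must be at least 4 for cubic splines")
    if not xmax > xmin:
        raise ValueError("degenerate predictor: xmax must exceed xmin")
    n_interior = basis_size - _DEGREE
    h = (xmax - xmin) / n_interior
    return xmin + h * np.arange(-_DEGREE, basis_size + 1)


def design_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """B-spline design matrix on the base interval [knots[3], knots[-4]].

    x is nudged into the base interval to absorb floating-point rounding at
    the boundary knots (domain control is the caller's job: fitting uses
    training x, prediction clamps to the training range first).
    """
    x = np.clip(np.asarray(x, float), knots[_DEGREE], knots[-_DEGREE - 1])
    return BSpline.design_matrix(x, knots, _DEGREE).toarray()


def second_difference_penalty(basis_size: int) -> np.ndarray:
    d2 = np.diff(np.eye(basis_size), n=2, axis=0)
    return d2.T @ d2


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    r = np.asarray(residuals, float)
    return float(np.sum(r * (tau - (r < 0))))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class QuantileFit:
    """A fitted τ-quantile P-spline for one predictor."""

    variable_id: str
    tau: float
    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    train_range: tuple[float, float]
    deviance_explained: float
    n_train: int
    n_iter: int = 0
    converged: bool = True

    def predict(self, x_new, extrapolation: str = "clamp"
                ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the smooth; never silently extrapolates.

        Returns ``(values, in_domain)``.  Outside the training range the
        out-of-domain flag is False and the value is either the boundary
        value (``extrapolation="clamp"``) or NaN (``"nan"``).
        """
        x = np.atleast_1d(np.asarray(x_new, float))
        lo, hi = self.train_range
        in_domain = (x >= lo) & (x <= hi)
        xc = np.clip(x, lo, hi)
        y = design_matrix(xc, self.knots) @ self.coefficients
        if extrapolation == "nan":
            y = np.where(in_domain, y, np.nan)
        elif extrapolation != "clamp":
            raise ValueError("extrapolation must be 'clamp' or 'nan'")
        return y, in_domain

    def __call__(self, x_new):
        return self.predict(x_new)[0]


def _irls_solve(B: np.ndarray, y: np.ndarray, tau: float, lam: float,
                penalty: np.ndarray, eps: float, max_iter: int = 400,
                tol: float = 1e-8) -> tuple[np.ndarray, int, bool]:
    """Asymmetric IRLS for the ε-smoothed pinball objective."""
    n, k = B.shape
    ridge = 1e-10 * np.eye(k)
    # warm start: unweighted ridge/penalised least squares
    coef = np.linalg.solve(B.T @ B + lam * penalty + ridge, B.T @ y)
    converged = False
    it = 0
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        r = y - B @ coef
        obj = pinball_loss(r, tau) + lam * float(coef @ penalty @ coef)
        w = np.where(r >= 0, tau, 1.0 - tau) / np.maximum(np.abs(r), eps)
        BW = B * w[:, None]
        new = np.linalg.solve(BW.T @ B + lam * penalty + ridge, BW.T @ y)
        if not np.all(np.isfinite(new)):
            raise RuntimeError(
                f"IRLS diverged at iteration {it} (tau={tau}, lam={lam:.3g})")
        delta = np.max(np.abs(new - coef)) / (1.0 + np.max(np.abs(new)))
        coef = new
        if delta < tol or abs(prev_obj - obj) < tol * (1.0 + abs(obj)):
            converged = True
            break
        prev_obj = obj
    return coef, it, converged


def _cv_lambda(x: np.ndarray, y: np.ndarray, tau: float, knots: np.ndarray,
               penalty: np.ndarray, lambda_grid: Sequence[float], eps: float,
               n_splits: int, rng: np.random.Generator) -> float:
    """Pick λ minimising mean held-out pinball loss over random k folds."""
    n = len(x)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_splits)
    B = design_matrix(x, knots)
    losses = np.zeros(len(lambda_grid))
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        if mask.sum() < 10:
            continue
        Btr, ytr = B[mask], y[mask]
        Bte, yte = B[~mask], y[~mask]
        for j, lam in enumerate(lambda_grid):
            coef, _, _ = _irls_solve(Btr, ytr, tau, lam, penalty, eps)
            losses[j] += pinball_loss(yte - Bte @ coef, tau)
    return float(lambda_grid[int(np.argmin(losses))])


def fit_qgam(x, y_log10density, tau: float, variable_id: str = "x",
             basis_size: int = DEFAULT_BASIS_SIZE,
             lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
             lam: float | None = None, eps_scale: float = 1e-6,
             cv_splits: int = 5, seed: int = 0) -> QuantileFit:
    """Fit one τ-quantile P-spline of log10 density on one predictor.

    If ``lam`` is given it is used directly; otherwise λ is chosen from
    ``lambda_grid`` by ``cv_splits``-fold random CV on the pinball loss.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y_log10density, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 30:
        raise ValueError("need at least 30 observations to fit the smoother")
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie strictly inside (0, 1)")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    xmin, xmax = float(x.min()), float(x.max())
    if xmax <= xmin:
        raise ValueError("degenerate predictor: all x equal")

    knots = pspline_knots(xmin, xmax, basis_size)
    penalty = second_difference_penalty(basis_size)
    sdy = float(np.std(y))
    eps = max(eps_scale * sdy, 1e-12)
    rng = np.random.default_rng(seed)

    if lam is None:
        lam = _cv_lambda(x, y, tau, knots, penalty, lambda_grid, eps, cv_splits, rng)

    B = design_matrix(x, knots)
    coef, n_iter, converged = _irls_solve(B, y, tau, lam, penalty, eps)
    if not converged:
        logger.warning("IRLS for %s tau=%.2f stopped at max_iter (lam=%.3g)",
                       variable_id, tau, lam)

    fit = QuantileFit(variable_id=variable_id, tau=tau, knots=knots,
                      coefficients=coef, lam=float(lam),
                      train_range=(xmin, xmax), deviance_explained=0.0,
                      n_train=int(x.size), n_iter=n_iter, converged=converged)
    fit.deviance_explained = deviance_explained(fit, x, y)
    return fit


def predict(fit: QuantileFit, x_new, extrapolation: str = "clamp"):
    """Module-level alias for :meth:`QuantileFit.predict`."""
    return fit.predict(x_new, extrapolation=extrapolation)


def deviance_explained(fit: QuantileFit, x, y) -> float:
    """1 − pinball(fit)/pinball(empirical τ-quantile); 0 if the null is 0.

    The intercept-only τ-quantile model is the empirical τ-quantile of y,
    so this is the quantile analogue of an unadjusted R².
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    yhat, _ = fit.predict(x)
    resid_dev = pinball_loss(y - yhat, fit.tau)
    null_q = np.quantile(y, fit.tau)
    null_dev = pinball_loss(y - null_q, fit.tau)
    if null_dev <= 0.0:
        return 0.0
    return float(1.0 - resid_dev / null_dev)


# ---------------------------------------------------------------------------
# h-block cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    train: np.ndarray
    test: np.ndarray
    n_dropped: int = 0  # training records removed by the h-block rule
    seed: int = 0


def hblock_folds(coords, n_folds: int = 1000, train_frac: float = 0.7,
                 h_km: float = DEFAULT_H_KM, strategy: str = "buffered",
                 seed: int = 0, min_train: int = 30,
                 max_retries: int = 20) -> list[Fold]:
    """Random 70/30 splits with an h-block spatial exclusion.

    ``coords`` is an (n, 2) array of (lat, lon).  Strategy "buffered" drops
    from each training set every record within ``h_km`` of any test record;
    "literal" instead greedily thins the training set so retained training
    records are pairwise ≥ ``h_km`` apart.  Folds whose training set falls
    below ``min_train`` are re-drawn up to ``max_retries`` times.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) lat/lon")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if h_km <= 0:
        raise ValueError("h_km must be positive")
    if strategy not in ("buffered", "literal"):
        raise ValueError("strategy must be 'buffered' or 'literal'")

    dist = pairwise_great_circle_km(coords[:, 0], coords[:, 1])
    n_train = int(round(train_frac * n))
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_folds * (max_retries + 1))]

    folds: list[Fold] = []
    seed_iter = iter(fold_seeds)
    for k in range(n_folds):
        ok = False
        for _ in range(max_retries + 1):
            fseed = next(seed_iter)
            rng = np.random.default_rng(fseed)
            perm = rng.permutation(n)
            train = perm[:n_train]
            test = perm[n_train:]
            if strategy == "buffered":
                near_test = dist[np.ix_(train, test)].min(axis=1) < h_km
                kept = train[~near_test]
            else:  # literal: pairwise thinning of the training set
                kept_list: list[int] = []
                for idx in train:
                    if all(dist[idx, j] >= h_km for j in kept_list):
                        kept_list.append(idx)
                kept = np.array(kept_list, int)
            dropped = len(train) - len(kept)
            if len(kept) >= min_train:
                folds.append(Fold(train=np.sort(kept), test=np.sort(test),
                                  n_dropped=dropped, seed=fseed))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"fold {k}: h-block training set below {min_train} records after "
                f"{max_retries + 1} draws (h_km={h_km}, strategy={strategy})")
    return folds


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Configuration of the h-block ensemble."""

    n_folds: int = 1000
    train_frac: float = 0.7
    h_km: float = DEFAULT_H_KM
    strategy: str = "buffered"
    seed: int = 0
    basis_size: int = DEFAULT_BASIS_SIZE
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    lambda_mode: str = "shared"  # "shared": one CV-chosen λ reused per fold
    min_train: int = 30


@dataclass
class EnsembleModel:
    """Per-fold τ-quantile fits for one predictor plus cross-fold metrics.

    ``metrics`` holds mean and (2.5%, 97.5%) percentile intervals across
    folds of: held-out deviance explained, squared Pearson correlation of
    predicted vs observed on the held-out set, and the same correlation on
    the training set (both are reported because the archival summary is
    ambiguous about which set its correlation column uses).
    """

    variable_id: str
    tau: float
    fits: list[QuantileFit]
    fold_train_indices: list[np.ndarray]
    fold_test_indices: list[np.ndarray]
    metrics: dict[str, float]
    lam: float

    @property
    def n_folds(self) -> int:
        return len(self.fits)

    @property
    def train_range(self) -> tuple[float, float]:
        """Pooled training range over folds (envelope)."""
        lo = min(f.train_range[0] for f in self.fits)
        hi = max(f.train_range[1] for f in self.fits)
        return lo, hi

    def predict_folds(self, x_new, extrapolation: str = "clamp") -> np.ndarray:
        """(n_folds, n_points) log10-density predictions."""
        x = np.atleast_1d(np.asarray(x_new, float))
        out = np.empty((self.n_folds, x.size))
        for i, f in enumerate(self.fits):
            out[i], _ = f.predict(x, extrapolation=extrapolation)
        return out

    def predict_mean_density(self, x_new, extrapolation: str = "clamp") -> np.ndarray:
        """Mean over folds of 10^fit(x): linear-scale ensemble density."""
        return np.nanmean(10.0 ** self.predict_folds(x_new, extrapolation), axis=0)


def _safe_sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _pct_ci(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    return float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))


def fit_ensemble(records: list[EthnographicRecord], variable_id: str, tau: float,
                 cv: CVConfig | None = None) -> EnsembleModel:
    """Fit the h-block fold ensemble for one predictor and quantile level."""
    cv = cv or CVConfig()
    if any(r.predictors is None for r in records):
        raise ValueError("records must carry derived predictors")
    x = np.array([r.predictors.get(variable_id) for r in records])
    y = np.array([r.log10_density for r in records])
    coords = np.array([[r.lat, r.lon] for r in records])

    folds = hblock_folds(coords, n_folds=cv.n_folds, train_frac=cv.train_frac,
                         h_km=cv.h_km, strategy=cv.strategy, seed=cv.seed,
                         min_train=cv.min_train)

    if cv.lambda_mode == "shared":
        shared = fit_qgam(x, y, tau, variable_id=variable_id,
                          basis_size=cv.basis_size, lambda_grid=cv.lambda_grid,
                          seed=cv.seed)
        lam: float | None = shared.lam
    elif cv.lambda_mode == "per_fold":
        lam = None
    else:
        raise ValueError("lambda_mode must be 'shared' or 'per_fold'")

    fits, dev, r2_test, r2_train = [], [], [], []
    used: list[Fold] = []
    n_failed = 0
    for fold in folds:
        try:
            f = fit_qgam(x[fold.train], y[fold.train], tau,
                         variable_id=variable_id, basis_size=cv.basis_size,
                         lambda_grid=cv.lambda_grid, lam=lam, seed=fold.seed)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("fold fit failed for %s tau=%.2f: %s", variable_id, tau, exc)
            n_failed += 1
            continue
        fits.append(f)
        used.append(fold)
        dev.append(deviance_explained(f, x[fold.test], y[fold.test]))
        yhat_te, _ = f.predict(x[fold.test])
        yhat_tr, _ = f.predict(x[fold.train])
        r2_test.append(_safe_sq_corr(yhat_te, y[fold.test]))
        r2_train.append(_safe_sq_corr(yhat_tr, y[fold.train]))

    if len(fits) < max(2, (len(folds) + 1) // 2):
        raise RuntimeError(
            f"ensemble for {variable_id} tau={tau}: only {len(fits)}/{len(folds)} "
            "folds succeeded")

    dev = np.array(dev)
    r2_test = np.array(r2_test)
    r2_train = np.array(r2_train)
    metrics = {
        "deviance_explained_mean": float(np.nanmean(dev)),
        "deviance_explained_lo": _pct_ci(dev)[0],
        "deviance_explained_hi": _pct_ci(dev)[1],
        "r2_test_mean": float(np.nanmean(r2_test)),
        "r2_test_lo": _pct_ci(r2_test)[0],
        "r2_test_hi": _pct_ci(r2_test)[1],
        "r2_train_mean": float(np.nanmean(r2_train)),
        "r2_train_lo": _pct_ci(r2_train)[0],
        "r2_train_hi": _pct_ci(r2_train)[1],
        "n_failed_folds": float(n_failed),
    }
    return EnsembleModel(variable_id=variable_id, tau=tau, fits=fits,
                         fold_train_indices=[f.train for f in used],
                         fold_test_indices=[f.test for f in used],
                         metrics=metrics,
                         lam=float(lam) if lam is not None else float("nan"))


def crossing_rate(fits_by_tau: dict[float, QuantileFit], x_eval) -> float:
    """Fraction of evaluation points where fitted quantile curves cross.

    Crossing is reported, never silently repaired.
    """
    taus = sorted(fits_by_tau)
    if len(taus) < 2:
        return 0.0
    x = np.atleast_1d(np.asarray(x_eval, float))
    preds = np.vstack([fits_by_tau[t].predict(x)[0] for t in taus])
    violated = np.zeros(x.size, bool)
    for i in range(len(taus) - 1):
        violated |= preds[i] > preds[i + 1] + 1e-12
    return float(violated.mean())
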