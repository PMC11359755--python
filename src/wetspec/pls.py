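"""NIPALS partial least squares regression with a single response (PLS-1).

Organised in the model/results style: :class:`PLS1` holds the data and
fitting options, ``PLS1.fit(n_lv)`` returns a :class:`PLS1Results` that
carries weights, scores, loadings, the collapsed regression vector,
per-latent-variable explained variance, and the Q-residual / Hotelling
T-squared diagnostics used for outlier screening.

For a univariate response the NIPALS recursion is finite — no inner
iteration is required.  Per component ``a`` on the deflated, mean-centred
data::

    w_a = X'y / ||X'y||          (weights, unit norm)
    t_a = X w_a                  (scores)
    p_a = X't_a / (t_a't_a)      (x-loadings)
    q_a = y't_a / (t_a't_a)      (y-loading)
    X  <- X - t_a p_a',  y <- y - t_a q_a

The regression vector is ``b = W (P'W)^{-1} q`` with intercept
``b0 = y_mean - x_mean . b``.  Weight signs are fixed so that the
largest-magnitude element of each ``w_a`` is positive, making loadings
reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["PLS1", "PLS1Results", "RankError", "fit_pls1"]

#: Relative threshold on ||X'y|| below which the response is treated as
#: exhausted (rank exhaustion).
RANK_TOL = 1e-12


class RankError(np.linalg.LinAlgError):
    """Requested more latent variables than the data support."""


class PLS1:
    """PLS-1 model specification.

    Parameters
    ----------
    endog : (n,) response values.
    exog : (n, p) predictor matrix (typically derivative spectra).
    wavelengths_nm : optional (p,) grid carried through to loadings.
    center : mean-centre X and y (default True).  Autoscaling (unit
        variance per column) is available via ``scale=True`` but is off
        by default: for derivative spectra, amplitude carries information.
    """

    def __init__(self, endog, exog, wavelengths_nm=None, center: bool = True,
                 scale: bool = False):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError("endog and exog row counts differ")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in endog/exog")
        self.endog = y
        self.exog = X
        self.nobs, self.nvar = X.shape
        self.center = center
        self.scale = scale
        if wavelengths_nm is not None:
            wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
            if wavelengths_nm.size != self.nvar:
                raise ValueError("wavelengths_nm length must equal exog columns")
        self.wavelengths_nm = wavelengths_nm

    @classmethod
    def from_spectra(cls, spectra, reference, constituent: str, **kwargs) -> "PLS1":
        """Build from a SpectraSet and a ReferenceTable for one constituent."""
        ids = spectra.meta["sample_id"].tolist()
        y = reference.values_for(constituent, ids)
        return cls(y, spectra.values, wavelengths_nm=spectra.wavelengths_nm, **kwargs)

    def fit(self, n_lv: int) -> "PLS1Results":
        if n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if n_lv > min(self.nobs - 1, self.nvar):
            raise RankError(
                f"n_lv={n_lv} exceeds min(n-1, p)={min(self.nobs - 1, self.nvar)}"
            )
        X = self.exog
        y = self.endog
        x_mean = X.mean(axis=0) if self.center else np.zeros(self.nvar)
        y_mean = float(y.mean()) if self.center else 0.0
        x_std = np.ones(self.nvar)
        if self.scale:
            x_std = X.std(axis=0, ddof=1)
            x_std[x_std == 0] = 1.0
        X0 = (X - x_mean) / x_std
        y0 = y - y_mean

        n, p = X0.shape
        Xd = X0.copy()
        yd = y0.copy()
        W = np.empty((p, n_lv))
        P = np.empty((p, n_lv))
        q = np.empty(n_lv)
        T = np.empty((n, n_lv))
        ssx0 = float(np.sum(X0 * X0))
        ssy0 = float(np.sum(y0 * y0))
        # scale against which X'y is judged exhausted: an upper bound on its
        # norm, so a response orthogonal to X triggers the rank error even
        # on the first component
        norm0 = np.sqrt(ssx0 * ssy0)
        for a in range(n_lv):
            cov = Xd.T @ yd
            nc = np.linalg.norm(cov)
            if not np.isfinite(nc) or nc <= RANK_TOL * max(norm0, 1e-300):
                raise RankError(
                    f"response orthogonal to remaining predictors at component {a + 1}"
                )
            w = cov / nc
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:  # sign convention: dominant weight positive
                w = -w
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 0 or not np.isfinite(tt):
                raise RankError(f"degenerate score vector at component {a + 1}")
            pa = Xd.T @ t / tt
            qa = float(yd @ t) / tt
            Xd -= np.outer(t, pa)
            yd -= t * qa
            W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t

        PtW = P.T @ W
        b = W @ np.linalg.solve(PtW, q)
        b0 = y_mean - float(x_mean / x_std @ b)
        tt_all = np.sum(T * T, axis=0)
        score_var = tt_all / (n - 1)
        expl_x = tt_all * np.sum(P * P, axis=0) / ssx0 if ssx0 > 0 else np.zeros(n_lv)
        expl_y = (q**2 * tt_all) / ssy0 if ssy0 > 0 else np.zeros(n_lv)
        return PLS1Results(
            model=self,
            n_lv=n_lv,
            x_mean=x_mean,
            x_std=x_std,
            y_mean=y_mean,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            scores=T,
            score_variances=score_var,
            coef=b / x_std,
            intercept=b0,
            explained_x_variance=expl_x,
            explained_y_variance=expl_y,
        )


@dataclass
class PLS1Results:
    """Fitted PLS-1 model: estimates, diagnostics and prediction."""

    model: PLS1 | None
    n_lv: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray        # W, p x A, unit-norm columns
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # q, A
    scores: np.ndarray | None  # T, n x A (calibration scores)
    score_variances: np.ndarray
    coef: np.ndarray           # regression vector b on the original X scale
    intercept: float
    explained_x_variance: np.ndarray
    explained_y_variance: np.ndarray
    wavelengths_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.wavelengths_nm is None and self.model is not None:
            self.wavelengths_nm = self.model.wavelengths_nm
        # rotation mapping centred X to scores: R = W (P'W)^{-1}
        self._rotation = self.weights @ np.linalg.inv(
            self.x_loadings.T @ self.weights
        )

    # -- prediction ---------------------------------------------------------
    def predict(self, X_new, n_lv: int | None = None) -> np.ndarray:
        """Predicted responses, optionally truncated to the first n_lv LVs."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"exog has {X_new.shape[1]} columns, model expects {self.coef.size}"
            )
        if n_lv is None or n_lv == self.n_lv:
            return self.intercept + X_new @ self.coef
        b, b0 = self.coef_path()[n_lv]
        return b0 + X_new @ b

    def coef_path(self) -> dict[int, tuple[np.ndarray, float]]:
        """Regression vector and intercept for every truncation 1..n_lv.

        One fitted model therefore yields predictions at every smaller
        component count, which makes the latent-variable grid search a
        single fit per fold.
        """
        out = {}
        for a in range(1, self.n_lv + 1):
            W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
            b = W @ np.linalg.solve(P.T @ W, q) / self.x_std
            b0 = self.y_mean - float(self.x_mean @ b)
            out[a] = (b, b0)
        return out

    # -- projections and diagnostics ----------------------------------------
    def transform(self, X_new) -> np.ndarray:
        """Score matrix for new observations (centred X times rotation)."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError("column count mismatch")
        return ((X_new - self.x_mean) / self.x_std) @ self._rotation

    def q_residuals(self, X_new) -> np.ndarray:
        """Squared reconstruction residual per row (distance from the LV span)."""
        X0 = (np.atleast_2d(np.asarray(X_new, dtype=float)) - self.x_mean) / self.x_std
        T = X0 @ self._rotation
        E = X0 - T @ self.x_loadings.T
        return np.sum(E * E, axis=1)

    def hotelling_t2(self, X_new) -> np.ndarray:
        """Hotelling T-squared of each row within the latent subspace."""
        if np.any(self.score_variances <= 0):
            raise ValueError("degenerate model: zero calibration score variance")
        T = self.transform(X_new)
        return np.sum(T * T / self.score_variances, axis=1)

    def loading_spectrum(self, a: int) -> tuple[np.ndarray | None, np.ndarray]:
        """(wavelengths, loading) of latent variable ``a`` (1-based)."""
        if not 1 <= a <= self.n_lv:
            raise IndexError(f"latent variable index {a} out of range 1..{self.n_lv}")
        return self.wavelengths_nm, self.x_loadings[:, a - 1].copy()

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "PLS-1 regression (NIPALS)",
            f"  observations: {self.scores.shape[0] if self.scores is not None else '?'}"
            f"   predictors: {self.coef.size}   latent variables: {self.n_lv}",
            "  LV   expl.var X   expl.var y   score var",
        ]
        for a in range(self.n_lv):
            lines.append(
                f"  {a + 1:2d}   {self.explained_x_variance[a]:10.4f}"
                f"   {self.explained_y_variance[a]:10.4f}"
                f"   {self.score_variances[a]:10.4g}"
            )
        lines.append(
            f"  cumulative explained X: {self.explained_x_variance.sum():.4f}"
            f"   y: {self.explained_y_variance.sum():.4f}"
        )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "format": "wetspec-pls1",
            "version": 1,
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "score_variances": self.score_variances.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "explained_x_variance": self.explained_x_variance.tolist(),
            "explained_y_variance": self.explained_y_variance.tolist(),
            "wavelengths_nm": None
            if self.wavelengths_nm is None
            else self.wavelengths_nm.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLS1Results":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        if doc.get("format") != "wetspec-pls1":
            raise ValueError("not a wetspec PLS-1 model document")
        arr = lambda k: np.asarray(doc[k], dtype=float)
        return cls(
            model=None,
            n_lv=int(doc["n_lv"]),
            x_mean=arr("x_mean"),
            x_std=arr("x_std"),
            y_mean=float(doc["y_mean"]),
            weights=arr("weights"),
            x_loadings=arr("x_loadings"),
            y_loadings=arr("y_loadings"),
            scores=None,
            score_variances=arr("score_variances"),
            coef=arr("coef"),
            intercept=float(doc["intercept"]),
            explained_x_variance=arr("explained_x_variance"),
            explained_y_variance=arr("explained_y_variance"),
            wavelengths_nm=None
            if doc["wavelengths_nm"] is None
            else arr("wavelengths_nm"),
        )


def fit_pls1(X, y, n_lv: int, **kwargs) -> PLS1Results:
    """Functional shorthand for ``PLS1(y, X, **kwargs).fit(n_lv)``."""
    return PLS1(y, X, **kwargs).fit(n_lv)
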