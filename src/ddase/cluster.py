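"""Gaussian mixture modelling of samples in expression space.

The puberty-state analysis places every testis sample in a 2-D feature
space (log amh/igf3 rate ratio, vgll3 copies/ng) and asks whether the
samples fall into more than one Gaussian cluster. The EM fitter here is
written from scratch (sklearn's mixture model is used only as an
independent cross-check in the test suite): k-means++ seeded restarts,
a covariance ridge for near-singular components, BIC model selection over
a (components x covariance-model) grid, and a parametric bootstrap
likelihood-ratio test for the number of components, in which B datasets
simulated from the smaller fitted model are refit under both hypotheses
and the observed statistic is ranked among them with the add-one rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import as_rng
from .exceptions import ValidationError

_LOG2PI = math.log(2.0 * math.pi)

COV_MODELS = ("full", "tied", "diag", "spherical")


def _kmeanspp(X: np.ndarray, g: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial means according to squared distance."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, g):
        d2 = np.min(((X[:, None, :] - X[idx][None, :, :]) ** 2).sum(-1), axis=1)
        tot = d2.sum()
        if tot <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / tot)))
    return X[idx].copy()


def _chol_logdet(cov: np.ndarray, ridge: float):
    """Cholesky factor and log-determinant, adding a ridge if near singular."""
    d = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + np.eye(d) * (ridge * max(np.trace(cov) / d, 1e-12) + 1e-12)
        L = np.linalg.cholesky(cov)
    return cov, L, 2.0 * float(np.log(np.diag(L)).sum())


class _Degenerate(Exception):
    pass


class GaussianMixtureEM(BaseEstimator):
    """EM-fitted Gaussian mixture with restarts, in the sklearn idiom.

    Parameters
    ----------
    n_components : number of Gaussian components G.
    covariance_type : "full", "tied", "diag" or "spherical" ("tied" shares
        one full covariance across components; the others are
        per-component).
    n_init : number of seeded k-means++ restarts; the best log-likelihood
        wins.
    tol : relative log-likelihood change declaring convergence.
    ridge : fractional ridge added to a component covariance diagonal when
        it approaches singularity.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, covariances_ (always stored as full matrices),
    log_likelihood_, log_likelihood_path_, bic_, converged_, n_iter_.
    BIC is the minimization convention, -2 loglik + n_params ln n.
    """

    def __init__(self, n_components=1, covariance_type="full", n_init=5,
                 tol=1e-8, max_iter=500, ridge=1e-6, random_state=None):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _log_prob(self, X, means, covs):
        g = len(means)
        n, d = X.shape
        out = np.empty((n, g))
        if d == 2:
            # hand-coded 2x2 path: the clustering space is 2-D and the
            # bootstrap refits dominate runtime
            for k in range(g):
                cov = covs[k]
                a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
                det = a * c - b * b
                if det <= 0 or a <= 0 or c <= 0:
                    r = self.ridge * max((a + c) / 2.0, 1e-12) + 1e-12
                    a, c = a + r, c + r
                    det = a * c - b * b
                    covs[k] = np.array([[a, b], [b, c]])
                d0 = X[:, 0] - means[k][0]
                d1 = X[:, 1] - means[k][1]
                q = (c * d0 * d0 - 2.0 * b * d0 * d1 + a * d1 * d1) / det
                out[:, k] = -0.5 * (2.0 * _LOG2PI + math.log(det) + q)
            return out, None
        chols = []
        for k in range(g):
            cov, L, logdet = _chol_logdet(covs[k], self.ridge)
            covs[k] = cov
            chols.append(L)
            diff = X - means[k]
            sol = np.linalg.solve(L, diff.T)
            out[:, k] = -0.5 * (d * _LOG2PI + logdet + (sol * sol).sum(axis=0))
        return out, chols

    def _m_step(self, X, resp):
        n, d = X.shape
        nk = resp.sum(axis=0)
        if np.min(nk) < 1.0:  # component weight below 1/n: degenerate
            raise _Degenerate
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = []
        for k in range(len(nk)):
            diff = X - means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs.append(cov)
        ct = self.covariance_type
        if ct == "tied":
            tied = sum(nk[k] * covs[k] for k in range(len(nk))) / n
            covs = [tied.copy() for _ in nk]
        elif ct == "diag":
            covs = [np.diag(np.diag(c)) for c in covs]
        elif ct == "spherical":
            covs = [np.eye(d) * (np.trace(c) / d) for c in covs]
        elif ct != "full":
            raise ValidationError(f"unknown covariance_type {ct!r}")
        return weights, means, covs

    def _fit_once(self, X, rng):
        n, d = X.shape
        g = self.n_components
        means = _kmeanspp(X, g, rng)
        base = np.cov(X.T, bias=True).reshape(d, d)
        base = base + np.eye(d) * (self.ridge * max(np.trace(base) / d, 1e-12))
        covs = [base.copy() for _ in range(g)]
        weights = np.full(g, 1.0 / g)
        ll_prev = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            logp, _ = self._log_prob(X, means, covs)
            logp = logp + np.log(weights)
            m = logp.max(axis=1)
            lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
            ll = float(lse.sum())
            path.append(ll)
            resp = np.exp(logp - lse[:, None])
            weights, means, covs = self._m_step(X, resp)
            if ll_prev > -np.inf and abs(ll - ll_prev) <= self.tol * abs(ll):
                converged = True
                break
            ll_prev = ll
        # final log-likelihood at the last parameter update
        logp, _ = self._log_prob(X, means, covs)
        lse_in = logp + np.log(weights)
        m = lse_in.max(axis=1)
        ll = float((m + np.log(np.exp(lse_in - m[:, None]).sum(axis=1))).sum())
        path.append(ll)
        return weights, means, covs, ll, path, converged, it

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D array")
        if not np.isfinite(X).all():
            raise ValidationError("X contains non-finite values")
        n, d = X.shape
        g = self.n_components
        if n <= g * (d + 1):
            raise ValidationError(
                f"need n > G(d+1) = {g * (d + 1)} points to fit {g} components")
        rng = as_rng(self.random_state)

        if g == 1:
            mean = X.mean(axis=0)
            cov = np.cov(X.T, bias=True).reshape(d, d)
            ct = self.covariance_type
            if ct == "diag":
                cov = np.diag(np.diag(cov))
            elif ct == "spherical":
                cov = np.eye(d) * (np.trace(cov) / d)
            cov, L, logdet = _chol_logdet(cov, self.ridge)
            diff = X - mean
            sol = np.linalg.solve(L, diff.T)
            ll = float(-0.5 * (d * _LOG2PI + logdet) * n - 0.5 * (sol * sol).sum())
            self.weights_ = np.array([1.0])
            self.means_ = mean[None, :]
            self.covariances_ = cov[None, :, :]
            self.log_likelihood_ = ll
            self.log_likelihood_path_ = [ll]
            self.converged_ = True
            self.n_iter_ = 0
        else:
            best = None
            successes = 0
            attempts = 0
            # a collapsed restart (component weight < 1/n) is retried with a
            # fresh seeding, up to a bounded number of extra attempts
            while successes < self.n_init and attempts < self.n_init + 10:
                attempts += 1
                try:
                    fit = self._fit_once(X, rng)
                except _Degenerate:
                    continue
                successes += 1
                if best is None or fit[3] > best[3]:
                    best = fit
            if best is None:
                raise ValidationError(
                    f"all {attempts} restarts collapsed onto degenerate "
                    "components")
            weights, means, covs, ll, path, converged, it = best
            self.weights_ = weights
            self.means_ = np.asarray(means)
            self.covariances_ = np.asarray(covs)
            self.log_likelihood_ = ll
            self.log_likelihood_path_ = path
            self.converged_ = converged
            self.n_iter_ = it

        self.n_features_in_ = d
        self.n_samples_ = n
        self.bic_ = -2.0 * self.log_likelihood_ + self._n_params(d) * math.log(n)
        return self

    def _n_params(self, d: int) -> int:
        g = self.n_components
        cov = {"full": g * d * (d + 1) // 2,
               "tied": d * (d + 1) // 2,
               "diag": g * d,
               "spherical": g}[self.covariance_type]
        return (g - 1) + g * d + cov

    def score_samples(self, X):
        X = np.asarray(X, dtype=float)
        logp, _ = self._log_prob(X, self.means_, list(self.covariances_))
        logp = logp + np.log(self.weights_)
        m = logp.max(axis=1)
        return m + np.log(np.exp(logp - m[:, None]).sum(axis=1))

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        logp, _ = self._log_prob(X, self.means_, list(self.covariances_))
        logp = logp + np.log(self.weights_)
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
        return np.exp(logp - lse[:, None])

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def sample(self, n: int, rng=None) -> np.ndarray:
        """Parametric draw of ``n`` points from the fitted mixture."""
        rng = as_rng(rng)
        counts = rng.multinomial(n, self.weights_)
        parts = []
        for k, c in enumerate(counts):
            if c:
                L = np.linalg.cholesky(self.covariances_[k])
                parts.append(self.means_[k]
                             + rng.standard_normal((c, len(self.means_[k]))) @ L.T)
        X = np.vstack(parts)
        return X[rng.permutation(n)]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class GMMFit:
    n_components: int
    covariance_type: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int
    model: GaussianMixtureEM


def fit_gmm(X, n_components: int, covariance_type: str = "full", *,
            seed=None, tol: float = 1e-8, max_iter: int = 500,
            n_init: int = 5, ridge: float = 1e-6) -> GMMFit:
    est = GaussianMixtureEM(n_components=n_components,
                            covariance_type=covariance_type, n_init=n_init,
                            tol=tol, max_iter=max_iter, ridge=ridge,
                            random_state=seed).fit(X)
    return GMMFit(n_components, covariance_type, est.weights_, est.means_,
                  est.covariances_, est.log_likelihood_, est.bic_,
                  est.converged_, est.n_iter_, est)


def select_bic(X, g_range=(1, 2, 3), cov_models=("full",), *, seed=None,
               **fit_kwargs) -> tuple[GMMFit, pd.DataFrame]:
    """Fit the (G, covariance model) grid; return the lowest-BIC fit + table."""
    rows, best = [], None
    rng = as_rng(seed)
    for g in g_range:
        for cm in cov_models:
            sub = int(rng.integers(2 ** 31))
            try:
                fit = fit_gmm(X, g, cm, seed=sub, **fit_kwargs)
            except (ValidationError, np.linalg.LinAlgError) as exc:
                rows.append({"n_components": g, "covariance_type": cm,
                             "bic": math.nan, "log_likelihood": math.nan,
                             "converged": False, "error": str(exc)})
                continue
            rows.append({"n_components": g, "covariance_type": cm,
                         "bic": fit.bic, "log_likelihood": fit.log_likelihood,
                         "converged": fit.converged, "error": ""})
            if best is None or fit.bic < best.bic:
                best = fit
    if best is None:
        raise ValidationError("every (G, covariance model) fit failed")
    return best, pd.DataFrame(rows)


@dataclass
class BootstrapLRT:
    observed_lrt: float
    boot_stats: np.ndarray
    p_value: float
    b: int
    g0: int
    g1: int


def bootstrap_lrt(X, g0: int, g1: int | None = None, b: int = 1000, *,
                  seed=None, covariance_type: str = "full", n_init: int = 2,
                  max_iter: int = 200, tol: float = 1e-6,
                  max_redraws_factor: int = 5) -> BootstrapLRT:
    """Parametric bootstrap LRT for g0 vs g0+1 mixture components.

    The observed statistic is 2(loglik_G1 - loglik_G0) (clipped at zero);
    B datasets of the same size are simulated from the fitted G0 model and
    refit under both hypotheses with the same EM settings, and

        p = (1 + #{boot >= observed}) / (B + 1)

    so p is never exactly zero. A bootstrap draw whose refit collapses is
    redrawn, up to ``max_redraws_factor x B`` total attempts.
    """
    if g1 is None:
        g1 = g0 + 1
    if g1 != g0 + 1:
        raise ValidationError("bootstrap LRT compares G0 against G0 + 1")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    rng = as_rng(seed)
    kw = dict(covariance_type=covariance_type, n_init=n_init,
              max_iter=max_iter, tol=tol)

    def lrt(data):
        f0 = fit_gmm(data, g0, seed=int(rng.integers(2 ** 31)), **kw)
        f1 = fit_gmm(data, g1, seed=int(rng.integers(2 ** 31)), **kw)
        return max(0.0, 2.0 * (f1.log_likelihood - f0.log_likelihood)), f0

    observed, fit0 = lrt(X)
    stats_out = np.empty(b)
    attempts = 0
    i = 0
    while i < b:
        if attempts >= max_redraws_factor * b:
            raise RuntimeError("too many failed bootstrap refits")
        attempts += 1
        data = fit0.model.sample(n, rng)
        try:
            stat, _ = lrt(data)
        except ValidationError:
            continue
        stats_out[i] = stat
        i += 1
    p = (1.0 + float((stats_out >= observed).sum())) / (b + 1.0)
    return BootstrapLRT(observed, stats_out, p, b, g0, g1)


def confidence_ellipse(fit: GMMFit | GaussianMixtureEM, level: float = 0.95):
    """Per-component 95%-coverage ellipses from covariance eigenstructure.

    Returns a list of dicts with ``center``, ``semi_axes`` (major, minor;
    sqrt(chi2_2(level) * eigenvalue)) and ``angle_deg`` of the major axis.
    """
    means = fit.means if isinstance(fit, GMMFit) else fit.means_
    covs = fit.covariances if isinstance(fit, GMMFit) else fit.covariances_
    if means.shape[1] != 2:
        raise ValidationError("confidence ellipses are defined for 2-D fits")
    q = stats.chi2.ppf(level, df=2)
    out = []
    for mean, cov in zip(means, covs):
        vals, vecs = np.linalg.eigh(cov)
        if np.min(vals) <= 0:
            raise ValidationError("covariance is not positive definite")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        angle = math.degrees(math.atan2(vecs[1, 0], vecs[0, 0]))
        out.append({"center": np.asarray(mean, dtype=float),
                    "semi_axes": np.sqrt(q * vals),
                    "angle_deg": angle})
    return out
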