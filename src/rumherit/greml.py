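"""Single-kernel GREML: REML variance components and heritability.

Model
-----
y = X beta + u + eps, with u ~ N(0, sigma_u^2 A) for a genetic relationship
matrix A and eps ~ N(0, sigma_e^2 I), so Var(y) = sigma_u^2 A + sigma_e^2 I
and the narrow-sense heritability is h2 = sigma_u^2 / (sigma_u^2 + sigma_e^2).

The restricted likelihood is profiled to one dimension.  Writing
V = sigma2 * H(h2) with H = h2 A + (1 - h2) I and sigma2 the total variance,
both beta and sigma2 have closed-form optima given h2, leaving a bounded
scalar maximization of

    l_R(h2) = -1/2 [ (n-p) log(2 pi sigmahat2) + (n-p)
                     + log|H| + log|X' H^-1 X| ]

over h2 in [0, 1].  A single eigendecomposition A = Q L Q' makes every
evaluation O(n) after rotating y and X by Q', so thousands of phenotypes
(and permutation nulls) reuse one spectral cache.  The maximizer is a
coarse grid followed by golden-section refinement inside the bracketing
cell — deterministic, no random restarts — and the boundary points h2 = 0
and h2 = 1 are always compared explicitly, so boundary solutions are exact
and the likelihood-ratio statistic against the sigma_u^2 = 0 null is
nonnegative by construction.

The null distribution of that statistic is the boundary case of the LRT:
an equal mixture of a point mass at zero and chi-square with 1 df, giving
p = 0.5 * Pr(chi2_1 >= LR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, InputError, NumericalError
from .grm import RelatednessMatrix

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
_NEG_INF = -np.inf


@dataclass
class VarianceComponents:
    """REML estimates for one phenotype.

    h2 always equals sigma_u2 / (sigma_u2 + sigma_e2); lr_statistic is
    2 * (loglik_full - loglik_null) clipped at zero.
    """

    sigma_u2: float
    sigma_e2: float
    h2: float
    loglik_full: float
    loglik_null: float
    lr_statistic: float
    p_value: float
    converged: bool
    n_used: int


class EigenGRM:
    """Spectral cache of a relatedness matrix for repeated REML fits.

    Performs the one-off eigendecomposition A = Q L Q^T and repairs small
    PSD violations by clipping negative eigenvalues to zero.  Two sources
    of negativity are tolerated: floating-point noise, and the mildly
    indefinite matrices that pairwise-complete GRM estimation produces when
    genotypes have missing calls (each pair's estimate uses its own SNP
    subset, so the assembled matrix need not be PSD).  Eigenvalues below
    ``-neg_tol * trace/n`` indicate a genuinely broken kernel and raise.
    """

    def __init__(self, a, neg_tol: float = 0.05):
        if isinstance(a, RelatednessMatrix):
            self.animal_ids: list[str] | None = list(a.animal_ids)
            mat = a.values
        else:
            self.animal_ids = None
            mat = np.asarray(a, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise InputError("relatedness matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise InputError("relatedness matrix is not symmetric")
        try:
            lam, q = np.linalg.eigh((mat + mat.T) / 2.0)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise NumericalError(f"eigendecomposition failed: {exc}") from exc
        scale = max(np.trace(mat) / mat.shape[0], np.finfo(float).tiny)
        if lam.min() < -neg_tol * scale:
            raise NumericalError(
                f"relatedness matrix is not PSD (min eigenvalue {lam.min():.3g}, "
                f"tolerance {-neg_tol * scale:.3g})"
            )
        lam = np.maximum(lam, 0.0)
        # snap near-null directions to exactly zero: a cohort-frequency GRM
        # annihilates the ones vector up to rounding, and a ~1e-15 eigenvalue
        # lets h2 = 1 slip past the singularity guard into catastrophic
        # cancellation in the profiled quadratic form
        lam[lam < 1e-10 * max(lam.max(), np.finfo(float).tiny)] = 0.0
        self.eigenvalues = lam
        self.eigenvectors = q
        self.n = mat.shape[0]

    def rotate(self, m: np.ndarray) -> np.ndarray:
        """Q^T m — map vectors into the eigenbasis where Var(y) is diagonal."""
        return self.eigenvectors.T @ m


def _as_eigen(a) -> EigenGRM:
    return a if isinstance(a, EigenGRM) else EigenGRM(a)


def eigen_prepare(a) -> EigenGRM:
    """Build the spectral cache used by :func:`reml_fit` and the batch fitters."""
    return _as_eigen(a)


def _loglik_h2(lam, yt, xt, h2):
    """Profiled REML log-likelihood at per-phenotype h2 values.

    Parameters
    ----------
    lam : (n,) eigenvalues of A
    yt : (n, P) rotated phenotypes
    xt : (n, p) rotated fixed-effect design
    h2 : (P,) heritability values, one per phenotype

    Returns
    -------
    ll : (P,) log-likelihoods (-inf where H(h2) is singular)
    sigma2 : (P,) profiled total variances
    """
    n, p = xt.shape
    h2 = np.asarray(h2, dtype=float)
    d = h2[None, :] * lam[:, None] + (1.0 - h2)[None, :]  # (n, P)
    bad = (d <= 0.0).any(axis=0)
    d = np.where(d <= 0.0, 1.0, d)
    w = 1.0 / d
    xtdx = np.einsum("ia,ij,ib->jab", xt, w, xt)  # (P, p, p)
    xtdy = np.einsum("ia,ij,ij->ja", xt, w, yt)  # (P, p)
    ytdy = np.einsum("ij,ij->j", yt * w, yt)  # (P,)
    beta = np.linalg.solve(xtdx, xtdy[..., None])[..., 0]
    quad = np.maximum(ytdy - np.einsum("ja,ja->j", xtdy, beta), 1e-300)
    sigma2 = quad / (n - p)
    _, logdet_x = np.linalg.slogdet(xtdx)
    logdet_d = np.log(d).sum(axis=0)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_d + logdet_x
    )
    return np.where(bad, _NEG_INF, ll), sigma2


def reml_loglik(a, y: np.ndarray, h2: float, X: np.ndarray | None = None) -> float:
    """Profiled REML log-likelihood of one phenotype at a fixed h2.

    Exposed so independent oracles (direct-matrix grid searches) can be
    compared against the rotated evaluation path.
    """
    eig = _as_eigen(a)
    y = np.asarray(y, dtype=float).reshape(-1)
    x = np.ones((eig.n, 1)) if X is None else np.asarray(X, dtype=float)
    ll, _ = _loglik_h2(eig.eigenvalues, eig.rotate(y[:, None]), eig.rotate(x), [h2])
    return float(ll[0])


def _maximize_batch(lam, yt, xt, grid_points=41, refine_iters=48, tol=1e-8):
    """Vectorized grid + golden-section maximization of the profiled REML
    log-likelihood over h2 in [0, 1], per phenotype column of ``yt``."""
    grid = np.linspace(0.0, 1.0, grid_points)
    ll_grid = np.stack([_loglik_h2(lam, yt, xt, np.full(yt.shape[1], g))[0] for g in grid])
    best = np.argmax(ll_grid, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid_points - 1)]

    # fixed iteration count (no data-dependent break): every phenotype's
    # trajectory is then independent of which others share the batch, so
    # batch and single fits agree exactly
    a, b = lo.copy(), hi.copy()
    for _ in range(refine_iters):
        span = b - a
        x1 = b - _INVPHI * span
        x2 = a + _INVPHI * span
        f1, _ = _loglik_h2(lam, yt, xt, x1)
        f2, _ = _loglik_h2(lam, yt, xt, x2)
        take_right = f1 < f2
        a = np.where(take_right, x1, a)
        b = np.where(take_right, b, x2)
    h2_mid = (a + b) / 2.0

    # compare against exact boundaries so boundary optima are returned exactly
    cand = np.stack([h2_mid, np.zeros_like(h2_mid), np.ones_like(h2_mid)])
    lls = np.stack([_loglik_h2(lam, yt, xt, c)[0] for c in cand])
    pick = np.argmax(lls, axis=0)
    h2_hat = cand[pick, np.arange(cand.shape[1])]
    ll_hat, sigma2_hat = _loglik_h2(lam, yt, xt, h2_hat)
    ll_null, _ = _loglik_h2(lam, yt, xt, np.zeros_like(h2_hat))
    return h2_hat, sigma2_hat, ll_hat, ll_null


def lrt_pvalue(v) -> float:
    """Boundary-mixture likelihood-ratio p-value for sigma_u^2 > 0.

    Accepts a VarianceComponents or a raw LR statistic.  Tiny negative
    statistics (numerical noise) are clipped to zero; p = 0.5 at LR = 0.
    """
    lr = v.lr_statistic if isinstance(v, VarianceComponents) else float(v)
    if lr < -1e-8:
        raise InputError(f"likelihood-ratio statistic is negative: {lr}")
    return float(0.5 * stats.chi2.sf(max(lr, 0.0), df=1))


class GREML(BaseEstimator):
    """Scikit-learn-style GREML estimator for a single precomputed kernel.

    Parameters
    ----------
    fit_intercept : bool
        Include an intercept column when no design matrix is supplied.
    grid_points : int
        Coarse-grid resolution over h2 before golden-section refinement.
    refine_iters : int
        Golden-section iterations; 48 shrinks the bracketing cell far below
        the 1e-8 tolerance.
    min_animals : int
        Minimum phenotyped animals accepted by :meth:`fit`.

    Attributes (after fit)
    ----------------------
    h2_, sigma_u2_, sigma_e2_, loglik_, loglik_null_, lr_, pvalue_,
    converged_, n_used_

    Examples
    --------
    >>> est = GREML().fit(A, y)      # A: (n, n) GRM, y: (n,) phenotype
    >>> est.h2_, est.pvalue_         # doctest: +SKIP
    """

    def __init__(self, fit_intercept=True, grid_points=41, refine_iters=48,
                 tol=1e-8, min_animals=10):
        self.fit_intercept = fit_intercept
        self.grid_points = grid_points
        self.refine_iters = refine_iters
        self.tol = tol
        self.min_animals = min_animals

    def fit(self, K, y, X=None):
        """Fit variance components for phenotype ``y`` under kernel ``K``.

        Parameters
        ----------
        K : ndarray (n, n), RelatednessMatrix or EigenGRM
        y : array-like (n,)
        X : array-like (n, p), optional fixed-effect design.  Defaults to
            an intercept column when ``fit_intercept`` is set.
        """
        eig = _as_eigen(K)
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.shape[0] != eig.n:
            raise InputError(f"phenotype length {y.shape[0]} != kernel size {eig.n}")
        if y.shape[0] < self.min_animals:
            raise InputError(
                f"{y.shape[0]} animals < minimum {self.min_animals} for a REML fit"
            )
        if np.ptp(y) == 0.0:
            raise DegenerateDataError("phenotype has zero variance")
        if X is None:
            if not self.fit_intercept:
                raise InputError("X is required when fit_intercept=False")
            x = np.ones((eig.n, 1))
        else:
            x = np.asarray(X, dtype=float)
            if x.ndim == 1:
                x = x[:, None]
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise InputError("fixed-effect design is rank deficient")

        yt = eig.rotate(y[:, None])
        xt = eig.rotate(x)
        h2, sigma2, ll, ll0 = _maximize_batch(
            eig.eigenvalues, yt, xt, self.grid_points, self.refine_iters, self.tol
        )
        h2, sigma2, ll, ll0 = float(h2[0]), float(sigma2[0]), float(ll[0]), float(ll0[0])
        self.converged_ = bool(np.isfinite(ll) and np.isfinite(sigma2))
        self.h2_ = h2
        self.sigma_u2_ = h2 * sigma2
        self.sigma_e2_ = (1.0 - h2) * sigma2
        self.loglik_ = ll
        self.loglik_null_ = ll0
        self.lr_ = max(2.0 * (ll - ll0), 0.0)
        self.pvalue_ = lrt_pvalue(self.lr_)
        self.n_used_ = eig.n
        return self

    def components_(self) -> VarianceComponents:
        """Bundle the fitted attributes into a VarianceComponents record."""
        return VarianceComponents(
            sigma_u2=self.sigma_u2_,
            sigma_e2=self.sigma_e2_,
            h2=self.h2_,
            loglik_full=self.loglik_,
            loglik_null=self.loglik_null_,
            lr_statistic=self.lr_,
            p_value=self.pvalue_,
            converged=self.converged_,
            n_used=self.n_used_,
        )


def reml_fit(a, y, X=None, **params) -> VarianceComponents:
    """Functional wrapper over :class:`GREML` returning VarianceComponents."""
    return GREML(**params).fit(a, y, X=X).components_()


def reml_fit_batch(a, Y: np.ndarray, X=None, **params) -> list[VarianceComponents]:
    """Fit many phenotypes (columns of ``Y``) against one kernel.

    Uses the same grid + golden-section maximizer as :class:`GREML`
    vectorized across phenotypes, so results are identical to per-column
    :func:`reml_fit` calls.  Columns with zero variance raise; screen-level
    callers are expected to filter those first.
    """
    eig = _as_eigen(a)
    est = GREML(**params)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != eig.n:
        raise InputError("Y must be (n_animals, n_phenotypes)")
    if (np.ptp(Y, axis=0) == 0.0).any():
        raise DegenerateDataError("a phenotype column has zero variance")
    x = np.ones((eig.n, 1)) if X is None else np.asarray(X, dtype=float)
    yt = eig.rotate(Y)
    xt = eig.rotate(x)
    h2, sigma2, ll, ll0 = _maximize_batch(
        eig.eigenvalues, yt, xt, est.grid_points, est.refine_iters, est.tol
    )
    lr = np.maximum(2.0 * (ll - ll0), 0.0)
    out = []
    for j in range(Y.shape[1]):
        out.append(
            VarianceComponents(
                sigma_u2=float(h2[j] * sigma2[j]),
                sigma_e2=float((1.0 - h2[j]) * sigma2[j]),
                h2=float(h2[j]),
                loglik_full=float(ll[j]),
                loglik_null=float(ll0[j]),
                lr_statistic=float(lr[j]),
                p_value=lrt_pvalue(float(lr[j])),
                converged=bool(np.isfinite(ll[j])),
                n_used=eig.n,
            )
        )
    return out
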