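"""Selection-index solvers operating on covariance inputs.

A linear selection index ``I_i = x_i' beta`` weights ``p`` measured
phenotypes to predict the genetic merit of a target trait.  Every solver in
this module works purely from covariance-scale inputs: the phenotypic
covariance matrix ``P_x`` of the measured traits and the vector ``G_xy`` of
genetic covariances between each measured trait and the target.

Solvers
-------
standard_si
    ``beta = P_x^{-1} G_xy`` — the best linear predictor when (P, G) are
    known without error.
l2_psi
    Ridge-type penalized index ``beta = (P_x + lambda I)^{-1} G_xy``.
elastic_net_psi
    Coordinate descent on the covariance-form elastic-net objective
    ``-G'beta + beta'P beta / 2 + lambda * [ (1-alpha) ||beta||_2^2 / 2
    + alpha ||beta||_1 ]``, warm-started along a decreasing lambda grid.
lars_psi
    The full piecewise-linear L1 (alpha = 1) solution path by homotopy in
    lambda with the lasso modification (drop steps), entirely from
    covariance updates.
pc_si
    Reduced-rank index from the top-q principal components, with
    coefficients back-mapped to trait space.

Correctness of every L1/elastic-net solution is certified by the KKT
conditions of the convex objective (see :func:`kkt_violation`); reduction
identities (alpha = 0 -> ridge, lambda = 0 -> standard, q = p -> standard)
tie the solvers together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CovariancePair",
    "IndexCoefficients",
    "RegularizationPath",
    "SpectralDecomposition",
    "phenotypic_covariance",
    "standard_si",
    "l2_psi",
    "elastic_net_psi",
    "lars_psi",
    "spectral_decomposition",
    "pc_si",
    "compute_index",
    "kkt_violation",
    "default_lambda_grid",
]

logger = logging.getLogger(__name__)

#: Numeric contract of the coordinate-descent solver.
CD_TOL = 1e-9
CD_MAX_SWEEPS = 10_000
#: Condition-number guard for the unpenalized solve.
MAX_CONDITION = 1e12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CovariancePair:
    """Phenotypic covariance matrix plus genetic covariances with the target.

    Attributes
    ----------
    P : (p, p) ndarray
        Symmetric phenotypic covariance matrix of the measured traits.
    G : (p,) ndarray
        Genetic covariances between each measured trait and the target.
    sigma2_gy : float
        Genetic variance of the target trait (>= 0).
    band_labels, wavelengths, timepoints
        Optional metadata carried through to coefficients.
    """

    P: np.ndarray
    G: np.ndarray
    sigma2_gy: float = float("nan")
    band_labels: list = field(default_factory=list)
    wavelengths: np.ndarray | None = None
    timepoints: np.ndarray | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.G = np.asarray(self.G, dtype=float).ravel()
        p = self.G.shape[0]
        if self.P.shape != (p, p):
            raise ValueError(
                f"dimension mismatch: P is {self.P.shape}, G has length {p}"
            )
        asym = np.max(np.abs(self.P - self.P.T)) if p else 0.0
        if asym > 1e-10 * max(1.0, np.max(np.abs(self.P))):
            raise ValueError(f"P is not symmetric (max asymmetry {asym:.3e})")
        self.P = 0.5 * (self.P + self.P.T)
        if p and np.any(np.diag(self.P) <= 0):
            j = int(np.flatnonzero(np.diag(self.P) <= 0)[0])
            raise ValueError(f"P has non-positive diagonal at index {j}")
        if not self.band_labels:
            self.band_labels = list(range(p))

    @property
    def p(self) -> int:
        return self.G.shape[0]


@dataclass
class IndexCoefficients:
    """Waveband weights of one selection index with regularization metadata."""

    beta: np.ndarray
    method: str  # standard | L2 | EN | L1 | PC
    lam: float = 0.0
    alpha: float = 1.0
    q: int | None = None
    band_labels: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not self.band_labels:
            self.band_labels = list(range(self.beta.shape[0]))

    @property
    def active(self) -> np.ndarray:
        """Indices with a non-zero coefficient."""
        return np.flatnonzero(self.beta != 0.0)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.beta))


@dataclass
class RegularizationPath:
    """Sequence of solutions along decreasing lambda (or increasing q)."""

    method: str
    alpha: float
    lambdas: np.ndarray  # strictly decreasing (or q grid, increasing)
    coefficients: list  # of IndexCoefficients, aligned with ``lambdas``
    # L1-homotopy segments: (lam_hi, lam_lo, active indices, signs) allowing
    # exact evaluation of the path at any lambda.
    segments: list = field(default_factory=list)
    _P: np.ndarray | None = None
    _G: np.ndarray | None = None
    converged: bool = True

    def __len__(self) -> int:
        return len(self.coefficients)

    def at(self, lam: float) -> IndexCoefficients:
        """Coefficients at an arbitrary lambda.

        For a homotopy (LARS) path this is exact (piecewise linear in
        lambda); for a grid path the nearest not-smaller grid solution is
        returned.
        """
        if self.segments:
            p = self._G.shape[0]
            if lam >= self.lambdas[0]:
                return IndexCoefficients(np.zeros(p), method=self.method,
                                         lam=lam, alpha=self.alpha)
            for lam_hi, lam_lo, active, signs in self.segments:
                if lam_lo <= lam <= lam_hi:
                    beta = np.zeros(p)
                    if len(active):
                        K = self._P[np.ix_(active, active)]
                        beta[active] = np.linalg.solve(
                            K, self._G[active] - lam * signs
                        )
                    return IndexCoefficients(beta, method=self.method,
                                             lam=lam, alpha=self.alpha)
            raise ValueError(
                f"lambda={lam} below the end of the computed path "
                f"({self.lambdas[-1]})"
            )
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefficients[idx]


@dataclass
class SpectralDecomposition:
    """SVD ``X = U D V'`` of a column-centered trait matrix."""

    U: np.ndarray
    D: np.ndarray  # singular values, descending
    V: np.ndarray
    n: int

    @property
    def rank(self) -> int:
        if self.D.size == 0:
            return 0
        return int(np.sum(self.D > 1e-10 * self.D[0]))

    def scores(self, q: int | None = None) -> np.ndarray:
        """PC scores ``W = U D`` (optionally only the first q columns)."""
        W = self.U * self.D[None, :]
        return W if q is None else W[:, :q]


# ---------------------------------------------------------------------------
# Covariance and index evaluation
# ---------------------------------------------------------------------------


def phenotypic_covariance(X: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance ``X'X / (n-1)`` of a centered matrix."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to estimate a covariance")
    means = X.mean(axis=0)
    if np.max(np.abs(means)) > 1e-8:
        raise ValueError(
            "columns are not centered "
            f"(max |mean| = {np.max(np.abs(means)):.3e}); center first"
        )
    P = X.T @ X / (n - 1)
    return 0.5 * (P + P.T)


def compute_index(
    X_new: np.ndarray,
    coef: IndexCoefficients,
    band_labels: Sequence | None = None,
) -> np.ndarray:
    """Apply index weights to new observations: ``I = X beta``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != coef.beta.shape[0]:
        raise ValueError(
            f"column count {X_new.shape[1]} does not match "
            f"{coef.beta.shape[0]} coefficients"
        )
    if band_labels is not None:
        mism = [
            (a, b) for a, b in zip(band_labels, coef.band_labels) if a != b
        ]
        if mism:
            raise ValueError(f"band label mismatch: {mism[:5]}")
    return X_new @ coef.beta


# ---------------------------------------------------------------------------
# Standard and L2 indices
# ---------------------------------------------------------------------------


def standard_si(cov: CovariancePair) -> IndexCoefficients:
    """Solve ``P_x beta = G_xy`` (the classical Smith-Hazel weights)."""
    cond = np.linalg.cond(cov.P)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"P_x is singular or ill-conditioned (cond={cond:.3e}); "
            "use a regularized index (L2/L1/PC) instead"
        )
    beta = np.linalg.solve(cov.P, cov.G)
    resid = np.linalg.norm(cov.P @ beta - cov.G)
    if resid > 1e-8 * max(np.linalg.norm(cov.G), 1e-300):
        raise np.linalg.LinAlgError(
            f"linear solve residual too large ({resid:.3e})"
        )
    return IndexCoefficients(beta, method="standard", lam=0.0, alpha=0.0,
                             band_labels=list(cov.band_labels))


def l2_psi(cov: CovariancePair, lam: float) -> IndexCoefficients:
    """Ridge-type index ``beta = (P_x + lambda I)^{-1} G_xy``."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    A = cov.P + lam * np.eye(cov.p)
    beta = np.linalg.solve(A, cov.G)
    return IndexCoefficients(beta, method="L2", lam=float(lam), alpha=0.0,
                             band_labels=list(cov.band_labels))


# ---------------------------------------------------------------------------
# Elastic net by coordinate descent (covariance updates)
# ---------------------------------------------------------------------------


def default_lambda_grid(cov: CovariancePair, alpha: float,
                        n_points: int = 100, eps: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from ``lambda_max = max|G| / max(alpha, 1e-3)`` down
    to ``eps * lambda_max``."""
    lam_max = float(np.max(np.abs(cov.G))) / max(alpha, 1e-3)
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, eps * lam_max, n_points)


def _soft(z: float, t: float) -> float:
    """Soft-thresholding operator sign(z) * max(|z| - t, 0)."""
    mag = abs(z) - t
    if mag <= 0.0:
        return 0.0
    return mag if z >= 0.0 else -mag


def kkt_violation(cov: CovariancePair, beta: np.ndarray,
                  lam: float, alpha: float) -> float:
    """Maximum KKT violation of the elastic-net objective at ``beta``.

    For active j: ``G_j - (P beta)_j - lam*(1-alpha)*beta_j`` must equal
    ``lam*alpha*sign(beta_j)``; for inactive j its magnitude must not
    exceed ``lam*alpha``.
    """
    beta = np.asarray(beta, dtype=float)
    grad = cov.G - cov.P @ beta - lam * (1.0 - alpha) * beta
    active = beta != 0.0
    v_active = (
        np.max(np.abs(grad[active] - lam * alpha * np.sign(beta[active])))
        if active.any() else 0.0
    )
    v_inactive = (
        max(np.max(np.abs(grad[~active])) - lam * alpha, 0.0)
        if (~active).any() else 0.0
    )
    return float(max(v_active, v_inactive))


def elastic_net_psi(
    cov: CovariancePair,
    lambda_grid: Sequence[float] | None = None,
    alpha: float = 1.0,
    tol: float = CD_TOL,
    max_sweeps: int = CD_MAX_SWEEPS,
) -> RegularizationPath:
    """Cyclical coordinate descent on the covariance-form objective.

    Updates ``beta_j <- S(G_j - sum_{k!=j} P_jk beta_k, lam*alpha) /
    (P_jj + lam*(1-alpha))`` in band order, warm-starting each grid point
    from the previous solution.  Convergence: max absolute coefficient
    change below ``tol`` within ``max_sweeps`` sweeps; failures are flagged
    on the affected solutions, never silent.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(cov, alpha)
    lams = np.asarray(list(lambda_grid), dtype=float)
    if lams.size > 1 and not np.all(np.diff(lams) < 0):
        raise ValueError("lambda grid must be strictly decreasing")
    P, G, p = cov.P, cov.G, cov.p
    diag = np.diag(P)
    beta = np.zeros(p)
    Pb = np.zeros(p)  # P @ beta, maintained incrementally
    coefs = []
    all_ok = True
    for lam in lams:
        ok = False
        for _ in range(max_sweeps):
            delta_max = 0.0
            for j in range(p):
                z = G[j] - Pb[j] + diag[j] * beta[j]
                bj = _soft(z, lam * alpha) / (diag[j] + lam * (1.0 - alpha))
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    Pb += P[:, j] * d
                    delta_max = max(delta_max, abs(d))
            if delta_max < tol:
                ok = True
                break
        if not ok:
            all_ok = False
            logger.warning(
                "coordinate descent did not converge at lambda=%.4g", lam
            )
        coefs.append(IndexCoefficients(
            beta.copy(), method="EN" if 0 < alpha < 1 else
            ("L1" if alpha == 1.0 else "L2"),
            lam=float(lam), alpha=float(alpha),
            band_labels=list(cov.band_labels), converged=ok,
        ))
    return RegularizationPath(
        method=coefs[0].method if coefs else "EN", alpha=float(alpha),
        lambdas=lams, coefficients=coefs, converged=all_ok,
    )


# ---------------------------------------------------------------------------
# LARS (lasso-modified) homotopy in lambda, covariance form
# ---------------------------------------------------------------------------


def lars_psi(cov: CovariancePair, lambda_min: float = 0.0,
             max_steps: int | None = None) -> RegularizationPath:
    """Full L1 solution path by homotopy on the covariance inputs.

    Within a segment with active set A and signs s, the solution is
    ``beta_A(lam) = P_AA^{-1} (G_A - lam * s_A)`` and the inactive
    "correlations" ``c_j(lam) = G_j - P_jA beta_A(lam)`` are affine in
    lambda; knots occur where an inactive |c_j| reaches lambda (entry) or an
    active coefficient crosses zero (drop — the lasso modification).  Ties
    at events are broken by the lowest band index (logged).

    Returns a path whose ``lambdas`` are the knots (starting at
    ``lambda_max = max|G|``) and whose :meth:`RegularizationPath.at`
    evaluates the exact solution at any lambda on the path.
    """
    P, G, p = cov.P, cov.G, cov.p
    if np.any(np.diag(P) <= 0):
        raise ValueError("P_x must have a strictly positive diagonal")
    if max_steps is None:
        max_steps = 8 * p + 10
    lam = float(np.max(np.abs(G))) if p else 0.0
    knots = [lam]
    coefs = [IndexCoefficients(np.zeros(p), method="L1", lam=lam, alpha=1.0,
                               band_labels=list(cov.band_labels))]
    segments = []
    if lam == 0.0:  # G == 0: the path is the single zero solution
        return RegularizationPath(method="L1", alpha=1.0,
                                  lambdas=np.array(knots), coefficients=coefs,
                                  segments=segments, _P=P, _G=G)
    c = G.copy()
    atmax = np.flatnonzero(np.abs(np.abs(c) - lam) <= 1e-12 * max(lam, 1.0))
    if atmax.size > 1:
        logger.info("tie at path start; entering lowest band index %d",
                    int(atmax[0]))
    active: list[int] = [int(atmax[0])]
    signs: dict[int, float] = {int(atmax[0]): float(np.sign(c[atmax[0]]))}
    eps = 1e-12

    for _ in range(max_steps):
        A = np.array(active, dtype=int)
        sA = np.array([signs[j] for j in active])
        K = P[np.ix_(A, A)]
        try:
            u = np.linalg.solve(K, G[A])
            v = np.linalg.solve(K, sA)
        except np.linalg.LinAlgError:
            logger.warning("singular active-set system; stopping path at "
                           "lambda=%.4g", lam)
            break
        # beta_A(t) = u - t v for t in (next_knot, lam]
        inact = np.array([j for j in range(p) if j not in signs], dtype=int)
        cand_lam = -np.inf
        cand_kind = None  # ("enter", j, sign) or ("drop", j)
        if inact.size:
            a = G[inact] - P[np.ix_(inact, A)] @ u
            b = P[np.ix_(inact, A)] @ v
            # entry at |a_j + t b_j| = t
            for sign_target in (+1.0, -1.0):
                denom = sign_target - b
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.where(np.abs(denom) > eps, a / denom, -np.inf)
                valid = (t > eps) & (t < lam - eps)
                if valid.any():
                    tv = np.where(valid, t, -np.inf)
                    jmax = int(inact[np.argmax(tv)])
                    tmax = float(np.max(tv))
                    if tmax > cand_lam + eps:
                        cand_lam, cand_kind = tmax, ("enter", jmax, sign_target)
                    elif abs(tmax - cand_lam) <= eps and cand_kind and \
                            cand_kind[0] == "enter" and jmax < cand_kind[1]:
                        logger.info("entry tie at lambda=%.6g; choosing band "
                                    "%d", tmax, jmax)
                        cand_kind = ("enter", jmax, sign_target)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_drop = np.where(np.abs(v) > eps, u / v, -np.inf)
        valid = (t_drop > eps) & (t_drop < lam - eps)
        if valid.any():
            tv = np.where(valid, t_drop, -np.inf)
            imax = int(np.argmax(tv))
            tmax = float(np.max(tv))
            if tmax > cand_lam + eps:
                cand_lam, cand_kind = tmax, ("drop", int(A[imax]))
            elif abs(tmax - cand_lam) <= eps and cand_kind is not None:
                jd = int(A[imax])
                if cand_kind[0] != "drop" or jd < cand_kind[1]:
                    logger.info("drop tie at lambda=%.6g; dropping band %d",
                                tmax, jd)
                    cand_lam, cand_kind = tmax, ("drop", jd)

        next_lam = max(cand_lam, lambda_min) if cand_kind else lambda_min
        next_lam = max(next_lam, 0.0)
        segments.append((lam, next_lam, A.copy(), sA.copy()))
        beta = np.zeros(p)
        beta[A] = u - next_lam * v
        knots.append(next_lam)
        coefs.append(IndexCoefficients(
            beta, method="L1", lam=float(next_lam), alpha=1.0,
            band_labels=list(cov.band_labels),
        ))
        lam = next_lam
        if cand_kind is None or cand_lam <= lambda_min:
            break
        if cand_kind[0] == "enter":
            _, j, sign_target = cand_kind
            active.append(j)
            signs[j] = sign_target
        else:
            _, j = cand_kind
            active.remove(j)
            del signs[j]
            if not active:
                # path restarts from zero (can happen with negative
                # covariances); re-enter the most correlated band
                c_now = G - P @ beta
                jn = int(np.argmax(np.abs(c_now)))
                active.append(jn)
                signs[jn] = float(np.sign(c_now[jn]))
    else:
        logger.warning("LARS reached max_steps=%d before lambda_min", max_steps)

    return RegularizationPath(
        method="L1", alpha=1.0, lambdas=np.array(knots), coefficients=coefs,
        segments=segments, _P=P, _G=G,
    )


# ---------------------------------------------------------------------------
# Reduced-rank (principal-component) index
# ---------------------------------------------------------------------------


def spectral_decomposition(X: np.ndarray, center: bool = True) -> SpectralDecomposition:
    """Thin SVD of the (column-centered) trait matrix."""
    X = np.asarray(X, dtype=float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, D, Vt = np.linalg.svd(X, full_matrices=False)
    return SpectralDecomposition(U=U, D=D, V=Vt.T, n=X.shape[0])


def pc_si(decomp: SpectralDecomposition, G_wy: np.ndarray, q: int) -> IndexCoefficients:
    """Reduced-rank index from the top-q principal components.

    The PC phenotypic covariance is the method-of-moments estimate
    ``D_q^2 / (n-1)``, so the PC coefficients are
    ``gamma_q = (n-1) D_q^{-2} G_wy`` and the trait-space weights are
    ``beta = V_q gamma_q``.

    Parameters
    ----------
    decomp
        SVD of the centered trait matrix.
    G_wy : (>= q,) array
        Genetic covariances between the leading PC scores and the target
        (either estimated directly on the scores, or rotated band-level
        estimates ``V' G_xy``).
    q
        Number of components to use (1 <= q <= rank).
    """
    rank = decomp.rank
    if not (1 <= q <= rank):
        raise ValueError(f"q={q} outside [1, rank={rank}]")
    G_wy = np.asarray(G_wy, dtype=float).ravel()
    if G_wy.shape[0] < q:
        raise ValueError(f"G_wy has {G_wy.shape[0]} entries; need >= q={q}")
    d2 = decomp.D[:q] ** 2
    gamma = (decomp.n - 1) * G_wy[:q] / d2
    beta = decomp.V[:, :q] @ gamma
    return IndexCoefficients(beta, method="PC", lam=0.0, alpha=0.0, q=int(q))
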