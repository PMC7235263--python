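"""Random-effects models for replicated field trials.

This module provides the mixed-model machinery used throughout the package:

* REML estimation of variance components for models in which every design
  factor (genotype, trial, replicate-within-trial, sub-block, time-point)
  enters as an iid random effect,
* BLUP-based pre-adjustment of phenotypes (removing the mean and the
  nuisance-factor BLUPs while keeping the genotype signal),
* an IQR outlier fence and unit-variance standardization,
* plot-basis heritability from the one-factor genotype model, and
* genetic covariances via the sum-of-traits identity
  ``G(y, x) = (var_g(y + x) - var_g(y) - var_g(x)) / 2``.

Numerics
--------
The restricted likelihood is maximized directly over the log variance
ratios ``log(sigma2_e / sigma2_k)`` using the profiled criterion computed
from Henderson's mixed-model equations; the residual variance is profiled
out in closed form.  Coordinate-wise bounded Brent searches are swept until
the relative change of the restricted log-likelihood falls below
``REML_RTOL`` (cap ``REML_MAX_SWEEPS`` sweeps); failure to converge is
flagged on the result, never silent.  Variance-ratio bounds place each
component variance in ``[~1e-15, ~1e5] * sigma2_e``; estimates below
``VARIANCE_FLOOR`` are reported as exactly 0.

The one-factor model (used for heritabilities and for the sum-of-traits
genetic covariances, where hundreds of fits share one genotype grouping) has
a dedicated profiled fast path that is vectorized across response columns:
a log-ratio grid scan followed by golden-section refinement.  Both paths
optimize the same criterion and agree to well below the tolerances stated on
the public operations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cholesky as _sp_cholesky
from scipy.linalg import solve_triangular as _sp_solve_triangular
from scipy.optimize import minimize_scalar

__all__ = [
    "PhenotypeTable",
    "VarianceComponents",
    "RandomEffectsFit",
    "AdjustedPhenotypes",
    "GeneticCovariances",
    "DEFAULT_NUISANCE_FACTORS",
    "fit_random_effects_model",
    "preadjust",
    "filter_and_standardize",
    "heritability",
    "genetic_covariance",
    "genetic_covariances_panel",
]

logger = logging.getLogger(__name__)

#: Convergence / numeric contract for the REML fitter.
REML_RTOL = 1e-8
REML_MAX_SWEEPS = 200
VARIANCE_FLOOR = 1e-10
#: Bounds on log(lambda_k), lambda_k = sigma2_e / sigma2_k.  The lower bound
#: keeps the MME matrix factorizable without jitter even when a component
#: absorbs (nearly) all variance.
_LOG_LAMBDA_LO = -20.0
_LOG_LAMBDA_HI = 35.0
_LOG2PI = math.log(2.0 * math.pi)

#: Nuisance factors of the pre-adjustment model; tuples denote nesting
#: (replicates are nested in trials, sub-blocks in trial x replicate).
DEFAULT_NUISANCE_FACTORS: tuple = (
    "trial",
    ("trial", "rep"),
    ("trial", "rep", "subblock"),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class PhenotypeTable:
    """Long-format plot records with design factors and one trait value.

    Parameters
    ----------
    data
        DataFrame with at least ``genotype`` and ``trial`` columns plus the
        value column.  ``rep``, ``subblock``, ``timepoint`` and ``env`` are
        used when present; replicate and sub-block labels are interpreted as
        nested within their parents.
    value_col
        Name of the trait-value column (default ``"value"``).
    """

    DESIGN_COLUMNS = ("genotype", "trial", "rep", "subblock", "timepoint", "env")

    def __init__(self, data: pd.DataFrame, value_col: str = "value"):
        if value_col not in data.columns:
            raise ValueError(f"value column {value_col!r} not in table")
        for col in ("genotype", "trial"):
            if col not in data.columns:
                raise ValueError(f"required column {col!r} not in table")
            if data[col].isna().any():
                raise ValueError(f"column {col!r} contains missing values")
        self.data = data.reset_index(drop=True)
        self.value_col = value_col

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data[self.value_col].to_numpy(dtype=float)

    def design_key(self) -> pd.DataFrame:
        """Plot-identifying design columns present in the table."""
        cols = [c for c in self.DESIGN_COLUMNS if c in self.data.columns]
        return self.data[cols]

    def with_values(self, values: np.ndarray, value_col: str | None = None) -> "PhenotypeTable":
        out = self.data.copy()
        col = value_col or self.value_col
        out[col] = np.asarray(values, dtype=float)
        return PhenotypeTable(out, value_col=col)


@dataclass
class VarianceComponents:
    """REML variance-component estimates (squared trait units)."""

    components: dict  # factor name -> variance (>= 0)
    residual: float
    converged: bool
    loglik: float
    n_sweeps: int = 0

    def total(self) -> float:
        return float(sum(self.components.values()) + self.residual)


@dataclass
class RandomEffectsFit:
    """Variance components, per-level BLUPs and the overall mean."""

    mean: float
    varcomp: VarianceComponents
    blups: dict  # factor name -> pd.Series indexed by level labels
    factor_names: tuple
    # fitted log variance ratios (internal; warm-starts related fits)
    _log_ratios: np.ndarray | None = None


@dataclass
class AdjustedPhenotypes:
    """Pre-adjusted records ``y* = y - mu - BLUP(nuisance)``.

    ``retained`` marks records inside the IQR fence; ``scale`` is the sample
    SD the retained values were divided by (1.0 before standardization).
    """

    table: pd.DataFrame  # design columns of the source records
    values: np.ndarray  # y*, same order as ``table``
    retained: np.ndarray  # bool mask
    scale: float = 1.0
    fit: RandomEffectsFit | None = None

    def retained_values(self) -> np.ndarray:
        return self.values[self.retained]

    def to_table(self, value_col: str = "value") -> PhenotypeTable:
        """Retained records as a PhenotypeTable (for downstream fits)."""
        out = self.table.loc[self.retained].copy()
        out[value_col] = self.values[self.retained]
        return PhenotypeTable(out.reset_index(drop=True), value_col=value_col)


@dataclass
class GeneticCovariances:
    """Sum-of-traits genetic covariances between a panel and the target."""

    g_xy: np.ndarray  # length p
    sigma2_gy: float
    sigma2_gx: np.ndarray  # length p, genetic variance per measured trait
    band_labels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Factor handling
# ---------------------------------------------------------------------------


def _factor_name(spec) -> str:
    return spec if isinstance(spec, str) else ":".join(spec)


def _factor_codes(df: pd.DataFrame, spec) -> tuple[np.ndarray, pd.Index]:
    """Integer level codes for a (possibly nested) factor spec."""
    cols = [spec] if isinstance(spec, str) else list(spec)
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"factor column {c!r} not in table")
    if len(cols) == 1:
        codes, uniques = pd.factorize(df[cols[0]], sort=True)
        return codes.astype(np.intp), pd.Index(uniques)
    mi = pd.MultiIndex.from_frame(df[cols])
    codes, uniques = pd.factorize(mi, sort=True)
    return codes.astype(np.intp), pd.Index(uniques)


# ---------------------------------------------------------------------------
# REML core (general, MME-based, profiled residual variance)
# ---------------------------------------------------------------------------


class _MMEProblem:
    """Precomputed sufficient statistics for the profiled REML criterion."""

    def __init__(self, y: np.ndarray, code_list: Sequence[np.ndarray],
                 q_list: Sequence[int], intercept: bool):
        n = y.shape[0]
        cols = []
        if intercept:
            cols.append(sparse.csr_matrix(np.ones((n, 1))))
        for codes, q in zip(code_list, q_list):
            Z = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q)
            )
            cols.append(Z)
        W = sparse.hstack(cols, format="csr")
        self.n = n
        self.f = 1 if intercept else 0
        self.q_list = list(q_list)
        self.WtW = np.asarray((W.T @ W).todense(), dtype=float)
        self.Wty = np.asarray(W.T @ y, dtype=float).ravel()
        self.yty = float(y @ y)
        # slices of the random blocks in the MME
        self.slices = []
        off = self.f
        for q in q_list:
            self.slices.append(slice(off, off + q))
            off += q
        self.dim = off
        self._buf = np.empty_like(self.WtW)
        self._diag_idx = np.diag_indices(self.dim)

    def _factor(self, loglam: np.ndarray) -> np.ndarray:
        """Cholesky factor of the scaled MME matrix (buffer reused)."""
        C = self._buf
        np.copyto(C, self.WtW)
        for sl, ll in zip(self.slices, loglam):
            C[self._diag_idx[0][sl], self._diag_idx[1][sl]] += math.exp(ll)
        try:
            return _sp_cholesky(C, lower=True, overwrite_a=True,
                                check_finite=False)
        except np.linalg.LinAlgError:
            np.copyto(C, self.WtW)
            jitter = 1e-8 * (np.trace(C) / self.dim + 1.0)
            for sl, ll in zip(self.slices, loglam):
                C[self._diag_idx[0][sl], self._diag_idx[1][sl]] += math.exp(ll)
            C[self._diag_idx] += jitter
            return _sp_cholesky(C, lower=True, overwrite_a=True,
                                check_finite=False)

    def criterion(self, loglam: np.ndarray) -> float:
        """-2 log restricted likelihood at profiled sigma2_e (up to a constant)."""
        L = self._factor(loglam)
        z = _sp_solve_triangular(L, self.Wty, lower=True, check_finite=False)
        quad = self.yty - float(z @ z)
        quad = max(quad, 1e-300)
        nf = self.n - self.f
        sigma2e = quad / nf
        logdetC = 2.0 * float(np.log(np.diag(L)).sum())
        pen = sum(q * ll for q, ll in zip(self.q_list, loglam))
        return nf * math.log(sigma2e) - pen + logdetC

    def solve(self, loglam: np.ndarray) -> tuple[np.ndarray, float]:
        """MME solution theta and profiled sigma2_e at the given ratios."""
        L = self._factor(loglam)
        z = _sp_solve_triangular(L, self.Wty, lower=True, check_finite=False)
        theta = _sp_solve_triangular(L.T, z, lower=False, check_finite=False)
        quad = max(self.yty - float(z @ z), 0.0)
        sigma2e = quad / (self.n - self.f)
        return theta, sigma2e

    def loglik(self, loglam: np.ndarray) -> float:
        nf = self.n - self.f
        return -0.5 * (self.criterion(loglam) + nf * (1.0 + _LOG2PI))


def _optimize_ratios(prob: _MMEProblem,
                     start: np.ndarray | None = None
                     ) -> tuple[np.ndarray, bool, int]:
    """Coordinate-wise Brent sweeps over the log variance ratios."""
    k = len(prob.q_list)
    loglam = np.zeros(k) if start is None else np.asarray(start, float).copy()
    crit = prob.criterion(loglam)
    converged = False
    sweeps = 0
    for sweeps in range(1, REML_MAX_SWEEPS + 1):
        for i in range(k):
            def f1(t, i=i):
                trial = loglam.copy()
                trial[i] = t
                return prob.criterion(trial)

            res = minimize_scalar(
                f1, bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
                method="bounded", options={"xatol": 1e-7},
            )
            best_t, best_f = float(res.x), float(res.fun)
            # a boundary can beat the interior optimum Brent settles on
            if best_t > _LOG_LAMBDA_HI - 1.0 or best_t < _LOG_LAMBDA_LO + 1.0:
                t_edge = (_LOG_LAMBDA_HI if best_t > 0 else _LOG_LAMBDA_LO)
                f_edge = f1(t_edge)
                if f_edge <= best_f + 1e-12:
                    best_t, best_f = t_edge, f_edge
            loglam[i] = best_t
        new_crit = prob.criterion(loglam)
        if abs(crit - new_crit) <= REML_RTOL * max(1.0, abs(new_crit)):
            crit = new_crit
            converged = True
            break
        crit = new_crit
    return loglam, converged, sweeps


def fit_random_effects_model(
    table: PhenotypeTable,
    factors: Sequence | None = None,
    include_intercept: bool = True,
    start_ratios: np.ndarray | None = None,
) -> RandomEffectsFit:
    """REML fit of ``y = mu + sum_k u_k + e`` with iid random factors.

    Parameters
    ----------
    table
        Phenotype records.
    factors
        Ordered factor specs; each entry is a column name or a tuple of
        column names (nesting).  Defaults to genotype plus the standard
        nuisance factors (trial, rep-in-trial, sub-block-in-trial-rep),
        restricted to columns present in the table.
    include_intercept
        Fit an overall mean (set False for pre-centered data, e.g. the
        heritability model).

    Returns
    -------
    RandomEffectsFit
        Variance components (boundary estimates reported as exactly 0),
        per-level BLUPs, the estimated mean, restricted log-likelihood and a
        convergence flag.
    """
    if factors is None:
        factors = ["genotype"] + [
            f for f in DEFAULT_NUISANCE_FACTORS
            if all(c in table.data.columns for c in ((f,) if isinstance(f, str) else f))
        ]
    if len(factors) == 0:
        raise ValueError("at least one random factor is required")
    y = table.values
    names, code_list, index_list, q_list = [], [], [], []
    for spec in factors:
        codes, uniques = _factor_codes(table.data, spec)
        if len(uniques) < 2:
            raise ValueError(
                f"factor {_factor_name(spec)!r} has a single level; "
                "cannot estimate its variance"
            )
        names.append(_factor_name(spec))
        code_list.append(codes)
        index_list.append(uniques)
        q_list.append(len(uniques))
    n = len(y)
    f = 1 if include_intercept else 0
    if n - f < 1:
        raise ValueError("no residual degrees of freedom")

    # canonical record order: identical sufficient statistics (bitwise)
    # regardless of the input row order
    order = np.lexsort((y, *reversed(code_list)))
    y = y[order]
    code_list = [c[order] for c in code_list]

    prob = _MMEProblem(y, code_list, q_list, include_intercept)
    loglam, converged, sweeps = _optimize_ratios(prob, start=start_ratios)
    if not converged:
        logger.warning("REML did not reach rtol=%.1e in %d sweeps", REML_RTOL, sweeps)
    theta, sigma2e = prob.solve(loglam)
    loglik = prob.loglik(loglam)

    components = {}
    blups = {}
    mean = float(theta[0]) if include_intercept else 0.0
    for name, sl, ll, idx in zip(names, prob.slices, loglam, index_list):
        var = sigma2e / math.exp(ll) if sigma2e > 0 else 0.0
        if var < VARIANCE_FLOOR:
            var = 0.0
        components[name] = var
        u = theta[sl]
        if var == 0.0:
            u = np.zeros_like(u)
        blups[name] = pd.Series(u, index=idx, name=name)
    varcomp = VarianceComponents(
        components=components,
        residual=float(sigma2e),
        converged=converged,
        loglik=float(loglik),
        n_sweeps=sweeps,
    )
    return RandomEffectsFit(mean=mean, varcomp=varcomp, blups=blups,
                            factor_names=tuple(names), _log_ratios=loglam)


# ---------------------------------------------------------------------------
# One-factor fast path (vectorized across response columns)
# ---------------------------------------------------------------------------


def _one_factor_reml(Y: np.ndarray, codes: np.ndarray, n_levels: int,
                     n_grid: int = 141, n_refine: int = 90):
    """Profiled REML for ``y = g_j + e`` (no intercept), vectorized.

    Parameters
    ----------
    Y : (n,) or (n, m) array
        Response column(s); all columns share the grouping.
    codes : (n,) int array
        Genotype level codes in ``range(n_levels)``.

    Returns
    -------
    sigma2_g, sigma2_e, loglik : (m,) arrays (scalars squeezed by callers).

    Notes
    -----
    A coarse scan of the criterion over a log variance-ratio grid brackets
    the optimum, then bisection on the *analytic derivative* of the
    criterion refines it.  The derivative is a plain sum of rational terms,
    so the root is located to ~1e-13 relative precision — far inside the
    flat plateau where criterion-value comparisons become noise — which
    makes independent fits of the same trait agree to well below 1e-10 and
    power-of-two rescalings of the response scale the estimates exactly.
    """
    Y = np.atleast_2d(Y.T).T  # (n, m)
    n, m = Y.shape
    nj = np.bincount(codes, minlength=n_levels).astype(float)  # (J,)
    M = sparse.csr_matrix(
        (np.ones(n), (codes, np.arange(n))), shape=(n_levels, n)
    )
    S = np.asarray(M @ Y)  # (J, m) group sums
    S2 = S * S
    SS = np.einsum("ij,ij->j", Y, Y)  # (m,)

    def crit(t: np.ndarray) -> np.ndarray:
        """(T, m) criterion for log-ratio grid t (phi = exp(t))."""
        phi = np.exp(t)[:, None]  # (T, 1)
        denom = 1.0 + phi * nj[None, :]  # (T, J)
        A = np.log(denom).sum(axis=1)  # (T,)
        w = phi / denom  # (T, J)
        quad = SS[None, :] - w @ S2  # (T, m)
        quad = np.maximum(quad, 1e-300)
        return n * np.log(quad / n) + A[:, None]

    def dcrit(t_cols: np.ndarray) -> np.ndarray:
        """Per-column derivative d(criterion)/dt at one t per column."""
        phi = np.exp(t_cols)  # (m,)
        denom = 1.0 + phi[None, :] * nj[:, None]  # (J, m)
        quad = SS - np.einsum("jm,jm->m", phi[None, :] / denom, S2)
        quad = np.maximum(quad, 1e-300)
        dquad = -np.einsum("jm,jm->m", 1.0 / (denom * denom), S2)
        dA = (nj[:, None] / denom).sum(axis=0)
        return phi * (n * dquad / quad + dA)

    t_lo_bound, t_hi_bound = -30.0, 15.0
    t_grid = np.linspace(t_lo_bound, t_hi_bound, n_grid)
    values = crit(t_grid)  # (T, m)
    best = np.argmin(values, axis=0)  # (m,)
    step = t_grid[1] - t_grid[0]
    lo = np.maximum(t_grid[best] - step, t_lo_bound)
    hi = np.minimum(t_grid[best] + step, t_hi_bound)
    g_lo = dcrit(lo)
    g_hi = dcrit(hi)
    # derivative positive already at the left edge: minimum at the
    # sigma2_g -> 0 boundary
    at_zero = (lo <= t_lo_bound + 1e-12) & (g_lo > 0)
    for _ in range(n_refine):
        mid = 0.5 * (lo + hi)
        g_mid = dcrit(mid)
        left = g_mid < 0
        lo = np.where(left, mid, lo)
        hi = np.where(left, hi, mid)
    t_opt = 0.5 * (lo + hi)
    phi = np.exp(t_opt)
    phi = np.where(at_zero, 0.0, phi)

    denom = 1.0 + phi[None, :] * nj[:, None]
    w = phi[None, :] / denom
    quad = np.maximum(SS - np.einsum("jm,jm->m", w, S2), 0.0)
    sigma2e = quad / n
    sigma2g = phi * sigma2e
    sigma2g = np.where(sigma2g < VARIANCE_FLOOR, 0.0, sigma2g)
    f_opt = np.where(
        at_zero,
        n * np.log(np.maximum(SS, 1e-300) / n),
        n * np.log(np.maximum(quad, 1e-300) / n)
        + np.log(denom).sum(axis=0),
    )
    loglik = -0.5 * (f_opt + n * (1.0 + _LOG2PI))
    return sigma2g, sigma2e, loglik


# ---------------------------------------------------------------------------
# Pre-adjustment, filtering, standardization
# ---------------------------------------------------------------------------


def preadjust(
    table: PhenotypeTable,
    nuisance_factors: Sequence = DEFAULT_NUISANCE_FACTORS,
    include_timepoint: bool = False,
    start_ratios: np.ndarray | None = None,
) -> AdjustedPhenotypes:
    """Remove the mean and nuisance BLUPs: ``y* = y - mu - t - r - b [- tp]``.

    The genotype BLUP is *not* subtracted; ``y*`` keeps the genotype signal
    plus residual.  With ``include_timepoint=True`` a time-point main effect
    is added to the nuisance model (used for reflectance panels measured at
    several flights).
    """
    nuisance = list(nuisance_factors)
    if include_timepoint:
        nuisance = nuisance + ["timepoint"]
    factors = ["genotype"] + nuisance
    fit = fit_random_effects_model(table, factors=factors,
                                   include_intercept=True,
                                   start_ratios=start_ratios)
    y_star = table.values - fit.mean
    for spec in nuisance:
        name = _factor_name(spec)
        codes, uniques = _factor_codes(table.data, spec)
        blup = fit.blups[name].to_numpy()
        y_star = y_star - blup[codes]
    return AdjustedPhenotypes(
        table=table.design_key().copy(),
        values=y_star,
        retained=np.ones(len(y_star), dtype=bool),
        scale=1.0,
        fit=fit,
    )


def filter_and_standardize(
    adjusted: AdjustedPhenotypes,
    fence_multiplier: float = 3.0,
) -> AdjustedPhenotypes:
    """Apply the quartile +/- ``fence_multiplier * IQR`` fence, then scale.

    Quartiles use linear interpolation (NumPy's default, "type 7").  Records
    outside ``[Q1 - m*IQR, Q3 + m*IQR]`` are dropped; the retained values are
    divided by their sample standard deviation so the retained sample has
    unit variance.
    """
    values = adjusted.values
    base = adjusted.retained
    v = values[base]
    if np.isfinite(fence_multiplier):
        q1, q3 = np.quantile(v, [0.25, 0.75])
        iqr = q3 - q1
        lo = q1 - fence_multiplier * iqr
        hi = q3 + fence_multiplier * iqr
        keep = (values >= lo) & (values <= hi) & base
    else:
        keep = base.copy()
    if keep.sum() < 4:
        raise ValueError("fewer than 4 records retained after outlier filtering")
    sd = float(np.std(values[keep], ddof=1))
    if sd <= 0.0:
        raise ValueError("zero variance after filtering; cannot standardize")
    return AdjustedPhenotypes(
        table=adjusted.table,
        values=values / sd,
        retained=keep,
        scale=sd,
        fit=adjusted.fit,
    )


# ---------------------------------------------------------------------------
# Heritability and genetic covariances
# ---------------------------------------------------------------------------


def _genotype_codes(table: PhenotypeTable) -> tuple[np.ndarray, int]:
    codes, uniques = _factor_codes(table.data, "genotype")
    if len(uniques) < 2:
        raise ValueError("factor 'genotype' has a single level")
    return codes, len(uniques)


def genetic_variance(table: PhenotypeTable) -> tuple[float, float]:
    """(sigma2_g, sigma2_e) from the one-factor genotype model ``y = g + e``."""
    codes, q = _genotype_codes(table)
    sg, se, _ = _one_factor_reml(table.values, codes, q)
    return float(sg[0]), float(se[0])


def heritability(table: PhenotypeTable) -> float:
    """Plot-basis heritability ``h2 = var_g / (var_g + var_e)`` in [0, 1].

    The model is the no-intercept one-factor genotype model fitted to
    pre-adjusted (null-mean) phenotypes.
    """
    sg, se = genetic_variance(table)
    total = sg + se
    if total <= 0.0:
        raise ValueError("both variance components are zero; h2 undefined")
    return float(min(max(sg / total, 0.0), 1.0))


def _check_matched(y: PhenotypeTable, x: PhenotypeTable) -> None:
    ky = y.design_key()
    kx = x.design_key()
    common = [c for c in ky.columns if c in kx.columns]
    if len(y) != len(x):
        raise ValueError(
            f"record count mismatch: {len(y)} target vs {len(x)} measured records"
        )
    a = ky[common].reset_index(drop=True)
    b = kx[common].reset_index(drop=True)
    neq = (a != b).any(axis=1)
    if neq.any():
        i = int(np.flatnonzero(neq.to_numpy())[0])
        raise ValueError(
            "record keys mismatch at row "
            f"{i}: {tuple(a.iloc[i])} != {tuple(b.iloc[i])}"
        )


def genetic_covariance(y: PhenotypeTable, x: PhenotypeTable) -> float:
    """Sum-of-traits genetic covariance between two matched trait tables.

    Fits the one-factor genotype model to ``y``, ``x`` and ``y + x`` and
    returns ``(var_g(y+x) - var_g(y) - var_g(x)) / 2``.  Symmetric in its
    arguments; may be negative when components hit the zero boundary.
    """
    _check_matched(y, x)
    codes, q = _genotype_codes(y)
    Y = np.column_stack([y.values, x.values, y.values + x.values])
    sg, _, _ = _one_factor_reml(Y, codes, q)
    return float(0.5 * (sg[2] - sg[0] - sg[1]))


def genetic_covariances_panel(
    y: PhenotypeTable,
    X: np.ndarray,
    band_labels: Sequence | None = None,
) -> GeneticCovariances:
    """Genetic covariances between the target and each column of a panel.

    Parameters
    ----------
    y
        Target-trait records (supplies the genotype grouping and plot order).
    X : (n, p) array
        Measured-trait panel aligned row-by-row with ``y``.
    band_labels
        Optional labels attached to the result.

    Notes
    -----
    All ``2p + 1`` one-factor fits (each band, each band + target, target)
    run through the vectorized profiled-REML path, so the result does not
    depend on band order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError(
            f"panel shape {X.shape} does not match {len(y)} target records"
        )
    codes, q = _genotype_codes(y)
    yv = y.values
    p = X.shape[1]
    big = np.column_stack([yv[:, None], X, X + yv[:, None]])
    sg, _, _ = _one_factor_reml(big, codes, q)
    bad = ~np.isfinite(sg)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite genetic variance at panel column {j - 1}")
    sigma2_gy = float(sg[0])
    sigma2_gx = sg[1:p + 1]
    sigma2_sum = sg[p + 1:]
    g_xy = 0.5 * (sigma2_sum - sigma2_gy - sigma2_gx)
    labels = list(band_labels) if band_labels is not None else list(range(p))
    return GeneticCovariances(
        g_xy=g_xy,
        sigma2_gy=sigma2_gy,
        sigma2_gx=sigma2_gx,
        band_labels=labels,
    )
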