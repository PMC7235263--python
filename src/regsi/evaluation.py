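"""Trial-blocked evaluation of indirect-selection accuracy.

Whole trials are assigned to training or testing sets, so no plot of any
trial appears on both sides (the setting a breeder faces when applying
historical index weights to future trials).  On the testing set we estimate,
from one-factor genotype models, the index heritability ``h2_I``, the target
heritability ``h2_y`` and the genetic correlation ``r_g`` between index and
target (via the sum-of-traits covariance), and report

    Acc(I) = sqrt(h2_I) * r_g          (accuracy of indirect selection)
    RE     = sqrt(h2_I / h2_y) * r_g   (efficiency vs. mass selection)

Tuning sweeps a complexity grid (lambda for penalized indices, q for the
reduced-rank index), fits coefficients on training covariances only, and
picks the complexity with the highest mean accuracy across partitions
(smallest complexity on ties).  Vegetation-index (RNDVI/GNDVI) and
L1-penalized phenotypic prediction baselines are included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import index_solvers as solvers
from . import mixed_models as mm

__all__ = [
    "Partition",
    "PlotData",
    "EvaluationResult",
    "TuningCurve",
    "make_partitions",
    "evaluate_index",
    "evaluate_indices",
    "tune",
    "vegetation_index",
    "l1_phen",
    "summarize",
    "preprocess_dataset",
    "DEFAULT_VEGETATION_WINDOWS",
]

logger = logging.getLogger(__name__)

#: Wavelength windows (nm) for the vegetation-index baselines.
DEFAULT_VEGETATION_WINDOWS = {
    "red": (660.0, 680.0),
    "green": (540.0, 560.0),
    "nir": (780.0, 850.0),
}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """One trial-blocked training/testing split."""

    train_trials: tuple
    test_trials: tuple
    replicate: int
    seed: int

    def __post_init__(self):
        if set(self.train_trials) & set(self.test_trials):
            raise ValueError("training and testing trial sets overlap")


@dataclass
class PlotData:
    """Plot-aligned, pre-adjusted and standardized analysis arrays.

    ``y`` and the columns of ``X`` are adjusted phenotypes (genotype signal
    plus residual, null mean, unit variance); rows are plots.
    """

    genotype: np.ndarray  # labels, length n
    trial: np.ndarray  # labels, length n
    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p)
    band_labels: list = field(default_factory=list)
    wavelengths: np.ndarray | None = None

    def __post_init__(self):
        n = self.y.shape[0]
        if not (len(self.genotype) == len(self.trial) == n == self.X.shape[0]):
            raise ValueError("plot-aligned arrays have inconsistent lengths")
        if not self.band_labels:
            self.band_labels = list(range(self.X.shape[1]))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def trial_ids(self) -> np.ndarray:
        return np.unique(self.trial)

    def subset(self, mask: np.ndarray) -> "PlotData":
        return PlotData(
            genotype=self.genotype[mask], trial=self.trial[mask],
            y=self.y[mask], X=self.X[mask],
            band_labels=self.band_labels, wavelengths=self.wavelengths,
        )


@dataclass
class EvaluationResult:
    """Indirect-selection metrics for one index on one testing set."""

    h2_I: float
    h2_y: float
    r_g: float
    acc: float
    re: float
    defined: bool = True
    n_clipped: int = 0


@dataclass
class TuningCurve:
    """Mean/SD of the evaluation metrics along a complexity axis."""

    axis_name: str  # "lambda" or "q"
    complexity: np.ndarray
    mean_acc: np.ndarray
    sd_acc: np.ndarray
    mean_h: np.ndarray  # sqrt-scale heritability of the index
    mean_rg: np.ndarray
    mean_active: np.ndarray  # mean number of active bands
    n_partitions: int = 0

    @property
    def argmax(self) -> int:
        """Index of the best complexity (max mean acc; ties -> smallest
        complexity, i.e. fewest active bands / largest lambda)."""
        best = np.nanmax(self.mean_acc)
        cands = np.flatnonzero(self.mean_acc >= best - 1e-12)
        order = np.argsort(self.mean_active[cands], kind="stable")
        return int(cands[order[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.axis_name: self.complexity,
            "mean_active": self.mean_active,
            "mean_acc": self.mean_acc,
            "sd_acc": self.sd_acc,
            "mean_h": self.mean_h,
            "mean_rg": self.mean_rg,
        })


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


def make_partitions(
    trial_ids: Sequence,
    n_train_trials: int,
    n_partitions: int,
    seed: int = 0,
) -> list[Partition]:
    """Uniform random trial-blocked splits, reproducible under ``seed``."""
    trials = list(trial_ids)
    if not (1 <= n_train_trials < len(trials)):
        raise ValueError(
            f"n_train_trials={n_train_trials} out of range [1, {len(trials) - 1}]"
        )
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_partitions):
        perm = rng.permutation(len(trials))
        train = tuple(sorted(trials[i] for i in perm[:n_train_trials]))
        test = tuple(sorted(trials[i] for i in perm[n_train_trials:]))
        out.append(Partition(train, test, replicate=r, seed=seed))
    return out


# ---------------------------------------------------------------------------
# Metric estimation on a testing set
# ---------------------------------------------------------------------------


def evaluate_indices(
    index_matrix: np.ndarray,
    target_values: np.ndarray,
    genotype_ids: np.ndarray,
) -> list[EvaluationResult]:
    """Evaluate many candidate indices at once (columns share the plots).

    All one-factor genotype fits (each index, the target, each index +
    target) run through the vectorized REML path.
    """
    I = np.asarray(index_matrix, dtype=float)
    if I.ndim == 1:
        I = I[:, None]
    y = np.asarray(target_values, dtype=float)
    if I.shape[0] != y.shape[0] or len(genotype_ids) != y.shape[0]:
        raise ValueError("index, target and genotype ids must share plots")
    codes, uniques = pd.factorize(pd.Series(genotype_ids), sort=True)
    if len(uniques) < 2:
        raise ValueError("need at least 2 genotypes to evaluate")
    m = I.shape[1]
    big = np.column_stack([y[:, None], I, I + y[:, None]])
    sg, se, _ = mm._one_factor_reml(big, codes.astype(np.intp), len(uniques))
    sg_y, se_y = sg[0], se[0]
    h2_y = sg_y / (sg_y + se_y) if (sg_y + se_y) > 0 else np.nan
    results = []
    for k in range(m):
        sg_I, se_I = sg[1 + k], se[1 + k]
        sg_sum = sg[1 + m + k]
        tot = sg_I + se_I
        if tot <= 0 or sg_I <= 0 or sg_y <= 0:
            results.append(EvaluationResult(
                h2_I=float(sg_I / tot) if tot > 0 else np.nan,
                h2_y=float(h2_y), r_g=np.nan, acc=np.nan, re=np.nan,
                defined=False,
            ))
            continue
        h2_I = min(max(sg_I / tot, 0.0), 1.0)
        g_Iy = 0.5 * (sg_sum - sg_I - sg_y)
        r_g = g_Iy / np.sqrt(sg_I * sg_y)
        clipped = 0
        if abs(r_g) > 1.0:
            clipped = 1
            logger.info("genetic correlation %.3f clipped to [-1, 1]", r_g)
            r_g = float(np.clip(r_g, -1.0, 1.0))
        acc = np.sqrt(h2_I) * r_g
        re = np.sqrt(h2_I / h2_y) * r_g if h2_y > 0 else np.nan
        results.append(EvaluationResult(
            h2_I=float(h2_I), h2_y=float(h2_y), r_g=float(r_g),
            acc=float(acc), re=float(re), defined=True, n_clipped=clipped,
        ))
    return results


def evaluate_index(
    index_values: np.ndarray,
    target_values: np.ndarray,
    genotype_ids: np.ndarray,
) -> EvaluationResult:
    """Heritability, genetic correlation, Acc and RE of one index."""
    return evaluate_indices(index_values, target_values, genotype_ids)[0]


# ---------------------------------------------------------------------------
# Training-side covariance estimation
# ---------------------------------------------------------------------------


def _training_covariances(train: PlotData) -> tuple[solvers.CovariancePair,
                                                    np.ndarray, np.ndarray,
                                                    float]:
    """P_hat, G_hat and the training centering/scaling for one partition.

    Centering and scaling are computed on the training plots only and later
    applied unchanged to the testing plots (no leakage).
    """
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (train.X - mu) / sd
    sy = float(np.std(train.y, ddof=1))
    ys = train.y / (sy if sy > 0 else 1.0)
    P = solvers.phenotypic_covariance(Xs - Xs.mean(axis=0))
    table = pd.DataFrame({"genotype": train.genotype,
                          "trial": train.trial, "value": ys})
    gc = mm.genetic_covariances_panel(
        mm.PhenotypeTable(table), Xs, band_labels=train.band_labels
    )
    cov = solvers.CovariancePair(
        P=P, G=gc.g_xy, sigma2_gy=gc.sigma2_gy,
        band_labels=list(train.band_labels),
        wavelengths=train.wavelengths,
    )
    return cov, mu, sd, (sy if sy > 0 else 1.0)


def _fit_grid(
    method: str,
    cov: solvers.CovariancePair,
    train: PlotData,
    mu: np.ndarray,
    sd: np.ndarray,
    sy: float,
    grid: np.ndarray,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient matrix (p x n_grid) for one training set.

    For L1/EN/L2 the grid holds fractions of lambda_max = max|G|; for PC it
    holds component counts q.
    """
    p = cov.p
    B = np.zeros((p, len(grid)))
    if method == "PC":
        mm_table = pd.DataFrame({"genotype": train.genotype,
                                 "trial": train.trial,
                                 "value": train.y / sy})
        Xs = (train.X - mu) / sd
        dec = solvers.spectral_decomposition(Xs, center=True)
        q_max = int(min(np.max(grid), dec.rank))
        W = dec.scores(q_max)
        gw = mm.genetic_covariances_panel(
            mm.PhenotypeTable(mm_table), W,
            band_labels=list(range(q_max)),
        )
        for i, q in enumerate(grid):
            q = int(min(q, dec.rank))
            B[:, i] = solvers.pc_si(dec, gw.g_xy, q).beta
        return B, grid.astype(float)
    lam_max = float(np.max(np.abs(cov.G)))
    lams = grid * lam_max
    if method == "L1":
        path = solvers.lars_psi(cov, lambda_min=float(lams.min()))
        for i, lam in enumerate(lams):
            B[:, i] = path.at(lam).beta
    elif method == "EN":
        path = solvers.elastic_net_psi(cov, lambda_grid=lams, alpha=alpha)
        for i, c in enumerate(path.coefficients):
            B[:, i] = c.beta
    elif method == "L2":
        for i, lam in enumerate(lams):
            B[:, i] = solvers.l2_psi(cov, lam).beta
    else:
        raise ValueError(f"unknown method {method!r}")
    return B, lams


def tune(
    data: PlotData,
    method: str,
    partitions: Sequence[Partition],
    grid: np.ndarray | None = None,
    alpha: float = 1.0,
) -> tuple[TuningCurve, solvers.IndexCoefficients]:
    """Trial-blocked tuning of one index family.

    For each partition the coefficients are fit on training covariances
    only, applied to the testing plots, and the accuracy estimated there;
    the curve aggregates mean/SD across partitions.  The optimum is the
    smallest complexity attaining the maximum mean accuracy; the returned
    coefficients are refit on the full dataset at that complexity.

    ``grid``: fractions of lambda_max (decreasing) for L1/EN/L2, component
    counts (increasing) for PC.  Defaults: 30 log-spaced fractions from 1
    to 0.01, or q = 1..min(p, 60).
    """
    method = method.upper()
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    if grid is None:
        if method == "PC":
            grid = np.arange(1, min(data.p, 60) + 1)
        else:
            grid = np.geomspace(1.0, 0.01, 30)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 1:
        raise ValueError("empty tuning grid")

    accs, hs, rgs, actives = [], [], [], []
    for part in partitions:
        trn_mask = np.isin(data.trial, part.train_trials)
        tst_mask = np.isin(data.trial, part.test_trials)
        train = data.subset(trn_mask)
        test = data.subset(tst_mask)
        cov, mu, sd, sy = _training_covariances(train)
        B, _ = _fit_grid(method, cov, train, mu, sd, sy, grid, alpha)
        X_tst = (test.X - mu) / sd
        I_tst = X_tst @ B
        res = evaluate_indices(I_tst, test.y / sy, test.genotype)
        accs.append([r.acc for r in res])
        hs.append([np.sqrt(r.h2_I) if np.isfinite(r.h2_I) else np.nan
                   for r in res])
        rgs.append([r.r_g for r in res])
        actives.append((B != 0).sum(axis=0))
    accs = np.asarray(accs, dtype=float)
    if np.all(np.isnan(accs)):
        raise ValueError("all grid points undefined on every partition")
    with warnings.catch_warnings():
        # all-NaN grid points (e.g. the null index at lambda_max) are
        # legitimately undefined
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = TuningCurve(
            axis_name="q" if method == "PC" else "lambda",
            complexity=grid,
            mean_acc=np.nanmean(accs, axis=0),
            sd_acc=np.nanstd(accs, axis=0, ddof=1) if accs.shape[0] > 1
            else np.zeros(accs.shape[1]),
            mean_h=np.nanmean(np.asarray(hs, dtype=float), axis=0),
            mean_rg=np.nanmean(np.asarray(rgs, dtype=float), axis=0),
            mean_active=np.mean(np.asarray(actives, dtype=float), axis=0),
            n_partitions=len(partitions),
        )
    best = curve.argmax
    # refit at the chosen complexity on the full dataset
    cov, mu, sd, sy = _training_covariances(data)
    B, lams = _fit_grid(method, cov, data, mu, sd, sy,
                        grid[best:best + 1], alpha)
    coef = solvers.IndexCoefficients(
        B[:, 0], method=method if method != "L1" else "L1",
        lam=float(lams[0]) if method != "PC" else 0.0,
        alpha=alpha if method in ("L1", "EN") else 0.0,
        q=int(grid[best]) if method == "PC" else None,
        band_labels=list(data.band_labels),
    )
    return curve, coef


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def vegetation_index(
    X: np.ndarray,
    wavelengths: np.ndarray,
    kind: str,
    windows: dict | None = None,
) -> np.ndarray:
    """Per-plot RNDVI or GNDVI from raw (non-negative) reflectances.

    ``RNDVI = (NIR - Red) / (NIR + Red)``; GNDVI uses the green window.
    Each window value is the mean reflectance over the bands whose
    wavelength lies inside the configured window.
    """
    kind = kind.upper()
    if kind not in ("RNDVI", "GNDVI"):
        raise ValueError(f"kind must be RNDVI or GNDVI, got {kind!r}")
    win = dict(DEFAULT_VEGETATION_WINDOWS)
    if windows:
        win.update(windows)
    X = np.asarray(X, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)

    def band_mean(name: str) -> np.ndarray:
        lo, hi = win[name]
        mask = (wavelengths >= lo) & (wavelengths <= hi)
        if not mask.any():
            raise ValueError(
                f"no band covers the {name} window [{lo}, {hi}] nm"
            )
        return X[:, mask].mean(axis=1)

    nir = band_mean("nir")
    other = band_mean("red" if kind == "RNDVI" else "green")
    denom = nir + other
    if np.any(denom == 0):
        i = int(np.flatnonzero(denom == 0)[0])
        raise ValueError(
            f"undefined {kind} at plot {i}: NIR + "
            f"{'Red' if kind == 'RNDVI' else 'Green'} is zero"
        )
    return (nir - other) / denom


def l1_phen(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    alpha: float = 1.0,
) -> solvers.RegularizationPath:
    """L1-penalized *phenotypic* prediction with the same solver machinery.

    Identical to the penalized index except the genetic covariances are
    replaced by the phenotypic covariances ``X'y / (n-1)`` — phenotypic
    prediction targets the phenotype, the index targets the genetic merit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n = X.shape[0]
    P = solvers.phenotypic_covariance(Xc)
    b = Xc.T @ yc / (n - 1)
    cov = solvers.CovariancePair(P=P, G=b, sigma2_gy=float(yc @ yc / (n - 1)))
    if lambda_grid is None and alpha == 1.0:
        return solvers.lars_psi(cov)
    return solvers.elastic_net_psi(cov, lambda_grid=lambda_grid, alpha=alpha)


def summarize(values: Sequence[float]) -> dict:
    """Mean, SD and normal-approximation 95% CI of per-partition values."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 partition values to summarize")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    half = 1.96 * sd / np.sqrt(v.size)
    return {"mean": mean, "sd": sd, "ci_low": mean - half,
            "ci_high": mean + half, "n": int(v.size)}


# ---------------------------------------------------------------------------
# Preprocessing pipeline (pre-adjust -> filter -> standardize -> PlotData)
# ---------------------------------------------------------------------------


def preprocess_dataset(
    target: mm.PhenotypeTable,
    reflectance: pd.DataFrame,
    band_labels: Sequence[str],
    include_timepoint: bool = False,
    fence_multiplier: float = 3.0,
) -> PlotData:
    """Full pre-processing: BLUP adjustment, outlier fence, standardization.

    The outlier fence is driven by the *target* adjusted values; reflectance
    records of removed plots are dropped in tandem.  Each band is
    pre-adjusted with its own random-effects model (time-point effect
    included when ``include_timepoint``); every adjusted trait is scaled to
    unit variance on the retained plots.
    """
    adj_y = mm.preadjust(target, include_timepoint=False)
    adj_y = mm.filter_and_standardize(adj_y, fence_multiplier=fence_multiplier)
    keep = adj_y.retained

    cols = [c for c in reflectance.columns if c not in band_labels]
    Xadj = np.empty((int(keep.sum()), len(band_labels)))
    start = None  # neighbouring bands warm-start each other's REML fit
    for j, label in enumerate(band_labels):
        tab = reflectance[cols].copy()
        tab["value"] = reflectance[label].to_numpy(dtype=float)
        adj_b = mm.preadjust(mm.PhenotypeTable(tab),
                             include_timepoint=include_timepoint,
                             start_ratios=start)
        start = adj_b.fit._log_ratios if adj_b.fit is not None else None
        vals = adj_b.values[keep]
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise ValueError(f"zero variance after adjustment in band {label}")
        Xadj[:, j] = vals / sd

    kept = target.data.loc[keep]
    return PlotData(
        genotype=kept["genotype"].to_numpy(),
        trial=kept["trial"].to_numpy(),
        y=adj_y.values[keep],
        X=Xadj,
        band_labels=list(band_labels),
    )
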