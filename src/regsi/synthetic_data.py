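"""Synthetic multi-trial phenotype and reflectance data with known truth.

The generator emulates the structure of a multi-environment wheat trial
system with aerial hyper-spectral phenotyping: genotypes nested in trials,
alpha-lattice replicates subdivided into sub-blocks, a smooth band-to-band
phenotypic correlation typical of reflectance spectra, and a low-dimensional
genetic covariance structure linking the bands to the target trait (grain
yield).  Because the generating genetic and environmental covariance
matrices are known, the accuracy of any index is available in closed form
(:func:`true_accuracy`), giving every downstream estimator an exact oracle.

Generative model (per plot, band vector x and target y):

    x = g_x(genotype) + e_x(plot) + trial + rep + subblock
    y = g_y(genotype) + e_y(plot) + trial + rep + subblock

with ``(g_x, g_y)`` drawn jointly from the (p+1)-dimensional genetic
covariance ``[[G_x, G_xy], [G_xy', sigma2_gy]]`` and plot-level
environmental deviations from ``E_x`` / ``sigma2_ey`` independent of all
genetic effects (the orthogonality assumption under which the selection
index is the best linear predictor).  Nuisance effects are iid per trait.

Default design constants mirror a CIMMYT-style yield trial system: 28
genotypes per trial in 3 replicates of 6 sub-blocks, 39 trials, 250
wavebands on 392-850 nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_models import PhenotypeTable

__all__ = [
    "SyntheticTruth",
    "SimulatedDataset",
    "make_covariance_structures",
    "simulate",
    "true_accuracy",
    "DEFAULT_DESIGN",
]

logger = logging.getLogger(__name__)

#: CIMMYT-style defaults: trials x genotypes/trial x replicates x sub-blocks.
DEFAULT_DESIGN = dict(n_trials=39, genotypes_per_trial=28, replicates=3,
                      subblocks=6)
#: Nuisance variances on the standardized-trait scale (modest trial-to-trial
#: and within-trial design effects relative to unit plot variance).
DEFAULT_NUISANCE_VARIANCES = dict(trial=0.5, rep=0.1, subblock=0.05)
WAVELENGTH_RANGE = (392.0, 850.0)


@dataclass
class SyntheticTruth:
    """Generating covariance structures (the oracle for all estimators)."""

    G_x: np.ndarray  # (p, p) genetic covariance of the bands
    E_x: np.ndarray  # (p, p) environmental covariance of the bands
    G_xy: np.ndarray  # (p,) genetic covariances bands-target
    sigma2_gy: float
    sigma2_ey: float
    wavelengths: np.ndarray
    nuisance_variances: dict = field(
        default_factory=lambda: dict(DEFAULT_NUISANCE_VARIANCES)
    )

    @property
    def p(self) -> int:
        return self.G_xy.shape[0]

    @property
    def P_x(self) -> np.ndarray:
        """Phenotypic (plot-level, pre-adjusted) covariance G_x + E_x."""
        return self.G_x + self.E_x

    def joint_genetic(self) -> np.ndarray:
        """(p+1)-dimensional genetic covariance of (bands, target)."""
        p = self.p
        J = np.empty((p + 1, p + 1))
        J[:p, :p] = self.G_x
        J[:p, p] = self.G_xy
        J[p, :p] = self.G_xy
        J[p, p] = self.sigma2_gy
        return J

    def h2_target(self) -> float:
        return self.sigma2_gy / (self.sigma2_gy + self.sigma2_ey)


@dataclass
class SimulatedDataset:
    """Simulated target table plus aligned reflectance panel and the truth."""

    target: PhenotypeTable
    reflectance: pd.DataFrame  # design columns + one column per band
    band_labels: list
    wavelengths: np.ndarray
    truth: SyntheticTruth

    @property
    def X(self) -> np.ndarray:
        return self.reflectance[self.band_labels].to_numpy(dtype=float)

    def band_table(self, j: int) -> PhenotypeTable:
        """Records of one band as a PhenotypeTable (for per-band models)."""
        label = self.band_labels[j]
        cols = [c for c in self.reflectance.columns if c not in self.band_labels]
        out = self.reflectance[cols].copy()
        out["value"] = self.reflectance[label].to_numpy(dtype=float)
        return PhenotypeTable(out)


def _smooth_loadings(wavelengths: np.ndarray, n_factors: int,
                     decay: float) -> np.ndarray:
    """(p, k) smooth factor loadings: Gaussian bumps along the spectrum.

    ``decay`` is the bump width in nm; decay = 0 degenerates to indicator
    loadings (each factor loads one band), giving diagonal structure when
    n_factors = p.
    """
    p = wavelengths.shape[0]
    centers = np.linspace(wavelengths[0], wavelengths[-1], n_factors)
    if decay <= 0.0:
        L = np.zeros((p, n_factors))
        for k, c in enumerate(centers):
            L[int(np.argmin(np.abs(wavelengths - c))), k] = 1.0
        return L
    d = wavelengths[:, None] - centers[None, :]
    return np.exp(-0.5 * (d / decay) ** 2)


def make_covariance_structures(
    p: int,
    n_factors: int = 5,
    decay: float = 60.0,
    h2_bands: float | np.ndarray = 0.5,
    h2_target: float = 0.5,
    r_g_profile: np.ndarray | None = None,
    env_corr_length: float | None = None,
    nuisance_variances: dict | None = None,
) -> SyntheticTruth:
    """Build generating covariances with requested heritabilities.

    Parameters
    ----------
    p
        Number of wavebands.
    n_factors
        Rank of the dominant genetic factor structure (the "informative
        genetic dimension").
    decay
        Smoothness scale in nm for both the genetic factor loadings and
        (by default) the environmental correlation; 0 gives diagonal
        ``G_x`` and ``E_x``.
    h2_bands, h2_target
        Plot-basis heritabilities; band total variance is 1, so
        ``diag(G_x) = h2_bands`` exactly.
    r_g_profile : (p,) array, optional
        Requested genetic correlations between each band and the target.
        Default: a smooth profile concentrated on the factor structure.
    env_corr_length
        Correlation length (nm) of the environmental band covariance;
        defaults to ``decay``.

    Raises
    ------
    ValueError
        If the requested profile makes the joint (bands + target) genetic
        covariance non-PSD even after shrinking ``G_x`` toward its
        diagonal; the message states the violated bound.
    """
    if not (0.0 < h2_target < 1.0):
        raise ValueError(f"h2_target must be in (0, 1), got {h2_target}")
    h2_b = np.broadcast_to(np.asarray(h2_bands, dtype=float), (p,)).copy()
    if np.any((h2_b <= 0) | (h2_b >= 1)):
        raise ValueError("band heritabilities must be in (0, 1)")
    wavelengths = np.linspace(*WAVELENGTH_RANGE, p)

    # genetic correlation structure of the bands: dominant low-rank smooth
    # factors plus a small diagonal nugget, rescaled to a correlation matrix
    L = _smooth_loadings(wavelengths, n_factors, decay)
    C = L @ L.T
    dg = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    C = C / np.outer(dg, dg)
    nugget = 0.05
    C = (1.0 - nugget) * C + nugget * np.eye(p)
    sd_g = np.sqrt(h2_b)
    G_x = C * np.outer(sd_g, sd_g)

    # environmental covariance: smooth exponential-decay correlation
    ell = decay if env_corr_length is None else env_corr_length
    if ell <= 0.0:
        R = np.eye(p)
    else:
        d = np.abs(wavelengths[:, None] - wavelengths[None, :])
        R = np.exp(-d / ell)
    sd_e = np.sqrt(1.0 - h2_b)
    E_x = R * np.outer(sd_e, sd_e)

    sigma2_gy = h2_target
    sigma2_ey = 1.0 - h2_target
    if r_g_profile is None:
        # concentrate the genetic link on the leading factor
        u = L[:, 0] / max(np.max(np.abs(L[:, 0])), 1e-12)
        r_g_profile = 0.6 * u
    r_g = np.asarray(r_g_profile, dtype=float).ravel()
    if r_g.shape[0] != p:
        raise ValueError(f"r_g_profile has length {r_g.shape[0]}, expected {p}")
    if np.any(np.abs(r_g) > 1.0):
        raise ValueError("genetic correlations must lie in [-1, 1]")
    G_xy = r_g * np.sqrt(np.diag(G_x) * sigma2_gy)

    # enforce PSD of the joint genetic covariance; shrink G_x toward its
    # diagonal if the requested cross-covariances are too strong for the
    # low-rank structure
    diag_Gx = np.diag(np.diag(G_x))
    for w in np.linspace(0.0, 1.0, 11):
        G_try = (1.0 - w) * G_x + w * diag_Gx
        schur = sigma2_gy - G_xy @ np.linalg.solve(G_try, G_xy)
        if schur >= -1e-10 * sigma2_gy:
            if w > 0:
                logger.info("shrunk G_x toward diagonal (w=%.1f) to keep the "
                            "joint genetic covariance PSD", w)
            G_x = G_try
            break
    else:
        bound = float(np.sum(r_g ** 2))
        raise ValueError(
            "infeasible genetic-correlation profile: even with diagonal "
            f"G_x, sum(r_g^2) = {bound:.3f} exceeds 1, so the target's "
            "genetic variance cannot accommodate the requested covariances"
        )

    return SyntheticTruth(
        G_x=G_x, E_x=E_x, G_xy=G_xy,
        sigma2_gy=float(sigma2_gy), sigma2_ey=float(sigma2_ey),
        wavelengths=wavelengths,
        nuisance_variances=dict(nuisance_variances
                                or DEFAULT_NUISANCE_VARIANCES),
    )


def _psd_sqrt(A: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (clipping tiny
    negative eigenvalues from round-off)."""
    vals, vecs = np.linalg.eigh(0.5 * (A + A.T))
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)[None, :]


def simulate(
    truth: SyntheticTruth,
    n_trials: int = 10,
    genotypes_per_trial: int = 28,
    replicates: int = 3,
    subblocks: int = 6,
    seed: int = 0,
    env_label: str = "SYN",
) -> SimulatedDataset:
    """Draw a complete multi-trial dataset from the generating model.

    Genotypes are nested in trials (distinct lines per trial, as in a
    breeding-stage trial system).  Within each trial x replicate, the
    genotypes are randomly divided into ``subblocks`` incomplete blocks.
    One seeded generator per effect type (genetic, environmental, each
    nuisance factor, blocking) keeps the streams independent.
    """
    for name, v in dict(n_trials=n_trials, genotypes_per_trial=genotypes_per_trial,
                        replicates=replicates, subblocks=subblocks).items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if subblocks > genotypes_per_trial:
        raise ValueError("more sub-blocks than genotypes per trial")
    p = truth.p
    ss = np.random.SeedSequence(seed)
    rng_g, rng_e, rng_trial, rng_rep, rng_block, rng_assign = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n_geno = n_trials * genotypes_per_trial
    A = _psd_sqrt(truth.joint_genetic())  # (p+1, p+1)
    gen = rng_g.standard_normal((n_geno, p + 1)) @ A.T  # genetic effects
    nv = truth.nuisance_variances
    sd_t = np.sqrt(nv.get("trial", 0.0))
    sd_r = np.sqrt(nv.get("rep", 0.0))
    sd_b = np.sqrt(nv.get("subblock", 0.0))
    trial_eff = sd_t * rng_trial.standard_normal((n_trials, p + 1))
    rep_eff = sd_r * rng_rep.standard_normal((n_trials * replicates, p + 1))
    block_eff = sd_b * rng_block.standard_normal(
        (n_trials * replicates * subblocks, p + 1))

    Ex_half = _psd_sqrt(truth.E_x)
    sd_ey = np.sqrt(truth.sigma2_ey)

    rows = []
    geno_ids = np.empty(0, dtype=np.intp)
    n_plots = n_geno * replicates
    geno_idx = np.empty(n_plots, dtype=np.intp)
    trial_idx = np.empty(n_plots, dtype=np.intp)
    rep_idx = np.empty(n_plots, dtype=np.intp)
    block_idx = np.empty(n_plots, dtype=np.intp)
    sub_lab = np.empty(n_plots, dtype=np.intp)
    pos = 0
    for t in range(n_trials):
        genos = np.arange(t * genotypes_per_trial, (t + 1) * genotypes_per_trial)
        for r in range(replicates):
            order = rng_assign.permutation(genotypes_per_trial)
            blocks = np.array_split(order, subblocks)
            for m, bl in enumerate(blocks):
                k = len(bl)
                sl = slice(pos, pos + k)
                geno_idx[sl] = genos[bl]
                trial_idx[sl] = t
                rep_idx[sl] = t * replicates + r
                block_idx[sl] = (t * replicates + r) * subblocks + m
                sub_lab[sl] = m
                pos += k
    assert pos == n_plots

    noise = rng_e.standard_normal((n_plots, p + 1))
    env_dev = np.empty((n_plots, p + 1))
    env_dev[:, :p] = noise[:, :p] @ Ex_half.T
    env_dev[:, p] = sd_ey * noise[:, p]

    values = (
        gen[geno_idx]
        + env_dev
        + trial_eff[trial_idx]
        + rep_eff[rep_idx]
        + block_eff[block_idx]
    )

    design = pd.DataFrame({
        "genotype": np.char.add("G", np.char.zfill(
            geno_idx.astype("U8"), 5)),
        "trial": np.char.add("T", np.char.zfill(
            trial_idx.astype("U4"), 3)),
        "rep": np.char.add("R", (rep_idx % replicates + 1).astype("U2")),
        "subblock": np.char.add("B", (sub_lab + 1).astype("U2")),
        "env": env_label,
    })
    target_df = design.copy()
    target_df["value"] = values[:, p]
    band_labels = [f"b{int(round(w))}_{j}" for j, w in
                   enumerate(truth.wavelengths)]
    refl = pd.concat(
        [design, pd.DataFrame(values[:, :p], columns=band_labels)], axis=1
    )

    return SimulatedDataset(
        target=PhenotypeTable(target_df),
        reflectance=refl,
        band_labels=band_labels,
        wavelengths=truth.wavelengths.copy(),
        truth=truth,
    )


def true_accuracy(beta: np.ndarray, truth: SyntheticTruth) -> float:
    """Closed-form accuracy of indirect selection of the index ``x' beta``.

    ``Acc = beta' G_xy / sqrt(beta' (G_x + E_x) beta * sigma2_gy)`` — the
    correlation between the index and the target's genetic merit under the
    generating model.  Invariant to positive rescaling of ``beta``.
    """
    beta = np.asarray(beta, dtype=float).ravel()
    if not np.any(beta != 0.0):
        raise ValueError("beta is zero; accuracy undefined")
    if truth.sigma2_gy <= 0.0:
        raise ValueError("target genetic variance is zero; accuracy undefined")
    num = float(beta @ truth.G_xy)
    den = float(beta @ truth.P_x @ beta) * truth.sigma2_gy
    return num / np.sqrt(den)
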