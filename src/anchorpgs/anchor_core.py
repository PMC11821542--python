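"""Ancestry-decomposed PGS model fitting and effect-size-correlation estimation.

The phenotype is modeled as ``Y = I + (b_eu * EPGS + b_af * APGS) * (1 +
omega * theta) + covariates + noise`` where EPGS / APGS are the portions
of a polygenic score accumulated over European- / African-background
segments (built from mean-centered ancestry-specific dosages) and theta
is the global African-ancestry fraction.  With omega fixed to zero the
model is linear; with omega free, conditioning on the ratio r = b_eu /
(b_eu + b_af) makes it linear again, so the fit is a 1,000-point grid
search over r in [0, 1] minimizing the residual sum of squares.

The ratio of the fitted b_eu to the phenotype-on-PGS slope in a
European-ancestry reference cohort estimates the correlation of causal
effect sizes between the two ancestry groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import as_rng
from .pgs_engine import PgsWeights, ReferenceSlope, match_weights

__all__ = [
    "DecomposedPGS",
    "AnchorFit",
    "RhoEstimate",
    "decompose_pgs",
    "residualize",
    "fit_anchor",
    "bootstrap_fit",
    "bin_and_fit",
    "estimate_rho",
    "pool_traits",
    "DEFAULT_BIN_EDGES",
]

log = logging.getLogger(__name__)

GRID_POINTS = 1_000

# African-ancestry-fraction bin edges: first bin closed, others (lo, hi]
DEFAULT_BIN_EDGES = (0.1, 0.35, 0.55, 0.78, 0.95, 1.0)


@dataclass
class DecomposedPGS:
    """European- and African-segment score components per individual."""

    epgs: np.ndarray
    apgs: np.ndarray
    theta: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.epgs = np.asarray(self.epgs, dtype=float).ravel()
        self.apgs = np.asarray(self.apgs, dtype=float).ravel()
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if not (self.epgs.shape == self.apgs.shape == self.theta.shape):
            raise ValueError("epgs, apgs and theta must have equal length")
        if not (np.all(np.isfinite(self.epgs)) and np.all(np.isfinite(self.apgs))):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return self.epgs.shape[0]

    def take(self, idx) -> "DecomposedPGS":
        cov = None if self.covariates is None else self.covariates[idx]
        return DecomposedPGS(self.epgs[idx], self.apgs[idx], self.theta[idx], cov)


@dataclass
class AnchorFit:
    """Fitted model parameters with optional bootstrap replicates.

    ``boot`` maps quantity name -> replicate vector; CIs are equal-tailed
    percentile intervals over replicates.
    """

    intercept: float
    beta_eu: float
    beta_af: float
    omega: float
    omega_mode: str
    omega_identifiable: bool = True
    sse: float = np.nan
    n: int = 0
    n_boot: int = 0
    n_boot_dropped: int = 0
    boot: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    @property
    def beta_eu_af(self) -> float:
        """Projected EPGS slope at 100% African ancestry."""
        return self.beta_eu * (1.0 + self.omega)

    @property
    def beta_af_af(self) -> float:
        """Projected APGS slope at 100% African ancestry."""
        return self.beta_af * (1.0 + self.omega)


@dataclass
class RhoEstimate:
    """Effect-size-correlation estimates derived from a fit and a reference slope."""

    rho: float
    rho_projected_af: float
    local_ratio: float
    ci: dict = field(default_factory=dict)
    unstable: bool = False
    n_boot: int = 0


def decompose_pgs(
    centered_eu,
    centered_af,
    weights: PgsWeights,
    variants,
    theta,
    covariates=None,
) -> DecomposedPGS:
    """Accumulate score weights over the two mean-centered dosage matrices."""
    centered_eu = np.asarray(centered_eu, dtype=float)
    centered_af = np.asarray(centered_af, dtype=float)
    cols, w = match_weights(weights, variants)
    if cols.shape[0] == 0:
        raise ValueError("no overlap between weight variants and cohort variants")
    epgs = centered_eu[:, cols] @ w
    apgs = centered_af[:, cols] @ w
    return DecomposedPGS(epgs=epgs, apgs=apgs, theta=theta, covariates=covariates)


def residualize(x, covariates=None) -> np.ndarray:
    """OLS residual of x on an intercept plus covariate columns."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must match x")
        cols.append(C)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariates (collinear columns: {bad})")
    coef, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef


def _prepare(Y, scores: DecomposedPGS):
    """Residualize phenotype-model ingredients on intercept + covariates."""
    Y = np.asarray(Y, dtype=float).ravel()
    if Y.shape[0] != scores.n:
        raise ValueError("phenotype length must match scores")
    C = scores.covariates
    e = residualize(scores.epgs, C)
    a = residualize(scores.apgs, C)
    th = scores.theta
    return Y, C, e, a, th


def _ols(X, y):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ coef
    return coef, float(res @ res)


def fit_anchor(Y, scores: DecomposedPGS, omega_mode: str = "fixed_zero") -> AnchorFit:
    """Fit the decomposed-score model, optionally with the ancestry interaction.

    ``omega_mode="fixed_zero"`` fits ``Y ~ I + b_eu*E + b_af*A (+ covariates)``
    by OLS.  ``omega_mode="free"`` grid-searches the ratio
    ``r = b_eu / (b_eu + b_af)`` over 1,000 values in [0, 1]; at each r the
    model ``Y ~ I + s*Z + t*(Z*theta)`` with ``Z = r*E + (1-r)*A`` is
    linear, and the grid minimizer yields ``b_eu = s*r``, ``b_af = s*(1-r)``,
    ``omega = t/s``.
    """
    Y, C, e, a, th = _prepare(Y, scores)
    n = Y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 individuals")
    if np.var(Y) <= 0:
        raise ValueError("constant phenotype")
    ones = np.ones(n)
    cov_cols = () if C is None else (C if C.ndim == 2 else C[:, None],)

    if omega_mode == "fixed_zero":
        X = np.column_stack([ones, e, a, *cov_cols])
        coef, sse = _ols(X, Y)
        return AnchorFit(
            intercept=float(coef[0]),
            beta_eu=float(coef[1]),
            beta_af=float(coef[2]),
            omega=0.0,
            omega_mode=omega_mode,
            sse=sse,
            n=n,
        )
    if omega_mode != "free":
        raise ValueError("omega_mode must be 'fixed_zero' or 'free'")

    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    best = None
    for r in grid:
        z = r * e + (1.0 - r) * a
        X = np.column_stack([ones, z, z * th, *cov_cols])
        coef, sse = _ols(X, Y)
        if not np.isfinite(sse):
            raise ValueError("non-finite SSE during grid search")
        if best is None or sse < best[0]:
            best = (sse, r, coef)
    sse, r, coef = best
    s, t = float(coef[1]), float(coef[2])
    sd_ratio = np.std(Y) / max(np.std(r * e + (1 - r) * a), 1e-300)
    identifiable = abs(s) >= 1e-10 * sd_ratio
    omega = t / s if identifiable else np.nan
    if not identifiable:
        log.warning("fit_anchor: composite slope ~ 0; omega unidentifiable")
    return AnchorFit(
        intercept=float(coef[0]),
        beta_eu=s * r,
        beta_af=s * (1.0 - r),
        omega=omega,
        omega_mode=omega_mode,
        omega_identifiable=identifiable,
        sse=sse,
        n=n,
    )


_BOOT_KEYS = ("intercept", "beta_eu", "beta_af", "omega", "beta_eu_af", "beta_af_af")


def bootstrap_fit(
    Y,
    scores: DecomposedPGS,
    omega_mode: str = "fixed_zero",
    n_boot: int = 1000,
    seed=None,
    rng=None,
) -> AnchorFit:
    """Point fit plus percentile bootstrap over individuals."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Y = np.asarray(Y, dtype=float).ravel()
    fit = fit_anchor(Y, scores, omega_mode)
    gen = as_rng(seed, rng)
    reps = {k: [] for k in _BOOT_KEYS}
    dropped = 0
    n = scores.n
    for _ in range(n_boot):
        take = gen.integers(0, n, size=n)
        yb = Y[take]
        if np.var(yb) <= 0:
            dropped += 1
            continue
        try:
            fb = fit_anchor(yb, scores.take(take), omega_mode)
        except ValueError:
            dropped += 1
            continue
        for k in _BOOT_KEYS:
            reps[k].append(getattr(fb, k))
    boot = {k: np.asarray(v) for k, v in reps.items()}
    ci = {
        k: tuple(np.percentile(v[np.isfinite(v)], [2.5, 97.5]))
        if np.isfinite(v).any()
        else (np.nan, np.nan)
        for k, v in boot.items()
    }
    return replace(
        fit, n_boot=n_boot - dropped, n_boot_dropped=dropped, boot=boot, ci=ci
    )


def assign_bins(theta, edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Bin index per individual (-1 = outside all bins).

    The first bin is closed [e0, e1]; later bins are half-open (lo, hi].
    """
    theta = np.asarray(theta, dtype=float)
    edges = np.asarray(edges, dtype=float)
    out = np.full(theta.shape, -1, dtype=int)
    out[(theta >= edges[0]) & (theta <= edges[1])] = 0
    for b in range(1, edges.shape[0] - 1):
        out[(theta > edges[b]) & (theta <= edges[b + 1])] = b
    return out


def bin_and_fit(
    Y,
    scores: DecomposedPGS,
    edges=DEFAULT_BIN_EDGES,
    min_bin_size: int = 30,
    n_boot: int = 0,
    seed=None,
) -> dict[int, AnchorFit | None]:
    """Independent omega=0 fits within global-ancestry bins.

    The top bin (near-100% African ancestry) is fitted with the APGS
    alone.  Bins below ``min_bin_size`` are skipped (recorded as None).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    which = assign_bins(scores.theta, edges)
    n_bins = len(edges) - 1
    results: dict[int, AnchorFit | None] = {}
    gen = as_rng(seed, None)
    for b in range(n_bins):
        idx = np.flatnonzero(which == b)
        if idx.shape[0] < min_bin_size:
            log.warning("bin %d has n=%d < %d; skipped", b, idx.shape[0], min_bin_size)
            results[b] = None
            continue
        sub = scores.take(idx)
        yb = Y[idx]
        if b == n_bins - 1:
            # top bin: EPGS carries no signal at ~100% African ancestry
            sub = DecomposedPGS(
                epgs=np.zeros(idx.shape[0]),
                apgs=sub.apgs,
                theta=sub.theta,
                covariates=sub.covariates,
            )
            fit = _fit_apgs_only(yb, sub)
        elif n_boot:
            fit = bootstrap_fit(yb, sub, "fixed_zero", n_boot=n_boot, rng=gen)
        else:
            fit = fit_anchor(yb, sub, "fixed_zero")
        results[b] = fit
    return results


def _fit_apgs_only(Y, scores: DecomposedPGS) -> AnchorFit:
    Y, C, _, a, _ = _prepare(Y, scores)
    n = Y.shape[0]
    cov_cols = () if C is None else (C if C.ndim == 2 else C[:, None],)
    X = np.column_stack([np.ones(n), a, *cov_cols])
    coef, sse = _ols(X, Y)
    return AnchorFit(
        intercept=float(coef[0]),
        beta_eu=np.nan,
        beta_af=float(coef[1]),
        omega=0.0,
        omega_mode="fixed_zero",
        sse=sse,
        n=n,
    )


def _ratio_ci(num_reps, den_reps):
    k = min(num_reps.shape[0], den_reps.shape[0])
    if k < 2:
        return (np.nan, np.nan), np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = num_reps[:k] / den_reps[:k]
    ok = np.isfinite(ratios)
    if not ok.any():
        return (np.nan, np.nan), ratios
    return tuple(np.percentile(ratios[ok], [2.5, 97.5])), ratios


def estimate_rho(fit: AnchorFit, reference: ReferenceSlope) -> RhoEstimate:
    """Effect-size correlation and 100%-ancestry projections.

    ``rho = beta_eu / beta_obs_eu``; the projection multiplies by
    ``(1 + omega)``; ``local_ratio = beta_af / beta_obs_eu`` captures
    LD-driven (local) attenuation.  CIs pair bootstrap replicates of the
    two fits (both cohorts resampled).
    """
    if reference.beta == 0:
        raise ValueError("reference slope is zero; rho undefined")
    rho = fit.beta_eu / reference.beta
    omega = fit.omega if np.isfinite(fit.omega) else 0.0
    rho_proj = fit.beta_eu * (1.0 + omega) / reference.beta
    local = fit.beta_af / reference.beta
    ci = {}
    n_boot = 0
    if fit.boot and reference.boot_beta.size:
        for key, num in (
            ("rho", fit.boot["beta_eu"]),
            ("rho_projected_af", fit.boot["beta_eu_af"]),
            ("local_ratio", fit.boot["beta_af"]),
        ):
            ci[key], reps = _ratio_ci(num, reference.boot_beta)
            n_boot = reps.shape[0]
    unstable = bool(
        reference.ci_beta[0] <= 0.0 <= reference.ci_beta[1]
    ) if np.all(np.isfinite(reference.ci_beta)) else False
    if unstable:
        log.warning("estimate_rho: reference slope CI covers 0; rho unstable")
    return RhoEstimate(
        rho=float(rho),
        rho_projected_af=float(rho_proj),
        local_ratio=float(local),
        ci=ci,
        unstable=unstable,
        n_boot=n_boot,
    )


def pool_traits(estimates, weighting: str = "inverse_variance"):
    """Pool per-trait numerators and denominators into one correlation.

    ``estimates`` is a sequence of (fit, reference) pairs; the pooled
    value is the weighted mean of beta_eu over traits divided by the
    weighted mean of beta_obs_eu, with a trait-paired bootstrap CI when
    replicates are available.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one trait")
    nums = np.array([f.beta_eu for f, _ in estimates], dtype=float)
    dens = np.array([r.beta for _, r in estimates], dtype=float)
    if weighting == "equal":
        w = np.ones(len(estimates))
    elif weighting == "inverse_variance":
        w = np.empty(len(estimates))
        for i, (f, _) in enumerate(estimates):
            reps = f.boot.get("beta_eu", np.empty(0)) if f.boot else np.empty(0)
            v = np.var(reps) if reps.size > 1 else np.nan
            w[i] = 1.0 / v if np.isfinite(v) and v > 0 else np.nan
        if np.any(~np.isfinite(w)):  # fall back when replicates are missing
            w = np.ones(len(estimates))
    else:
        raise ValueError("weighting must be 'equal' or 'inverse_variance'")
    w = w / w.sum()
    den = float(np.sum(w * dens))
    if den == 0:
        raise ValueError("pooled reference slope is zero")
    pooled = float(np.sum(w * nums) / den)

    ci = (np.nan, np.nan)
    reps_n = [f.boot.get("beta_eu") for f, _ in estimates if f.boot]
    reps_d = [r.boot_beta for _, r in estimates if r.boot_beta.size]
    if len(reps_n) == len(estimates) and len(reps_d) == len(estimates):
        k = min(min(r.shape[0] for r in reps_n), min(r.shape[0] for r in reps_d))
        if k >= 2:
            num_mat = np.stack([r[:k] for r in reps_n])
            den_mat = np.stack([r[:k] for r in reps_d])
            pooled_reps = (w @ num_mat) / (w @ den_mat)
            ok = np.isfinite(pooled_reps)
            if ok.any():
                ci = tuple(np.percentile(pooled_reps[ok], [2.5, 97.5]))
    return pooled, ci
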