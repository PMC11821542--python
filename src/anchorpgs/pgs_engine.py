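"""Miniature GWAS, LD clumping, and polygenic-score construction.

Per-variant association is ordinary least squares of the (unnormalized)
phenotype on dosage plus covariates, so effect estimates stay in
phenotype units per allele copy.  Clumping greedily keeps the most
significant variant of each LD cluster; scores are uncentered weighted
dosage sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GwasResult",
    "PgsWeights",
    "ReferenceSlope",
    "run_gwas",
    "ld_clump",
    "compute_pgs",
    "fit_reference_slope",
    "attenuation_ratio",
]

log = logging.getLogger(__name__)


@dataclass
class GwasResult:
    """Per-variant marginal association estimates."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    variants: pd.DataFrame | None = None
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"beta": self.beta, "se": self.se, "p": self.p})
        if self.variants is not None:
            df.insert(0, "variant", self.variants["id"].to_numpy())
        return df


@dataclass
class PgsWeights:
    """Per-variant score weights keyed by variant identity."""

    table: pd.DataFrame  # columns: variant, chrom, pos, effect_allele, other_allele, weight

    REQUIRED = ("variant", "chrom", "pos", "effect_allele", "other_allele", "weight")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"weights table missing columns {missing}")
        if self.table["variant"].duplicated().any():
            raise ValueError("weights table has duplicate variants")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant"].to_numpy()


@dataclass
class ReferenceSlope:
    """Phenotype-on-PGS slope in a reference cohort, with bootstrap CI."""

    beta: float
    delta_r2: float
    ci_beta: tuple[float, float] = (np.nan, np.nan)
    ci_delta_r2: tuple[float, float] = (np.nan, np.nan)
    n: int = 0
    n_boot: int = 0
    boot_beta: np.ndarray = field(default_factory=lambda: np.empty(0))


def _design(n: int, covariates=None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must match the number of individuals")
        cols.append(C)
    return np.column_stack(cols)


def run_gwas(G, Y, covariates=None) -> GwasResult:
    """Marginal OLS association of Y on each dosage column plus covariates.

    Monomorphic variants yield NaN estimates (flagged, not raised).
    Missing dosages (NaN) are mean-imputed per variant, which leaves the
    estimate for the non-missing subset approximately unchanged at desk
    scale.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, m = G.shape
    if Y.shape[0] != n:
        raise ValueError("phenotype length must match genotype rows")
    X = _design(n, covariates)
    k = X.shape[1]  # includes intercept
    if n <= k + 1:
        raise ValueError("too few individuals for the covariate set")

    if np.any(np.isnan(G)):
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)

    # Frisch-Waugh: residualize Y and every dosage column on [1, covariates]
    Q, _ = np.linalg.qr(X)
    y_res = Y - Q @ (Q.T @ Y)
    G_res = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_res, G_res)
    poly = gg > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    gy = G_res.T @ y_res
    beta[poly] = gy[poly] / gg[poly]
    dof = n - k - 1
    sse = (y_res @ y_res) - beta[poly] ** 2 * gg[poly]
    sigma2 = np.maximum(sse, 0.0) / dof
    se[poly] = np.sqrt(sigma2 / gg[poly])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[poly] / se[poly]
    p[poly] = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p[poly] = np.clip(p[poly], np.finfo(float).tiny, 1.0)
    n_mono = int(m - poly.sum())
    if n_mono:
        log.info("run_gwas: %d monomorphic variants flagged missing", n_mono)
    return GwasResult(beta=beta, se=se, p=p, n=n)


def ld_clump(
    results: GwasResult,
    G,
    variants: pd.DataFrame,
    p1: float = 0.05,
    r2: float = 0.1,
    window_kb: float = 500.0,
    candidates=None,
) -> PgsWeights:
    """Greedy p-value-ranked LD clumping; index-variant effects as weights.

    A variant becomes an index if its p-value is below ``p1`` and it is
    not simultaneously within ``window_kb`` and in LD (squared Pearson
    correlation of dosages above ``r2``) with an already-chosen index.
    Ties in p are broken by genomic order.  ``candidates`` optionally
    restricts the variants eligible to become indices.
    """
    G = np.asarray(G, dtype=float)
    pos = variants["pos"].to_numpy(dtype=np.int64)
    chrom = pd.factorize(variants["chrom"].to_numpy())[0]
    p = results.p
    m = p.shape[0]
    eligible = np.zeros(m, dtype=bool)
    sel = np.arange(m) if candidates is None else np.asarray(candidates)
    eligible[sel] = True
    eligible &= ~np.isnan(p) & (p < p1)
    cand = np.flatnonzero(eligible)
    # ascending p, ties by genomic order (chrom, pos)
    order = np.lexsort((pos[cand], chrom[cand], p[cand]))
    cand = cand[order]

    window_bp = int(window_kb * 1000)
    Gc = G - G.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    indices: list[int] = []
    for j in cand:
        keep = True
        for k in indices:
            if chrom[k] != chrom[j] or abs(int(pos[k]) - int(pos[j])) > window_bp:
                continue
            denom = norms[j] * norms[k]
            r2_jk = 0.0 if denom == 0 else (Gc[:, j] @ Gc[:, k] / denom) ** 2
            if r2_jk > r2:
                keep = False
                break
        if keep:
            indices.append(int(j))
    if not indices:
        log.warning("ld_clump: no variants pass p1=%g; empty weight set", p1)
    idx = np.sort(np.asarray(indices, dtype=np.int64))
    table = pd.DataFrame(
        {
            "variant": variants["id"].to_numpy()[idx],
            "chrom": variants["chrom"].to_numpy()[idx],
            "pos": pos[idx],
            "effect_allele": variants["alt"].to_numpy()[idx],
            "other_allele": variants["ref"].to_numpy()[idx],
            "weight": results.beta[idx],
        }
    )
    return PgsWeights(table=table)


def match_weights(weights: PgsWeights, variants: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map weight rows onto cohort variant columns by variant id.

    Returns (column indices, weights); unmatched weights are skipped with
    a logged count.
    """
    id_to_col = {v: i for i, v in enumerate(variants["id"].to_numpy())}
    cols, w = [], []
    n_skip = 0
    for vid, wt in zip(weights.variant_ids, weights.weights):
        col = id_to_col.get(vid)
        if col is None:
            n_skip += 1
            continue
        cols.append(col)
        w.append(wt)
    if n_skip:
        log.info("compute_pgs: %d weight variants not in cohort, skipped", n_skip)
    return np.asarray(cols, dtype=np.int64), np.asarray(w, dtype=float)


def compute_pgs(G, weights: PgsWeights, variants: pd.DataFrame) -> np.ndarray:
    """Uncentered weighted dosage sum per individual."""
    G = np.asarray(G, dtype=float)
    cols, w = match_weights(weights, variants)
    if cols.shape[0] == 0:
        return np.zeros(G.shape[0])
    return G[:, cols] @ w


def fit_reference_slope(
    Y, pgs, covariates=None, n_boot: int = 1000, seed=None, rng=None
) -> ReferenceSlope:
    """Slope of phenotype on PGS plus covariates, with percentile bootstrap.

    ``delta_r2`` is one minus the ratio of residual variance of the full
    model to the residual variance of the covariates-only model.
    """
    from ._utils import as_rng

    Y = np.asarray(Y, dtype=float).ravel()
    pgs = np.asarray(pgs, dtype=float).ravel()
    n = Y.shape[0]
    if np.var(pgs) <= 0:
        raise ValueError("zero-variance PGS")
    X0 = _design(n, covariates)
    if n <= X0.shape[1] + 2:
        raise ValueError("too few individuals for the covariate set")
    X = np.column_stack([X0, pgs])

    def _fit(yb, Xb, X0b):
        coef, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        res_full = yb - Xb @ coef
        coef0, _, _, _ = np.linalg.lstsq(X0b, yb, rcond=None)
        res_red = yb - X0b @ coef0
        sse_full = res_full @ res_full
        sse_red = res_red @ res_red
        dr2 = 0.0 if sse_red == 0 else 1.0 - sse_full / sse_red
        return coef[-1], dr2

    beta, dr2 = _fit(Y, X, X0)
    boot_beta = np.empty(n_boot)
    boot_dr2 = np.empty(n_boot)
    gen = as_rng(seed, rng)
    for b in range(n_boot):
        take = gen.integers(0, n, size=n)
        boot_beta[b], boot_dr2[b] = _fit(Y[take], X[take], X0[take])
    ci_b = tuple(np.percentile(boot_beta, [2.5, 97.5])) if n_boot else (np.nan, np.nan)
    ci_d = tuple(np.percentile(boot_dr2, [2.5, 97.5])) if n_boot else (np.nan, np.nan)
    return ReferenceSlope(
        beta=float(beta),
        delta_r2=float(dr2),
        ci_beta=ci_b,
        ci_delta_r2=ci_d,
        n=n,
        n_boot=n_boot,
        boot_beta=boot_beta,
    )


def attenuation_ratio(intercept: float, mean_chi2: float) -> float:
    """Stratification-inflation summary: (intercept - 1) / (mean chi2 - 1).

    Both inputs are floored at 1; the 0/0 case is reported as 0.
    """
    if not (np.isfinite(intercept) and np.isfinite(mean_chi2)):
        raise ValueError("inputs must be finite")
    num = max(float(intercept), 1.0) - 1.0
    den = max(float(mean_chi2), 1.0) - 1.0
    if num == 0.0:
        return 0.0
    if den == 0.0:
        return np.inf
    return num / den
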