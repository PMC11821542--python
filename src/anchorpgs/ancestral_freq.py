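"""Background-specific allele frequencies and mean-centered ancestry dosages.

Frequencies on the two ancestral backgrounds are estimated per site by
ordinary least squares of the genotype on the expected number of
European-background allele copies, then mapped to ``f_eu = slope +
intercept / 2`` and ``f_af = intercept / 2``.  Ancestry-specific dosages
are centered by subtracting the frequency times the expected copy count
on that background, which makes the combined centered dosage the OLS
residual (zero-sum per site when frequencies are fitted on the same
cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AncestralFrequencies",
    "fit_site_frequencies",
    "mean_center_dosages",
]

#: variance floor below which the per-site OLS is declared degenerate
DEGENERACY_TOL = 1e-8


@dataclass
class AncestralFrequencies:
    """Per-variant allele frequencies on the two ancestral backgrounds.

    Attributes
    ----------
    f_eu, f_af : ndarray
        Counted-allele frequency on the European / African background,
        clipped to [0, 1].
    slope, intercept : ndarray, optional
        Per-site fit diagnostics (``f_eu = slope + intercept/2``,
        ``f_af = intercept/2`` before clipping).
    predictor_var : ndarray, optional
        Variance of the European-copy predictor at each site.
    degenerate : ndarray of bool, optional
        Sites where the predictor variance fell below tolerance and the
        fallback ``f_eu = f_af = mean(G)/2`` was used.
    n_used : ndarray of int, optional
        Individuals contributing to each per-site fit.
    """

    f_eu: np.ndarray
    f_af: np.ndarray
    slope: np.ndarray | None = None
    intercept: np.ndarray | None = None
    predictor_var: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    n_used: np.ndarray | None = None
    clipped: np.ndarray | None = None

    def __post_init__(self):
        self.f_eu = np.atleast_1d(np.asarray(self.f_eu, dtype=float))
        self.f_af = np.atleast_1d(np.asarray(self.f_af, dtype=float))
        if self.f_eu.shape != self.f_af.shape:
            raise ValueError("f_eu and f_af must have the same shape")

    @property
    def n_variants(self) -> int:
        return self.f_eu.shape[0]

    def to_frame(self, variant_ids=None) -> pd.DataFrame:
        n = self.n_variants
        df = pd.DataFrame(
            {
                "variant": variant_ids if variant_ids is not None else np.arange(n),
                "f_eu": self.f_eu,
                "f_af": self.f_af,
                "n_used": self.n_used if self.n_used is not None else np.full(n, -1),
                "degenerate": (
                    self.degenerate if self.degenerate is not None else np.zeros(n, bool)
                ),
            }
        )
        return df


def fit_site_frequencies(genotypes, probs) -> AncestralFrequencies:
    """Estimate per-site background frequencies by per-site OLS.

    Parameters
    ----------
    genotypes : (n, m) array
        Dosages in [0, 2]; NaN marks missing (excluded pairwise).
    probs : DiploidAncestryProbs
        Local-ancestry state probabilities for the same individuals/sites.

    Returns
    -------
    AncestralFrequencies with fit diagnostics.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x variants) array")
    x = probs.eu_copies  # expected European-background allele copies, in [0, 2]
    if x.shape != G.shape:
        raise ValueError(
            f"dimension mismatch: genotypes {G.shape} vs ancestry probs {x.shape}"
        )
    n, m = G.shape
    if n < 2:
        raise ValueError("need at least 2 individuals to fit site frequencies")

    ok = ~np.isnan(G)
    n_used = ok.sum(axis=0)
    if np.any(n_used == 0):
        bad = int(np.flatnonzero(n_used == 0)[0])
        raise ValueError(f"site {bad} has no non-missing genotypes")

    Gz = np.where(ok, G, 0.0)
    xz = np.where(ok, x, 0.0)
    mean_g = Gz.sum(axis=0) / n_used
    mean_x = xz.sum(axis=0) / n_used
    # pairwise-complete second moments
    sxx = np.einsum("ij,ij->j", xz, xz) / n_used - mean_x**2
    sxg = np.einsum("ij,ij->j", xz, Gz) / n_used - mean_x * mean_g

    degenerate = sxx < DEGENERACY_TOL
    slope = np.where(degenerate, 0.0, sxg / np.where(degenerate, 1.0, sxx))
    intercept = mean_g - slope * mean_x

    f_eu = slope + intercept / 2.0
    f_af = intercept / 2.0
    # degenerate sites: no ancestry contrast, split the mean dosage evenly
    f_eu = np.where(degenerate, mean_g / 2.0, f_eu)
    f_af = np.where(degenerate, mean_g / 2.0, f_af)

    clipped = (f_eu < 0) | (f_eu > 1) | (f_af < 0) | (f_af > 1)
    return AncestralFrequencies(
        f_eu=np.clip(f_eu, 0.0, 1.0),
        f_af=np.clip(f_af, 0.0, 1.0),
        slope=slope,
        intercept=intercept,
        predictor_var=sxx,
        degenerate=degenerate,
        n_used=n_used,
        clipped=clipped,
    )


def mean_center_dosages(dosages, probs, freqs, mask=None):
    """Mean-center ancestry-specific dosages given background frequencies.

    ``centered_eu = G_eu - f_eu * E[# European allele copies]`` and
    analogously for the African background.  Masked sites are zeroed in
    both matrices so they contribute nothing to downstream scores.

    Returns
    -------
    (centered_eu, centered_af) : pair of (n, m) arrays
    """
    g_eu = np.asarray(dosages.g_eu, dtype=float)
    g_af = np.asarray(dosages.g_af, dtype=float)
    xe = probs.eu_copies
    xa = probs.af_copies
    f_eu = np.atleast_1d(np.asarray(freqs.f_eu, dtype=float))
    f_af = np.atleast_1d(np.asarray(freqs.f_af, dtype=float))
    if f_eu.shape[0] != g_eu.shape[1]:
        raise ValueError("frequency vector length does not match number of sites")

    if mask is None:
        mask = dosages.mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)

    nan_site = np.isnan(f_eu) | np.isnan(f_af)
    if np.any(nan_site):
        if mask is None or np.any(~mask[:, nan_site]):
            raise ValueError("missing frequency at an unmasked site")
        f_eu = np.nan_to_num(f_eu)
        f_af = np.nan_to_num(f_af)

    cen_eu = g_eu - f_eu[None, :] * xe
    cen_af = g_af - f_af[None, :] * xa
    if mask is not None:
        cen_eu = np.where(mask, 0.0, cen_eu)
        cen_af = np.where(mask, 0.0, cen_af)
    return cen_eu, cen_af
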