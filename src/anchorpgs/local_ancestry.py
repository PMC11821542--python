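"""Diploid local-ancestry state probabilities, ancestry dosages, masking.

The diploid state at a site is one of EE / EA / AE / AA ("E" European,
"A" African), with the two chromosomes ordered arbitrarily.  State
probabilities are built from per-haplotype European posteriors under an
independence approximation.  Ancestry-specific expected allele counts
split the genotype between the two backgrounds, and masking removes
uncertain sites and short runs of constant most-probable state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import check_probability

__all__ = [
    "DiploidAncestryProbs",
    "AncestryDosages",
    "diploid_state_probs",
    "expected_ancestry_dosages",
    "mask_segments",
]

STATES = ("EE", "EA", "AE", "AA")


@dataclass
class DiploidAncestryProbs:
    """Per-individual, per-site probabilities of the four diploid states.

    All four arrays are (n_individuals, n_sites) and sum to one at every
    entry (within 1e-8).
    """

    p_ee: np.ndarray
    p_ea: np.ndarray
    p_ae: np.ndarray
    p_aa: np.ndarray

    def __post_init__(self):
        arrs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in
                (self.p_ee, self.p_ea, self.p_ae, self.p_aa)]
        shape = arrs[0].shape
        for name, a in zip(STATES, arrs):
            if a.shape != shape:
                raise ValueError("all four state-probability arrays must share a shape")
            if np.any((a < -1e-12) | (a > 1 + 1e-12)):
                raise ValueError(f"P^{name} outside [0, 1]")
        total = arrs[0] + arrs[1] + arrs[2] + arrs[3]
        if np.any(np.abs(total - 1.0) > 1e-8):
            raise ValueError("diploid state probabilities must sum to 1 at every site")
        self.p_ee, self.p_ea, self.p_ae, self.p_aa = arrs

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_ee.shape

    @property
    def eu_copies(self) -> np.ndarray:
        """Expected number of European-background allele copies, in [0, 2].

        Equals ``2 P_EE + 2 P_EA`` whenever the heterogeneous states are
        symmetric (``P_EA == P_AE``); the symmetric form used here is
        additionally invariant to relabeling EA <-> AE.
        """
        return 2.0 * self.p_ee + self.p_ea + self.p_ae

    @property
    def af_copies(self) -> np.ndarray:
        """Expected number of African-background allele copies, in [0, 2]."""
        return 2.0 * self.p_aa + self.p_ea + self.p_ae

    def stacked(self) -> np.ndarray:
        """(n, m, 4) array in EE, EA, AE, AA order."""
        return np.stack([self.p_ee, self.p_ea, self.p_ae, self.p_aa], axis=-1)

    @classmethod
    def from_hap_posteriors(cls, hap1_eu, hap2_eu, symmetrize: bool = True):
        """Build diploid probabilities from two per-haplotype European posteriors.

        With ``symmetrize`` the two heterogeneous states are averaged,
        reflecting arbitrary chromosome ordering.
        """
        a = check_probability(hap1_eu, "hap1_eu")
        b = check_probability(hap2_eu, "hap2_eu")
        p_ee = a * b
        p_ea = a * (1.0 - b)
        p_ae = (1.0 - a) * b
        p_aa = (1.0 - a) * (1.0 - b)
        if symmetrize:
            het = 0.5 * (p_ea + p_ae)
            p_ea = p_ae = het
        return cls(p_ee=p_ee, p_ea=p_ea, p_ae=p_ae, p_aa=p_aa)

    def to_frame(self, samples, variants: pd.DataFrame) -> pd.DataFrame:
        """Long-format table: individual, chrom, pos, pEE, pEA, pAE, pAA."""
        n, m = self.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(np.asarray(samples), m),
                "chrom": np.tile(variants["chrom"].to_numpy(), n),
                "pos": np.tile(variants["pos"].to_numpy(), n),
                "pEE": self.p_ee.ravel(),
                "pEA": self.p_ea.ravel(),
                "pAE": self.p_ae.ravel(),
                "pAA": self.p_aa.ravel(),
            }
        )


@dataclass
class AncestryDosages:
    """Expected counted-allele counts on each background, plus a mask.

    ``g_eu + g_af`` equals the genotype wherever defined; ``mask`` is
    True at sites excluded from downstream analysis.
    """

    g_eu: np.ndarray
    g_af: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.g_eu = np.atleast_2d(np.asarray(self.g_eu, dtype=float))
        self.g_af = np.atleast_2d(np.asarray(self.g_af, dtype=float))
        if self.g_eu.shape != self.g_af.shape:
            raise ValueError("g_eu and g_af must share a shape")
        if self.mask is not None:
            self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
            if self.mask.shape != self.g_eu.shape:
                raise ValueError("mask shape mismatch")

    @property
    def genotype(self) -> np.ndarray:
        return self.g_eu + self.g_af


def diploid_state_probs(hap1_eu_prob, hap2_eu_prob) -> tuple:
    """Diploid state probabilities (EE, EA, AE, AA) for one entry or array.

    Independence approximation: ``P_EE = a*b``, ``P_EA = a*(1-b)``,
    ``P_AE = (1-a)*b``, ``P_AA = (1-a)*(1-b)``.
    """
    a = check_probability(hap1_eu_prob, "hap1_eu_prob")
    b = check_probability(hap2_eu_prob, "hap2_eu_prob")
    return a * b, a * (1.0 - b), (1.0 - a) * b, (1.0 - a) * (1.0 - b)


def expected_ancestry_dosages(hap1_allele, hap2_allele, hap1_eu, hap2_eu) -> AncestryDosages:
    """Split allele counts between backgrounds using haplotype posteriors.

    ``g_eu = h1*a1 + h2*a2`` and ``g_af = h1*(1-a1) + h2*(1-a2)``, so the
    two always add back to the genotype.
    """
    h1 = np.asarray(hap1_allele, dtype=float)
    h2 = np.asarray(hap2_allele, dtype=float)
    if np.any(~np.isin(h1[~np.isnan(h1)], (0.0, 1.0))) or np.any(
        ~np.isin(h2[~np.isnan(h2)], (0.0, 1.0))
    ):
        raise ValueError("haplotype alleles must be 0 or 1")
    a1 = check_probability(hap1_eu, "hap1_eu")
    a2 = check_probability(hap2_eu, "hap2_eu")
    g_eu = h1 * a1 + h2 * a2
    g_af = h1 * (1.0 - a1) + h2 * (1.0 - a2)
    return AncestryDosages(g_eu=g_eu, g_af=g_af)


def _run_bounds(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal runs of constant value."""
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.shape[0]]))
    return starts, ends


def mask_segments(
    probs: DiploidAncestryProbs,
    positions,
    chrom=None,
    min_length_bp: int = 5_000_000,
    min_posterior: float = 0.9,
) -> np.ndarray:
    """Mask uncertain sites and short runs of constant ancestry state.

    A site is masked when its maximal diploid-state posterior is below
    ``min_posterior``, or when it lies in a maximal run of identical
    most-probable state whose bp span is shorter than ``min_length_bp``.
    Runs never extend across chromosomes.  Sites must be sorted by
    (chrom, position).

    Returns
    -------
    (n, m) boolean matrix, True = masked.
    """
    positions = np.asarray(positions)
    n, m = probs.shape
    if positions.shape[0] != m:
        raise ValueError("positions length must match the number of sites")
    if chrom is None:
        chrom_codes = np.zeros(m, dtype=int)
    else:
        chrom_codes = pd.factorize(np.asarray(chrom))[0]
    order_key = chrom_codes.astype(np.int64) * (positions.max() + 2) + positions
    if np.any(np.diff(order_key) < 0):
        raise ValueError("sites must be sorted by (chrom, pos)")

    stacked = probs.stacked()
    best_state = stacked.argmax(axis=-1)
    best_post = stacked.max(axis=-1)
    mask = best_post < min_posterior

    chrom_starts, chrom_ends = _run_bounds(chrom_codes)
    for i in range(n):
        for cs, ce in zip(chrom_starts, chrom_ends):
            starts, ends = _run_bounds(best_state[i, cs:ce])
            for s, e in zip(starts, ends):
                span = positions[cs + e - 1] - positions[cs + s] + 1
                if span < min_length_bp:
                    mask[i, cs + s : cs + e] = True
    return mask
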