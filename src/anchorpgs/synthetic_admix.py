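"""Synthetic admixed cohorts with controllable cross-ancestry genetics.

Two ancestral populations diverge under a Balding-Nichols model; admixed
haplotypes are mosaics of ancestry tracts laid down by a Poisson switch
process along the genetic map.  Optional founder-haplotype copying in
fixed-size blocks induces background-specific linkage disequilibrium so
that tag-SNP scores are meaningful.  Phenotypes are additive with noise
calibrated to a target heritability, and effect sizes on the two
backgrounds can be given any correlation in [-1, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import as_rng
from .ancestral_freq import AncestralFrequencies

__all__ = [
    "SimulationConfig",
    "AdmixedCohort",
    "FounderPanel",
    "EffectSizes",
    "Phenotype",
    "CausalSet",
    "draw_ancestral_frequencies",
    "draw_founder_panel",
    "simulate_admixed_genomes",
    "select_causal_variants",
    "draw_effect_sizes",
    "simulate_phenotype",
    "scenario_grid",
    "hudson_fst",
]

# Global-ancestry mixture used by default: African-fraction bins with
# occupancies matching a large admixed biobank subset; theta is drawn
# uniformly within the selected bin.
DEFAULT_THETA_BINS = (
    "bins",
    (0.1, 0.35, 0.55, 0.78, 0.95, 1.0),
    (373, 560, 475, 2556, 4039),
)

CAUSAL_COUNTS = (100, 1_000, 10_000)
PLACEMENTS = ("uniform", "clustered")
EFFECT_DISTS = ("normal", "frequency_scaled")
HERITABILITIES = (0.3, 0.6)

CLUSTER_REGION_BP = 10_000


@dataclass
class SimulationConfig:
    """Full description of one simulation scenario."""

    n_individuals: int
    n_variants: int
    n_causal: int
    seed: int
    placement: str = "uniform"
    effect_dist: str = "normal"
    h2: float = 0.6
    rho: float = 1.0
    fst: float = 0.15
    admix_generations: float = 10.0
    theta_distribution: tuple = DEFAULT_THETA_BINS
    genetic_map: np.ndarray | None = None
    chrom_length_bp: int = 100_000_000
    cm_per_mb: float = 1.0
    n_founders: int = 0
    ld_block_kb: float = 50.0
    ancestry_error_rate: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        if self.effect_dist not in EFFECT_DISTS:
            raise ValueError(f"effect_dist must be one of {EFFECT_DISTS}")
        if self.genetic_map is not None:
            gm = np.asarray(self.genetic_map, dtype=float)
            if gm.ndim != 1 or gm.shape[0] != self.n_variants:
                raise ValueError("genetic_map must be one cM value per variant")
            if np.any(np.diff(gm) < 0):
                raise ValueError("genetic_map cM positions must be nondecreasing")
            self.genetic_map = gm


@dataclass
class AdmixedCohort:
    """Phased genotypes with a truth (or blurred) local-ancestry track.

    ``haplotypes`` is (n, 2, m) in {0, 1}; ``hap_ancestry`` holds the
    per-haplotype European posterior (1 = European); ``theta`` is each
    individual's global African-ancestry fraction.
    """

    haplotypes: np.ndarray
    hap_ancestry: np.ndarray
    theta: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            self.samples = [f"ind{i:05d}" for i in range(self.n_individuals)]
        dup = self.variants.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("variant table not unique on (chrom, pos)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def genotypes(self) -> np.ndarray:
        """(n, m) dosage matrix: sum of the two haplotype alleles."""
        return self.haplotypes.sum(axis=1).astype(np.float64)


@dataclass
class FounderPanel:
    """Per-population founder haplotypes used for block-copy LD.

    ``haplotypes[pop]`` is (n_founders, m), pop 0 = European, 1 = African;
    ``block_id`` assigns each variant to a copying block.
    """

    haplotypes: np.ndarray
    block_id: np.ndarray


@dataclass
class CausalSet:
    """Causal-variant indices plus, in clustered mode, the region spans."""

    indices: np.ndarray
    regions: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.indices.shape[0]

    def __iter__(self):
        return iter(self.indices)


@dataclass
class EffectSizes:
    """Per-causal-variant effects on the two backgrounds."""

    indices: np.ndarray
    gamma_eu: np.ndarray
    gamma_af: np.ndarray


@dataclass
class Phenotype:
    """Simulated trait values together with the genetic component."""

    values: np.ndarray
    genetic_values: np.ndarray
    noise_sd: float

    @property
    def realized_h2(self) -> float:
        return float(np.var(self.genetic_values) / np.var(self.values))


def hudson_fst(f1, f2) -> float:
    """Hudson estimator of FST from two vectors of population frequencies."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    # ratio-of-averages form on parametric frequencies (no sample-size terms)
    num = (f1 - f2) ** 2
    den = f1 * (1 - f2) + f2 * (1 - f1)
    return float(num.mean() / den.mean())


def draw_ancestral_frequencies(
    n_variants: int,
    fst: float,
    seed=None,
    rng=None,
    ancestral_low: float = 0.05,
    ancestral_high: float = 0.95,
    clip: tuple[float, float] = (0.01, 0.99),
) -> AncestralFrequencies:
    """Balding-Nichols frequencies for the two ancestral populations.

    A shared ancestral frequency is drawn Uniform(ancestral_low,
    ancestral_high); each population's frequency is then Beta-distributed
    around it with dispersion set by ``fst``, and clipped away from 0/1.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = as_rng(seed, rng)
    p = rng.uniform(ancestral_low, ancestral_high, size=n_variants)
    if fst == 0.0:
        f_eu = f_af = p.copy()
    else:
        a = p * (1.0 - fst) / fst
        b = (1.0 - p) * (1.0 - fst) / fst
        f_eu = rng.beta(a, b)
        f_af = rng.beta(a, b)
    lo, hi = clip
    return AncestralFrequencies(
        f_eu=np.clip(f_eu, lo, hi), f_af=np.clip(f_af, lo, hi)
    )


def default_variant_table(
    n_variants: int, chrom_length_bp: int, rng, chrom: str = "1", cm_per_mb: float = 1.0
) -> pd.DataFrame:
    """Random sorted variant positions on one chromosome with a linear map."""
    if n_variants > chrom_length_bp - 1:
        raise ValueError("chromosome too short for the requested variant count")
    pos = np.sort(
        rng.choice(np.int64(chrom_length_bp - 1), size=n_variants, replace=False) + 1
    )
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "cm": pos * 1e-6 * cm_per_mb,
            "ref": "A",
            "alt": "G",
            "id": [f"1:{p}:A:G" for p in pos],
        }
    )


def draw_theta(theta_distribution, n: int, rng) -> np.ndarray:
    """Sample global African-ancestry fractions from a distribution spec.

    Specs: ``("fixed", v)``, ``("uniform", lo, hi)``, ``("beta", a, b)``
    or ``("bins", edges, weights)`` (bin chosen by weight, uniform within).
    """
    kind = theta_distribution[0]
    if kind == "fixed":
        theta = np.full(n, float(theta_distribution[1]))
    elif kind == "uniform":
        lo, hi = float(theta_distribution[1]), float(theta_distribution[2])
        theta = rng.uniform(lo, hi, size=n)
    elif kind == "beta":
        theta = rng.beta(float(theta_distribution[1]), float(theta_distribution[2]), size=n)
    elif kind == "bins":
        edges = np.asarray(theta_distribution[1], dtype=float)
        weights = np.asarray(theta_distribution[2], dtype=float)
        if edges.shape[0] != weights.shape[0] + 1:
            raise ValueError("bins spec needs len(edges) == len(weights) + 1")
        probs = weights / weights.sum()
        which = rng.choice(weights.shape[0], size=n, p=probs)
        theta = rng.uniform(edges[which], edges[which + 1])
    else:
        raise ValueError(f"unknown theta distribution kind {kind!r}")
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta values must lie in [0, 1]")
    return theta


def draw_founder_panel(
    freqs: AncestralFrequencies,
    positions,
    n_founders: int,
    block_kb: float = 50.0,
    seed=None,
    rng=None,
) -> FounderPanel:
    """Draw founder haplotypes per population for block-copy LD.

    Founder alleles are Bernoulli(population frequency) per site; copying
    whole 1-founder blocks into sample haplotypes induces within-block
    correlation that differs between the two backgrounds.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders per population")
    rng = as_rng(seed, rng)
    positions = np.asarray(positions, dtype=np.int64)
    m = positions.shape[0]
    haps = np.empty((2, n_founders, m), dtype=np.int8)
    for pop, f in enumerate((freqs.f_eu, freqs.f_af)):
        haps[pop] = (rng.random((n_founders, m)) < f[None, :]).astype(np.int8)
    block_id = positions // int(block_kb * 1000)
    return FounderPanel(haplotypes=haps, block_id=np.asarray(block_id))


def simulate_tracts(rng, length_cm: float, generations: float, theta: float):
    """Ancestry tract boundaries (cM) and per-tract ancestry for one haplotype.

    Switch points follow a Poisson process at ``generations`` per Morgan;
    each tract is African (code 1) independently with probability theta.

    Returns
    -------
    boundaries : ndarray, increasing cM positions of tract ends
        (the last equals ``length_cm``).
    ancestries : ndarray of {0, 1}, one per tract (0 = European).
    """
    if length_cm <= 0:
        raise ValueError("chromosome has zero genetic length")
    mean_tract_cm = 100.0 / generations if generations > 0 else np.inf
    bounds = []
    pos = 0.0
    while True:
        pos += rng.exponential(mean_tract_cm) if np.isfinite(mean_tract_cm) else np.inf
        if pos >= length_cm:
            break
        bounds.append(pos)
    boundaries = np.asarray(bounds + [length_cm])
    ancestries = (rng.random(boundaries.shape[0]) < theta).astype(np.int8)
    return boundaries, ancestries


def _hap_alleles(rng, anc: np.ndarray, freqs, founders: FounderPanel | None):
    """Alleles for one haplotype given its per-variant ancestry codes."""
    m = anc.shape[0]
    if founders is None:
        f = np.where(anc == 0, freqs.f_eu, freqs.f_af)
        return (rng.random(m) < f).astype(np.int8)
    # copy a random founder of the matching population within each maximal
    # run of constant (block, tract ancestry)
    seg_key = founders.block_id * 2 + anc
    change = np.flatnonzero(seg_key[1:] != seg_key[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [m]))
    n_f = founders.haplotypes.shape[1]
    choice = rng.integers(0, n_f, size=starts.shape[0])
    alleles = np.empty(m, dtype=np.int8)
    for s, e, c in zip(starts, ends, choice):
        alleles[s:e] = founders.haplotypes[anc[s], c, s:e]
    return alleles


def simulate_admixed_genomes(
    config: SimulationConfig,
    freqs: AncestralFrequencies,
    founders: FounderPanel | None = None,
    rng=None,
    variants: pd.DataFrame | None = None,
) -> AdmixedCohort:
    """Simulate phased mosaic genomes for an admixed cohort.

    Tracts switch ancestry as a Poisson process at ``admix_generations``
    per Morgan; tract ancestry is African with probability theta_i; the
    haplotype's alleles come from the tract's background (i.i.d. draws, or
    founder-block copies when ``founders`` is given).  ``hap_ancestry``
    records the truth track, optionally blurred by
    ``config.ancestry_error_rate``.
    """
    if freqs.n_variants != config.n_variants:
        raise ValueError("frequencies do not cover the configured variant count")
    rng = as_rng(config.seed, rng)
    if variants is None:
        if config.genetic_map is not None:
            gm = np.asarray(config.genetic_map, dtype=float)
            pos = np.round(gm * 1e6 / config.cm_per_mb).astype(np.int64)
            pos = np.maximum.accumulate(np.maximum(pos, 1))
            while np.any(np.diff(pos) == 0):  # bump rounding collisions
                pos[np.concatenate(([False], np.diff(pos) == 0))] += 1
                pos = np.maximum.accumulate(pos)
            variants = pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": pos,
                    "cm": gm,
                    "ref": "A",
                    "alt": "G",
                    "id": [f"1:{p}:A:G" for p in pos],
                }
            )
            if variants.duplicated(subset=["chrom", "pos"]).any():
                raise ValueError("genetic map induces duplicate bp positions")
        else:
            variants = default_variant_table(
                config.n_variants, config.chrom_length_bp, rng, cm_per_mb=config.cm_per_mb
            )
    cm = variants["cm"].to_numpy(dtype=float)
    if cm.shape[0] == 0:
        raise ValueError("empty genetic map")
    length_cm = float(cm[-1] - cm[0]) + 1e-9

    theta = draw_theta(config.theta_distribution, config.n_individuals, rng)

    n, m = config.n_individuals, config.n_variants
    haplotypes = np.empty((n, 2, m), dtype=np.int8)
    hap_anc_code = np.empty((n, 2, m), dtype=np.int8)
    rel_cm = cm - cm[0]
    for i in range(n):
        for h in range(2):
            if theta[i] == 0.0:
                anc = np.zeros(m, dtype=np.int8)
            elif theta[i] == 1.0:
                anc = np.ones(m, dtype=np.int8)
            else:
                bounds, tract_anc = simulate_tracts(
                    rng, length_cm, config.admix_generations, theta[i]
                )
                anc = tract_anc[np.searchsorted(bounds, rel_cm, side="right").clip(
                    max=tract_anc.shape[0] - 1
                )]
            hap_anc_code[i, h] = anc
            haplotypes[i, h] = _hap_alleles(rng, anc, freqs, founders)

    eu_post = 1.0 - hap_anc_code.astype(np.float64)
    e = float(config.ancestry_error_rate)
    if e > 0:
        eu_post = eu_post * (1.0 - e) + (1.0 - eu_post) * e
    return AdmixedCohort(
        haplotypes=haplotypes, hap_ancestry=eu_post, theta=theta, variants=variants
    )


def select_causal_variants(config: SimulationConfig, variant_table, rng=None) -> CausalSet:
    """Choose causal-variant indices uniformly or in clustered regions.

    Clustered mode designates ``J/10`` nonoverlapping 10-kb regions,
    spreads ``J/2`` causal variants over them by a symmetric multinomial,
    and places the remaining half uniformly outside the regions.
    """
    rng = as_rng(config.seed + 1 if rng is None else None, rng)
    pos = np.asarray(variant_table["pos"], dtype=np.int64)
    m = pos.shape[0]
    j = int(config.n_causal)
    if j > m:
        raise ValueError("n_causal exceeds available variants")
    if j == 0:
        return CausalSet(indices=np.empty(0, dtype=np.int64))
    if config.placement == "uniform":
        idx = np.sort(rng.choice(m, size=j, replace=False))
        return CausalSet(indices=idx)

    n_regions = max(j // 10, 1)
    n_clustered = j // 2
    # pick nonoverlapping windows anchored at random variants
    anchors = rng.permutation(m)
    regions: list[tuple[int, int]] = []
    taken: list[tuple[int, int]] = []
    for a in anchors:
        start = int(pos[a])
        end = start + CLUSTER_REGION_BP
        if any(start < e and end > s for s, e in taken):
            continue
        taken.append((start, end))
        regions.append((start, end))
        if len(regions) == n_regions:
            break
    if len(regions) < n_regions:
        raise ValueError(
            f"could not place {n_regions} nonoverlapping {CLUSTER_REGION_BP//1000}-kb "
            f"regions: only {len(regions)} available"
        )
    region_members = [
        np.flatnonzero((pos >= s) & (pos < e)) for s, e in regions
    ]
    capacity = np.array([r.shape[0] for r in region_members])
    if capacity.sum() < n_clustered:
        raise ValueError(
            f"designated regions contain {int(capacity.sum())} variants; "
            f"{n_clustered} clustered causal variants requested"
        )
    counts = rng.multinomial(n_clustered, np.full(n_regions, 1.0 / n_regions))
    # redistribute overflow from regions with too few variants
    overflow = int(np.maximum(counts - capacity, 0).sum())
    counts = np.minimum(counts, capacity)
    while overflow > 0:
        spare = np.flatnonzero(counts < capacity)
        pick = rng.choice(spare)
        counts[pick] += 1
        overflow -= 1
    chosen = [
        rng.choice(members, size=c, replace=False)
        for members, c in zip(region_members, counts)
        if c > 0
    ]
    clustered_idx = (
        np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
    )
    in_region = np.zeros(m, dtype=bool)
    for members in region_members:
        in_region[members] = True
    outside = np.flatnonzero(~in_region)
    n_uniform = j - n_clustered
    if outside.shape[0] < n_uniform:
        raise ValueError(
            f"only {outside.shape[0]} variants outside clustered regions; "
            f"{n_uniform} uniform causal variants requested"
        )
    uniform_idx = rng.choice(outside, size=n_uniform, replace=False)
    idx = np.sort(np.concatenate([clustered_idx, uniform_idx]).astype(np.int64))
    return CausalSet(indices=idx, regions=regions)


def draw_effect_sizes(
    causal,
    freqs: AncestralFrequencies,
    effect_dist: str = "normal",
    rho: float = 1.0,
    seed=None,
    rng=None,
    scaling_exponent: float = -0.25,
    scaling_background: str = "european",
) -> EffectSizes:
    """Draw correlated per-copy effects for the two backgrounds.

    European effects are N(0, sigma_j^2) with sigma_j = 1 (``normal``) or
    sigma_j = [2 p_j (1 - p_j)]^scaling_exponent (``frequency_scaled``);
    African effects are rho * gamma_eu + sigma_j * sqrt(1 - rho^2) * Z so
    that they are marginally N(0, sigma_j^2) with correlation rho.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = as_rng(seed, rng)
    indices = np.asarray(
        causal.indices if isinstance(causal, CausalSet) else causal, dtype=np.int64
    )
    j = indices.shape[0]
    if effect_dist == "normal":
        sigma = np.ones(j)
    elif effect_dist == "frequency_scaled":
        p = (freqs.f_eu if scaling_background == "european" else freqs.f_af)[indices]
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("frequency scaling undefined at p in {0, 1}")
        sigma = (2.0 * p * (1.0 - p)) ** scaling_exponent
    else:
        raise ValueError(f"unknown effect_dist {effect_dist!r}")
    gamma_eu = sigma * rng.standard_normal(j)
    gamma_af = rho * gamma_eu + sigma * np.sqrt(1.0 - rho**2) * rng.standard_normal(j)
    return EffectSizes(indices=indices, gamma_eu=gamma_eu, gamma_af=gamma_af)


def simulate_phenotype(
    cohort: AdmixedCohort,
    effects: EffectSizes,
    h2: float,
    ancestry_specific: bool = False,
    effect_mode: str = "group",
    seed=None,
    rng=None,
) -> Phenotype:
    """Additive phenotype with noise calibrated to the target heritability.

    The noise variance is set to ``(1 - h2) / h2`` times the observed
    variance of the genetic term of this cohort, so the configured
    heritability is maintained for the group being simulated.  With
    ``ancestry_specific``, ``effect_mode`` selects how African-background
    effects enter: ``"group"`` applies gamma_af to every allele copy of
    this (admixed) cohort, ``"tract"`` applies gamma_eu / gamma_af per
    copy according to the haplotype's local ancestry.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    rng = as_rng(seed, rng)
    idx = effects.indices
    G = cohort.genotypes[:, idx]
    if not ancestry_specific:
        genetic = G @ effects.gamma_eu
    elif effect_mode == "group":
        genetic = G @ effects.gamma_af
    elif effect_mode == "tract":
        anc_eu = np.rint(cohort.hap_ancestry[:, :, idx])  # truth: 1 = European copy
        hap = cohort.haplotypes[:, :, idx].astype(np.float64)
        eu_copies = (hap * anc_eu).sum(axis=1)
        af_copies = (hap * (1.0 - anc_eu)).sum(axis=1)
        genetic = eu_copies @ effects.gamma_eu + af_copies @ effects.gamma_af
    else:
        raise ValueError(f"unknown effect_mode {effect_mode!r}")
    sigma_g2 = float(np.var(genetic))
    if sigma_g2 <= 0.0:
        raise ValueError(
            "genetic variance is zero (no polymorphic causal variant with a "
            "nonzero effect); cannot calibrate heritability"
        )
    sigma_e2 = (1.0 - h2) / h2 * sigma_g2
    noise_sd = float(np.sqrt(sigma_e2))
    y = genetic + rng.normal(0.0, noise_sd, size=genetic.shape[0]) if noise_sd > 0 else genetic.copy()
    return Phenotype(values=y, genetic_values=genetic, noise_sd=noise_sd)


def scenario_grid(
    n_individuals: int = 2_000,
    n_variants: int = 20_000,
    seed: int = 0,
    **overrides,
) -> list[SimulationConfig]:
    """Full factorial of the simulation study: 3 x 2 x 2 x 2 = 24 scenarios."""
    configs = []
    for k, (j, placement, dist, h2) in enumerate(
        itertools.product(CAUSAL_COUNTS, PLACEMENTS, EFFECT_DISTS, HERITABILITIES)
    ):
        scaling = "0.5" if dist == "frequency_scaled" else "0"
        mode = "clustered" if placement == "clustered" else "uniform"
        label = f"#causal:{j}({mode})S:{scaling} h2:{h2}"
        configs.append(
            SimulationConfig(
                n_individuals=n_individuals,
                n_variants=n_variants,
                n_causal=j,
                placement=placement,
                effect_dist=dist,
                h2=h2,
                seed=seed + k,
                label=label,
                **overrides,
            )
        )
    return configs
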