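"""End-to-end glue: simulate cohorts, run GWAS -> clump -> decompose -> fit.

The standard experiment simulates three cohorts from one founder panel so
linkage structure is shared where it should be: a European training
cohort (GWAS), a European test cohort (reference phenotype-on-PGS
slope), and an admixed cohort (decomposed-score fit).  Traits are then
layered on top: each trait redraws causal variants and effects, builds a
tag-SNP score from clumped GWAS hits, and estimates the cross-ancestry
effect-size correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng
from . import synthetic_admix as sim
from .local_ancestry import (
    DiploidAncestryProbs,
    expected_ancestry_dosages,
    mask_segments,
)
from .ancestral_freq import fit_site_frequencies, mean_center_dosages
from .pgs_engine import (
    compute_pgs,
    fit_reference_slope,
    ld_clump,
    run_gwas,
)
from .anchor_core import bootstrap_fit, decompose_pgs, estimate_rho, fit_anchor

log = logging.getLogger(__name__)

#: desk-scale calibration-study cohort layout: admixed target cohort,
#: European training cohort for the GWAS, European test cohort for the
#: reference slope; strong founder-block LD so tag-SNP scores carry signal
DESK_EXPERIMENT = dict(
    n_admixed=2_000,
    n_train=5_000,
    n_ref=2_000,
    n_variants=5_000,
    fst=0.15,
    n_founders=4,
    theta_distribution=("uniform", 0.1, 0.9),
)


@dataclass
class ExperimentCohorts:
    """Simulated cohorts plus precomputed centering shared across traits."""

    freqs: object
    founders: object
    variants: pd.DataFrame
    train: sim.AdmixedCohort
    ref_test: sim.AdmixedCohort
    admixed: sim.AdmixedCohort
    probs: DiploidAncestryProbs
    mask: np.ndarray
    site_freqs: object
    centered_eu: np.ndarray
    centered_af: np.ndarray


@dataclass
class TraitResult:
    """Per-trait pipeline outputs."""

    fit: object
    reference: object
    rho: object
    n_weights: int
    effects: sim.EffectSizes
    weights: object = None
    y_admixed: np.ndarray | None = None


def build_experiment(
    n_admixed: int = 2_000,
    n_train: int = 5_000,
    n_ref: int = 2_000,
    n_variants: int = 5_000,
    fst: float = 0.15,
    seed: int = 0,
    n_founders: int = 20,
    generations: float = 10.0,
    chrom_length_bp: int = 50_000_000,
    theta_distribution=sim.DEFAULT_THETA_BINS,
    mask_min_length_bp: int = 5_000_000,
) -> ExperimentCohorts:
    """Simulate the three cohorts and precompute admixed-cohort centering."""
    rng = as_rng(seed)
    freqs = sim.draw_ancestral_frequencies(n_variants, fst, rng=rng)
    variants = sim.default_variant_table(n_variants, chrom_length_bp, rng)
    founders = sim.draw_founder_panel(
        freqs, variants["pos"].to_numpy(), n_founders, rng=rng
    )

    def _cohort(n, theta_dist):
        cfg = sim.SimulationConfig(
            n_individuals=n,
            n_variants=n_variants,
            n_causal=0,
            seed=seed,
            fst=fst,
            admix_generations=generations,
            theta_distribution=theta_dist,
            chrom_length_bp=chrom_length_bp,
        )
        return sim.simulate_admixed_genomes(
            cfg, freqs, founders=founders, rng=rng, variants=variants
        )

    train = _cohort(n_train, ("fixed", 0.0))
    ref_test = _cohort(n_ref, ("fixed", 0.0))
    admixed = _cohort(n_admixed, theta_distribution)

    probs = DiploidAncestryProbs.from_hap_posteriors(
        admixed.hap_ancestry[:, 0, :], admixed.hap_ancestry[:, 1, :]
    )
    mask = mask_segments(
        probs,
        positions=variants["pos"].to_numpy(),
        chrom=variants["chrom"].to_numpy(),
        min_length_bp=mask_min_length_bp,
    )
    site_freqs = fit_site_frequencies(admixed.genotypes, probs)
    dosages = expected_ancestry_dosages(
        admixed.haplotypes[:, 0, :],
        admixed.haplotypes[:, 1, :],
        admixed.hap_ancestry[:, 0, :],
        admixed.hap_ancestry[:, 1, :],
    )
    centered_eu, centered_af = mean_center_dosages(
        dosages, probs, site_freqs, mask=mask
    )
    return ExperimentCohorts(
        freqs=freqs,
        founders=founders,
        variants=variants,
        train=train,
        ref_test=ref_test,
        admixed=admixed,
        probs=probs,
        mask=mask,
        site_freqs=site_freqs,
        centered_eu=centered_eu,
        centered_af=centered_af,
    )


def run_trait(
    cohorts: ExperimentCohorts,
    n_causal: int = 500,
    rho: float = 1.0,
    h2: float = 0.6,
    effect_dist: str = "normal",
    placement: str = "uniform",
    seed: int = 0,
    n_boot: int = 200,
    p1: float = 0.05,
    r2: float = 0.1,
    window_kb: float = 500.0,
    exclude_causal: bool = True,
    omega_mode: str = "fixed_zero",
) -> TraitResult:
    """Simulate one trait and push it through the full estimation pipeline.

    With ``exclude_causal`` the causal variants cannot become clump
    indices, so the score is built purely from tag SNPs (the regime in
    which local LD differences attenuate cross-ancestry prediction).
    """
    rng = as_rng(seed)
    variants = cohorts.variants
    cfg = sim.SimulationConfig(
        n_individuals=cohorts.train.n_individuals,
        n_variants=len(variants),
        n_causal=n_causal,
        placement=placement,
        effect_dist=effect_dist,
        h2=h2,
        rho=rho,
        seed=seed,
    )
    causal = sim.select_causal_variants(cfg, variants, rng=rng)
    effects = sim.draw_effect_sizes(
        causal, cohorts.freqs, effect_dist=effect_dist, rho=rho, rng=rng
    )

    y_train = sim.simulate_phenotype(cohorts.train, effects, h2, rng=rng).values
    y_ref = sim.simulate_phenotype(cohorts.ref_test, effects, h2, rng=rng).values
    y_adm = sim.simulate_phenotype(
        cohorts.admixed, effects, h2, ancestry_specific=True, rng=rng
    ).values

    gwas = run_gwas(cohorts.train.genotypes, y_train)
    candidates = None
    if exclude_causal:
        candidates = np.setdiff1d(np.arange(len(variants)), effects.indices)
    weights = ld_clump(
        gwas,
        cohorts.train.genotypes,
        variants,
        p1=p1,
        r2=r2,
        window_kb=window_kb,
        candidates=candidates,
    )
    if len(weights) == 0:
        raise RuntimeError("clumping produced an empty weight set")

    pgs_ref = compute_pgs(cohorts.ref_test.genotypes, weights, variants)
    reference = fit_reference_slope(y_ref, pgs_ref, n_boot=n_boot, rng=rng)

    scores = decompose_pgs(
        cohorts.centered_eu,
        cohorts.centered_af,
        weights,
        variants,
        theta=cohorts.admixed.theta,
    )
    if n_boot:
        fit = bootstrap_fit(y_adm, scores, omega_mode, n_boot=n_boot, rng=rng)
    else:
        fit = fit_anchor(y_adm, scores, omega_mode)
    rho_est = estimate_rho(fit, reference)
    return TraitResult(
        fit=fit, reference=reference, rho=rho_est, n_weights=len(weights),
        effects=effects, weights=weights, y_admixed=y_adm,
    )


def uncentered_rho(cohorts: ExperimentCohorts, trait: TraitResult) -> float:
    """Re-estimate rho with mean-centering disabled (raw ancestry dosages).

    Used as a regression check: without centering the estimate is
    downward biased on null (shared-effect) traits.
    """
    dos = expected_ancestry_dosages(
        cohorts.admixed.haplotypes[:, 0, :],
        cohorts.admixed.haplotypes[:, 1, :],
        cohorts.admixed.hap_ancestry[:, 0, :],
        cohorts.admixed.hap_ancestry[:, 1, :],
    )
    g_eu = np.where(cohorts.mask, 0.0, dos.g_eu)
    g_af = np.where(cohorts.mask, 0.0, dos.g_af)
    scores = decompose_pgs(
        g_eu, g_af, trait.weights, cohorts.variants, theta=cohorts.admixed.theta
    )
    fit = fit_anchor(trait.y_admixed, scores, "fixed_zero")
    return estimate_rho(fit, trait.reference).rho


def null_calibration_study(
    n_traits: int = 50,
    seed: int = 0,
    n_boot: int = 200,
    n_causal: int = 100,
    h2: float = 0.6,
    with_uncentered: bool = False,
    cohorts: ExperimentCohorts | None = None,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Shared-effect (rho = 1) traits through the full pipeline.

    Returns one row per trait with the rho estimate, its bootstrap CI,
    whether the CI covers 1, and the local (African-segment) ratio.
    """
    if cohorts is None:
        cohorts = build_experiment(seed=seed, **{**DESK_EXPERIMENT, **experiment_kwargs})
    rows = []
    for t in range(n_traits):
        tr = run_trait(
            cohorts, n_causal=n_causal, rho=1.0, h2=h2,
            seed=seed + 1000 + t, n_boot=n_boot,
        )
        lo, hi = tr.rho.ci.get("rho", (np.nan, np.nan))
        row = {
            "trait": t,
            "rho": tr.rho.rho,
            "ci_lo": lo,
            "ci_hi": hi,
            "covered": bool(lo <= 1.0 <= hi),
            "local_ratio": tr.rho.local_ratio,
            "beta_eu": tr.fit.beta_eu,
            "beta_obs_eu": tr.reference.beta,
            "delta_r2": tr.reference.delta_r2,
            "n_weights": tr.n_weights,
        }
        if with_uncentered:
            row["rho_uncentered"] = uncentered_rho(cohorts, tr)
        rows.append(row)
        log.info(
            "null trait %d/%d: rho=%.3f CI=(%.3f, %.3f)", t + 1, n_traits,
            row["rho"], lo, hi,
        )
    return pd.DataFrame(rows)


def rho_recovery_study(
    rho: float = 0.5,
    n_replicates: int = 20,
    seed: int = 0,
    n_causal: int = 100,
    h2: float = 0.6,
    cohorts: ExperimentCohorts | None = None,
    **experiment_kwargs,
) -> pd.DataFrame:
    """Replicate traits at a fixed generating effect-size correlation."""
    if cohorts is None:
        cohorts = build_experiment(seed=seed, **{**DESK_EXPERIMENT, **experiment_kwargs})
    rows = []
    for t in range(n_replicates):
        tr = run_trait(
            cohorts, n_causal=n_causal, rho=rho, h2=h2,
            seed=seed + 5000 + t, n_boot=0,
        )
        rows.append({"replicate": t, "rho_true": rho, "rho": tr.rho.rho})
        log.info("rho=%.1f replicate %d/%d: rho_hat=%.3f", rho, t + 1,
                 n_replicates, tr.rho.rho)
    return pd.DataFrame(rows)


def heritability_check(
    n_individuals: int = 50_000,
    n_variants: int = 500,
    n_causal: int = 250,
    h2: float = 0.6,
    seed: int = 0,
) -> float:
    """Realized var(genetic) / var(phenotype) on a large simulated cohort."""
    cfg = sim.SimulationConfig(
        n_individuals=n_individuals, n_variants=n_variants, n_causal=n_causal,
        h2=h2, seed=seed, theta_distribution=("uniform", 0.0, 1.0),
    )
    rng = as_rng(seed)
    freqs = sim.draw_ancestral_frequencies(n_variants, cfg.fst, rng=rng)
    cohort = sim.simulate_admixed_genomes(cfg, freqs, rng=rng)
    causal = sim.select_causal_variants(cfg, cohort.variants, rng=rng)
    effects = sim.draw_effect_sizes(causal, freqs, rho=1.0, rng=rng)
    phe = sim.simulate_phenotype(cohort, effects, h2=h2, rng=rng)
    return phe.realized_h2
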