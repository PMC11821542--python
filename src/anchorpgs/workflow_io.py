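"""File formats and cohort-bundle assembly.

Formats: plain-text VCF with phased GT for genotypes; headered TSVs for
local-ancestry probabilities (long format: individual, chrom, pos, pEE,
pEA, pAE, pAA), samples (individual, theta_af, phenotype columns), PGS
weights, GWAS summaries and background frequencies; JSON for fit
reports.  Coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd
import yaml

from .local_ancestry import DiploidAncestryProbs
from .pgs_engine import PgsWeights
from .synthetic_admix import AdmixedCohort, SimulationConfig

__all__ = [
    "CohortBundle",
    "write_vcf",
    "read_vcf",
    "write_ancestry_tsv",
    "read_ancestry_tsv",
    "read_ancestry_probs_tsv",
    "read_hap_posterior_tsv",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_weights_tsv",
    "read_weights_tsv",
    "load_cohort_bundle",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "write_cohort_bundle",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _tool_version() -> str:
    try:
        return _pkg_version("anchorpgs")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class CohortBundle:
    """Aligned in-memory cohort: genotypes, ancestry, samples, weights."""

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    probs: DiploidAncestryProbs | None = None
    sample_table: pd.DataFrame | None = None
    weights: PgsWeights | None = None
    haplotypes: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray | None:
        if self.sample_table is not None and "theta_af" in self.sample_table:
            return self.sample_table["theta_af"].to_numpy(dtype=float)
        return None


# ---------------------------------------------------------------------------
# VCF

def write_vcf(cohort: AdmixedCohort, path) -> None:
    """Write phased genotypes as a plain-text VCF (GT only)."""
    v = cohort.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=anchorpgs {_tool_version()}\n")
        for chrom in pd.unique(v["chrom"]):
            maxpos = int(v.loc[v["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        hap = cohort.haplotypes
        for j in range(cohort.n_variants):
            row = v.iloc[j]
            gts = "\t".join(
                f"{hap[i, 0, j]}|{hap[i, 1, j]}" for i in range(cohort.n_individuals)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (haplotypes, genotypes, variants, samples).

    The ALT allele is the counted allele.  Unphased genotypes are
    accepted; missing calls ('.') become NaN dosages.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    haps, rows = [], []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "cm": rec.POS * 1e-6,
                "ref": rec.REF,
                "alt": alt,
                "id": rec.ID if rec.ID not in (None, ".") else
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}",
            }
        )
        pair = np.array([[g[0], g[1]] for g in rec.genotypes], dtype=float)
        pair[pair < 0] = np.nan
        haps.append(pair)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    hap = np.stack(haps, axis=-1)  # (n, 2, m)
    geno = hap.sum(axis=1)
    variants = pd.DataFrame(rows)
    return hap, geno, variants, samples


# ---------------------------------------------------------------------------
# TSVs

def write_ancestry_tsv(probs: DiploidAncestryProbs, samples, variants, path) -> None:
    probs.to_frame(samples, variants).to_csv(path, sep="\t", index=False)


def read_ancestry_tsv(path, samples, variants) -> list[np.ndarray]:
    """Read the long-format local-ancestry TSV, aligned to samples x variants."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _pivot_ancestry(df, samples, variants, ("pEE", "pEA", "pAE", "pAA"))


def _pivot_ancestry(df, samples, variants, value_cols):
    key = pd.MultiIndex.from_frame(
        variants[["chrom", "pos"]].astype({"chrom": str})
    )
    df = df.set_index(["individual", "chrom", "pos"])
    n, m = len(samples), len(variants)
    mats = [np.full((n, m), np.nan) for _ in value_cols]
    for i, s in enumerate(samples):
        try:
            sub = df.xs(s, level="individual")
        except KeyError:
            raise ValueError(f"ancestry file missing sample {s!r}") from None
        sub = sub.reindex(key)
        for mat, col in zip(mats, value_cols):
            mat[i] = sub[col].to_numpy(dtype=float)
    if any(np.isnan(mat).any() for mat in mats):
        raise ValueError("ancestry file missing entries for some (sample, site) pairs")
    return mats


def read_ancestry_probs_tsv(path, samples, variants) -> DiploidAncestryProbs:
    mats = read_ancestry_tsv(path, samples, variants)
    return DiploidAncestryProbs(*mats)


def read_hap_posterior_tsv(path, samples, variants) -> DiploidAncestryProbs:
    """Read per-haplotype European posteriors and convert to diploid states."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    a1, a2 = _pivot_ancestry(df, samples, variants, ("hap1_eu", "hap2_eu"))
    return DiploidAncestryProbs.from_hap_posteriors(a1, a2)


def write_samples_tsv(samples, theta, path, phenotypes: dict | None = None) -> None:
    data = {"individual": list(samples), "theta_af": np.asarray(theta, dtype=float)}
    for name, vals in (phenotypes or {}).items():
        data[name] = np.asarray(vals, dtype=float)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "individual" not in df.columns:
        raise ValueError("sample TSV must have an 'individual' column")
    return df


def write_weights_tsv(weights: PgsWeights, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)


def read_weights_tsv(path) -> PgsWeights:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return PgsWeights(table=df)


def write_freqs_tsv(freqs, variants, path) -> None:
    df = freqs.to_frame(variant_ids=variants["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def write_gwas_tsv(result, variants, path) -> None:
    df = result.to_frame()
    if "variant" not in df.columns:
        df.insert(0, "variant", variants["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bundles

def harmonize_weights(weights: PgsWeights, variants: pd.DataFrame) -> PgsWeights:
    """Orient weight rows to the cohort's counted (ALT) allele.

    A weight whose effect allele equals the cohort REF has its sign
    flipped (dosage of the other allele is 2 - G).  Variants whose
    alleles cannot be reconciled, and strand-ambiguous (A/T, C/G)
    variants, are dropped with a logged count; ambiguous variants that do
    match are kept but flagged in the log.
    """
    key = {(c, p): i for i, (c, p) in enumerate(zip(variants["chrom"].astype(str),
                                                    variants["pos"]))}
    rows = []
    n_flip = n_drop = n_ambig = 0
    for _, r in weights.table.iterrows():
        i = key.get((str(r["chrom"]), int(r["pos"])))
        if i is None:
            rows.append(r)
            continue
        ref, alt = variants["ref"].iloc[i], variants["alt"].iloc[i]
        ea, oa = r["effect_allele"], r["other_allele"]
        if (ea, oa) in AMBIGUOUS_PAIRS:
            n_ambig += 1
        if ea == alt and oa == ref:
            rows.append(r)
        elif ea == ref and oa == alt:
            r = r.copy()
            r["weight"] = -r["weight"]
            r["effect_allele"], r["other_allele"] = alt, ref
            rows.append(r)
            n_flip += 1
        else:
            n_drop += 1
    if n_flip or n_drop or n_ambig:
        log.info(
            "harmonize_weights: %d flipped, %d dropped, %d strand-ambiguous",
            n_flip, n_drop, n_ambig,
        )
    if rows:
        table = pd.DataFrame(rows).reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=list(PgsWeights.REQUIRED))
    return PgsWeights(table=table)


def load_cohort_bundle(
    vcf_path,
    ancestry_path=None,
    samples_path=None,
    weights_path=None,
    strict: bool = True,
) -> CohortBundle:
    """Load and align a genotype VCF with its companion TSVs."""
    hap, geno, variants, samples = read_vcf(vcf_path)
    probs = None
    if ancestry_path is not None:
        probs = read_ancestry_probs_tsv(ancestry_path, samples, variants)
    sample_table = None
    if samples_path is not None:
        sample_table = read_samples_tsv(samples_path)
        missing = sorted(set(samples) - set(sample_table["individual"]))
        extra = sorted(set(sample_table["individual"]) - set(samples))
        if missing or extra:
            msg = f"sample-set mismatch: missing={missing[:5]} extra={extra[:5]}"
            if strict:
                raise ValueError(msg)
            log.warning(msg)
        sample_table = (
            sample_table.set_index("individual").reindex(samples).reset_index()
        )
    weights = None
    if weights_path is not None:
        weights = harmonize_weights(read_weights_tsv(weights_path), variants)
    return CohortBundle(
        genotypes=geno,
        variants=variants,
        samples=samples,
        probs=probs,
        sample_table=sample_table,
        weights=weights,
        haplotypes=hap,
        provenance={"vcf": str(vcf_path), "tool_version": _tool_version()},
    )


def write_cohort_bundle(cohort: AdmixedCohort, prefix, phenotypes: dict | None = None,
                        config: SimulationConfig | None = None) -> dict:
    """Write VCF + ancestry TSV + samples TSV for a simulated cohort."""
    prefix = str(prefix)
    paths = {
        "vcf": prefix + ".vcf",
        "ancestry": prefix + ".ancestry.tsv",
        "samples": prefix + ".samples.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    probs = DiploidAncestryProbs.from_hap_posteriors(
        cohort.hap_ancestry[:, 0, :], cohort.hap_ancestry[:, 1, :]
    )
    write_ancestry_tsv(probs, cohort.samples, cohort.variants, paths["ancestry"])
    write_samples_tsv(cohort.samples, cohort.theta, paths["samples"], phenotypes)
    if config is not None:
        cfg = {k: v for k, v in vars(config).items() if k != "genetic_map"}
        paths["config"] = prefix + ".config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Fit reports

def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [None if not np.isfinite(v) else float(v) for v in x.tolist()]
    if isinstance(x, (np.floating, float)):
        return None if not np.isfinite(x) else float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (tuple, list)):
        return [_jsonable(v) for v in x]
    return x


def write_fit_report(
    fit,
    path,
    reference=None,
    rho=None,
    seed=None,
    config: dict | None = None,
    include_replicates: bool = True,
) -> dict:
    """Serialize a fit (and optional rho estimates) as schema-versioned JSON."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": _tool_version(),
        "estimates": {
            "intercept": fit.intercept,
            "beta_eu": fit.beta_eu,
            "beta_af": fit.beta_af,
            "omega": fit.omega,
            "beta_eu_af": fit.beta_eu_af,
            "beta_af_af": fit.beta_af_af,
        },
        "ci": fit.ci,
        "flags": {"omega_identifiable": fit.omega_identifiable,
                  "omega_mode": fit.omega_mode},
        "n": fit.n,
        "n_boot": fit.n_boot,
        "n_boot_dropped": fit.n_boot_dropped,
        "seed": seed,
        "config": config or {},
    }
    if reference is not None:
        report["reference"] = {
            "beta_obs_eu": reference.beta,
            "delta_r2": reference.delta_r2,
            "ci_beta": list(reference.ci_beta),
            "n": reference.n,
            "n_boot": reference.n_boot,
        }
        if include_replicates:
            report["reference"]["boot_beta"] = reference.boot_beta
    if rho is not None:
        report["rho"] = {
            "rho": rho.rho,
            "rho_projected_af": rho.rho_projected_af,
            "local_ratio": rho.local_ratio,
            "ci": rho.ci,
            "unstable": rho.unstable,
            "n_boot": rho.n_boot,
        }
    if include_replicates and fit.boot:
        report["boot"] = fit.boot
    report = _jsonable(report)
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return report


def read_fit_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported fit-report schema in {path}")
    return report


def load_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML key-value file (seed mandatory)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    if "seed" not in raw:
        raise ValueError("config must specify a seed")
    if "theta_distribution" in raw and isinstance(raw["theta_distribution"], list):
        td = raw["theta_distribution"]
        raw["theta_distribution"] = tuple(
            tuple(x) if isinstance(x, list) else x for x in td
        )
    return SimulationConfig(**raw)


def config_hash(config: SimulationConfig) -> str:
    payload = {k: v for k, v in vars(config).items() if k != "genetic_map"}
    blob = json.dumps(_jsonable(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
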