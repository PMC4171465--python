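"""Synthetic case-control sequencing data for size and power studies.

Emulates the structure of a resequenced genomic region without external
data.  Haplotypes are generated from a latent Gaussian AR(1) copula:
each haplotype is a stationary AR(1) Gaussian vector, thresholded per
variant at the normal quantile of that variant's drawn minor-allele
frequency; a genotype is the sum of two independent haplotypes.  This
reproduces the features the association tests exploit — LD that decays
with distance, a mixed rare/common (L-shaped) frequency spectrum, and,
after minor-allele recoding of the realized sample, occasional negative
pairwise LD — without modelling any specific locus.

Disease status follows a logistic model on the causal variants' genotype
codes, logit P(case) = beta0 + sum_c beta_c g_ic, with per-variant effects
drawn once from Normal(mu, sigma^2).  Case-control cohorts are assembled
by retrospective quota sampling: population subjects are simulated until
the requested numbers of cases and controls are reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .genotype_data import GenotypeMatrix


@dataclass
class SimConfig:
    """Full parameterization of one simulated region study.

    Defaults describe a small balanced case-control study of a sequencing
    region with a half-rare, half-common variant spectrum and moderate LD.
    ``maf_rare`` / ``maf_common`` are Beta(a, b) parameter pairs from which
    per-variant minor-allele frequencies are drawn (clipped to (0, 0.01]
    and [0.01, 0.5] respectively).
    """

    n_cases: int = 25
    n_controls: int = 25
    n_variants: int = 100
    rare_fraction: float = 0.5
    maf_rare: tuple[float, float] = (1.0, 300.0)
    maf_common: tuple[float, float] = (1.0, 3.0)
    ld_rho: float = 0.5
    causal_fraction: float = 0.0
    effect_mean: float = 0.0
    effect_sd: float = 0.25
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.05
    region_length: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_cases >= 1 and self.n_controls >= 1):
            raise ValueError("need at least one case and one control")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in [0, 1]")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _draw_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p = cfg.n_variants
    n_rare = int(round(cfg.rare_fraction * p))
    rare = np.clip(rng.beta(*cfg.maf_rare, size=n_rare), 2e-4, 0.01)
    common = np.clip(rng.beta(*cfg.maf_common, size=p - n_rare), 0.01, 0.5)
    mafs = np.concatenate([rare, common])
    rng.shuffle(mafs)
    return mafs


def _haplotypes(
    mafs: np.ndarray, rho: float, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Threshold a latent AR(1) Gaussian at each variant's MAF quantile."""
    p = mafs.size
    z = rng.standard_normal((n_hap, p))
    if rho > 0.0:
        w = np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + w * z[:, j]
    thresh = norm.ppf(1.0 - mafs)
    return (z > thresh).astype(float)


def _complete_genotypes(
    cfg: SimConfig, n_subjects: int, rng: np.random.Generator, mafs: np.ndarray
) -> np.ndarray:
    h1 = _haplotypes(mafs, cfg.ld_rho, n_subjects, rng)
    h2 = _haplotypes(mafs, cfg.ld_rho, n_subjects, rng)
    return h1 + h2


def _positions(cfg: SimConfig) -> np.ndarray:
    return np.unique(
        np.round(np.linspace(1, cfg.region_length, cfg.n_variants)).astype(int)
    )


def simulate_genotypes(
    cfg: SimConfig, n_subjects: int, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Genotypes for ``n_subjects`` (no phenotype), with MCAR missingness."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mafs = _draw_mafs(cfg, rng)
    codes = _complete_genotypes(cfg, n_subjects, rng, mafs)
    if cfg.missing_rate > 0.0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = np.nan
    return GenotypeMatrix(
        codes=codes,
        positions=_positions(cfg),
        sample_ids=[f"S{i}" for i in range(n_subjects)],
        region_id="simulated",
    )


def _effects(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Causal variant indices and their per-allele log-odds effects."""
    n_causal = int(round(cfg.causal_fraction * cfg.n_variants))
    causal = rng.choice(cfg.n_variants, size=n_causal, replace=False)
    betas = rng.normal(cfg.effect_mean, cfg.effect_sd, size=n_causal)
    return causal, betas


def simulate_phenotype(
    G: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw case/control labels from the logistic disease model.

    ``P(case_i) = expit(beta0 + sum_c beta_c g_ic)`` with effects drawn once
    from Normal(effect_mean, effect_sd^2) for a causal subset of
    ``round(causal_fraction * p)`` variants; ``beta0 = logit(prevalence)``
    so a genotype-free subject has the baseline disease probability.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    codes = np.nan_to_num(G.codes, nan=0.0)
    causal, betas = _effects(
        replace(cfg, n_variants=G.n_variants) if G.n_variants != cfg.n_variants else cfg,
        rng,
    )
    eta = logit(cfg.baseline_prevalence) + codes[:, causal] @ betas
    status = rng.random(G.n_subjects) < expit(eta)
    return np.where(status, "case", "control")


def simulate_dataset(cfg: SimConfig, max_batches: int = 1000) -> GenotypeMatrix:
    """One complete case-control region dataset.

    Population subjects are drawn in batches and assigned disease status
    until the case and control quotas are both filled (retrospective
    sampling); monomorphic variants are then dropped and MCAR missingness
    applied.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = _draw_mafs(cfg, rng)
    causal, betas = _effects(cfg, rng)
    beta0 = logit(cfg.baseline_prevalence)

    need = {"case": cfg.n_cases, "control": cfg.n_controls}
    got: dict[str, list[np.ndarray]] = {"case": [], "control": []}
    counts = {"case": 0, "control": 0}
    want = max(
        cfg.n_cases / cfg.baseline_prevalence,
        cfg.n_controls / (1.0 - cfg.baseline_prevalence),
    )
    batch = int(np.clip(np.ceil(want / 2), 64, 20_000))
    for _ in range(max_batches):
        codes = _complete_genotypes(cfg, batch, rng, mafs)
        eta = beta0 + codes[:, causal] @ betas
        is_case = rng.random(batch) < expit(eta)
        for label, sel in (("case", is_case), ("control", ~is_case)):
            take = min(need[label] - counts[label], int(sel.sum()))
            if take > 0:
                got[label].append(codes[sel][:take])
                counts[label] += take
        if counts["case"] >= need["case"] and counts["control"] >= need["control"]:
            break
    else:
        raise RuntimeError(
            "could not fill case/control quotas; check baseline_prevalence"
        )

    codes = np.vstack(got["case"] + got["control"])
    groups = np.array(
        ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    )
    positions = _positions(cfg)

    poly = codes.max(axis=0) != codes.min(axis=0)
    codes, positions = codes[:, poly], positions[poly]

    if cfg.missing_rate > 0.0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = np.nan

    return GenotypeMatrix(
        codes=codes,
        positions=positions,
        sample_ids=[f"S{i}" for i in range(codes.shape[0])],
        groups=groups,
        region_id="simulated",
    )
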