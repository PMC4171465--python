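"""Monte-Carlo harnesses: type-I-error and power experiments.

Thin loops over the simulator and the region-test pipeline, shared by the
test suite and the reproduction script.  Each replicate draws a fresh
region dataset, pushes it through QC / imputation / minor-allele recoding /
position scaling / (optional) relabeling / smoothing, and records the
FANOVA asymptotic p-value — optionally for several smoothing strategies on
the same dataset so strategies are compared on identical draws.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import genotype_data as gd
from .fanova import distance_matrix, fanova_test, permutation_pvalue
from .relabel import minimize_flips
from .smoothing import SmoothStrategy, Strategy, smooth_all
from .simulate import SimConfig, simulate_dataset

_MAX_SEED = 2**31 - 1


def replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, _MAX_SEED, size=n_reps)


def prepare_replicate(cfg: SimConfig) -> gd.GenotypeMatrix:
    """Simulate one dataset and run it through QC and preprocessing."""
    G = simulate_dataset(cfg)
    G = gd.apply_qc(G)
    G = gd.impute_missing(G, method="mode", seed=cfg.seed)
    G = gd.recode_to_minor(G)
    # monomorphic columns can reappear after subject-level QC + imputation
    G = gd.apply_qc(G)
    return gd.scale_positions(G)


def fanova_pvalues(
    cfg: SimConfig,
    n_reps: int,
    seed: int,
    strategies: list[tuple[Strategy | str, bool]] = ((Strategy.PENALIZED_GCV, True),),
    grid_multiplier: int = 2,
    permutations: int = 0,
) -> dict[tuple[str, bool], np.ndarray]:
    """Asymptotic (and optionally permutation) FANOVA p-values per replicate.

    ``strategies`` is a list of (smoothing strategy, relabel?) pairs, all
    evaluated on the same simulated datasets.  Returns arrays of shape
    (n_reps,) — or (n_reps, 2) with columns (asymptotic, permutation) when
    ``permutations > 0`` — keyed by (strategy value, relabel?).
    """
    combos = [(Strategy(s), bool(r)) for s, r in strategies]
    width = 2 if permutations > 0 else 1
    out = {
        (s.value, r): np.full((n_reps, width), np.nan) for s, r in combos
    }
    for rep, rep_seed in enumerate(replicate_seeds(seed, n_reps)):
        G = prepare_replicate(replace(cfg, seed=int(rep_seed)))
        relabeled = None
        for s, r in combos:
            Gs = G
            if r:
                if relabeled is None:
                    _, relabeled = minimize_flips(G)
                    relabeled.scaled_positions = G.scaled_positions
                Gs = relabeled
            curves = smooth_all(Gs, SmoothStrategy(kind=s), grid_multiplier)
            res = fanova_test(curves, Gs.groups)
            row = out[(s.value, r)][rep]
            row[0] = res.p_asymptotic
            if permutations > 0:
                D2 = distance_matrix(curves)
                _, row[1] = permutation_pvalue(
                    D2, Gs.groups, B=permutations, seed=int(rep_seed)
                )
    return {k: v.squeeze(axis=1) if width == 1 else v for k, v in out.items()}


def rejection_rate(pvalues: np.ndarray, alpha: float) -> float:
    p = np.asarray(pvalues)
    return float((p <= alpha).mean())


def type_i_error(
    cfg: SimConfig,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    strategies: list[tuple[Strategy | str, bool]] = ((Strategy.PENALIZED_GCV, True),),
) -> dict[tuple[str, bool], float]:
    """Empirical size of the FANOVA asymptotic test under the null."""
    null_cfg = replace(cfg, causal_fraction=0.0)
    pvals = fanova_pvalues(null_cfg, n_reps, seed, strategies)
    return {k: rejection_rate(v, alpha) for k, v in pvals.items()}


def power(
    cfg: SimConfig,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    strategies: list[tuple[Strategy | str, bool]] = ((Strategy.PENALIZED_GCV, True),),
) -> dict[tuple[str, bool], float]:
    """Empirical power of the FANOVA asymptotic test at level ``alpha``."""
    pvals = fanova_pvalues(cfg, n_reps, seed, strategies)
    return {k: rejection_rate(v, alpha) for k, v in pvals.items()}
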