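"""Flip-minimizing genotype relabeling.

Negative pairwise LD between minor alleles produces alternating 0-2 / 2-0
patterns along a region, which force smoothed genotype curves to oscillate.
Because the choice of which allele is coded 2 versus 0 is arbitrary for a
test that makes no directional assumption, the coding at a position may be
flipped (0 <-> 2, for all subjects simultaneously) without changing what the
test measures.  This module finds, by exact dynamic programming over the
variant chain, the per-variant flip assignment that minimizes the total
number of adjacent 0-2 (or 2-0) pairs summed over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix


@dataclass
class FlipVector:
    """Per-variant flip indicators with the objective before/after."""

    flips: np.ndarray  # p binary indicators; 1 = codes mapped 0<->2
    cost_before: int
    cost_after: int

    def to_tsv(self, path: str | Path, positions: np.ndarray | None = None) -> None:
        pos = positions if positions is not None else np.arange(1, len(self.flips) + 1)
        pd.DataFrame({"position": pos, "flipped": self.flips.astype(int)}).to_csv(
            path, sep="\t", index=False
        )


def _check_complete(G: GenotypeMatrix) -> None:
    if G.has_missing:
        raise ValueError("relabeling requires an imputed (complete) genotype matrix")


def _pair_costs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip counts for each adjacent variant pair under the two parities.

    ``same[j]`` counts subjects with a 0-2 or 2-0 pattern across pair
    (j, j+1) when both variants keep the same parity (both flipped or both
    unflipped); ``diff[j]`` is the count when exactly one is flipped, i.e.
    the number of 0-0 / 2-2 patterns.  Heterozygotes never contribute.
    """
    a, b = codes[:, :-1], codes[:, 1:]
    same = (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum(axis=0)
    diff = (((a == 0) & (b == 0)) | ((a == 2) & (b == 2))).sum(axis=0)
    return same.astype(np.int64), diff.astype(np.int64)


def flip_cost(G: GenotypeMatrix) -> int:
    """Total count of adjacent 0-2 / 2-0 pairs, summed over all subjects."""
    _check_complete(G)
    if G.n_variants < 2:
        return 0
    same, _ = _pair_costs(G.codes)
    return int(same.sum())


def apply_flips(G: GenotypeMatrix, flips: np.ndarray) -> GenotypeMatrix:
    """Return a copy with codes mapped 0<->2 at flagged variants (involution)."""
    out = G.copy()
    f = np.asarray(flips, dtype=bool)
    out.codes[:, f] = 2.0 - out.codes[:, f]
    return out


def minimize_flips(G: GenotypeMatrix) -> tuple[FlipVector, GenotypeMatrix]:
    """Globally optimal relabeling of the variant chain.

    Exact two-state dynamic program: each variant is either flipped or not,
    and the cost between consecutive variants depends only on whether their
    flip states agree.  Among cost-optimal assignments the one with fewer
    flips is returned; remaining ties are broken toward leaving the
    leftmost differing variant unflipped, so the first variant is unflipped
    whenever optima tie.
    """
    _check_complete(G)
    p = G.n_variants
    if p < 2:
        fv = FlipVector(np.zeros(p, dtype=np.int8), 0, 0)
        return fv, G.copy()

    same, diff = _pair_costs(G.codes)
    before = int(same.sum())

    # Suffix DP on (pair cost, number of flips); lexicographic comparison of
    # the tuple implements the fewer-flips tie-break, and the greedy forward
    # pass below (preferring state 0) the leftmost-unflipped tie-break.
    INF = (np.iinfo(np.int64).max, np.iinfo(np.int64).max)
    best: list[list[tuple[int, int]]] = [[INF, INF] for _ in range(p)]
    best[p - 1][0] = (0, 0)
    best[p - 1][1] = (0, 1)
    for j in range(p - 2, -1, -1):
        for s in (0, 1):
            opts = []
            for t in (0, 1):
                trans = same[j] if s == t else diff[j]
                c, f = best[j + 1][t]
                opts.append((trans + c, f + s))
            best[j][s] = min(opts)

    flips = np.zeros(p, dtype=np.int8)
    flips[0] = 0 if best[0][0] <= best[0][1] else 1
    for j in range(1, p):
        prev = flips[j - 1]
        cands = []
        for s in (0, 1):
            trans = same[j - 1] if s == prev else diff[j - 1]
            c, f = best[j][s]
            cands.append(((trans + c, f), s))
        flips[j] = min(cands)[1]

    relabeled = apply_flips(G, flips)
    after = flip_cost(relabeled)
    fv = FlipVector(flips=flips, cost_before=before, cost_after=after)
    return fv, relabeled
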