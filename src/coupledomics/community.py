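"""Alpha diversity, Bray-Curtis dissimilarity, ANOSIM, and NMDS ordination.

Shannon-Weaver H = -sum p_i ln p_i and Simpson reciprocal 1/D = 1/sum p_i²
are computed on per-library proportions, so both are invariant to scaling a
library by a positive constant.  Community comparison uses the Bray-Curtis
dissimilarity d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), the rank-based
ANOSIM permutation statistic

    R = (mean between-group rank - mean within-group rank) / (M / 2),
    M = n(n - 1)/2,

with p = (1 + #{permuted R >= observed}) / (1 + n_permutations), and
non-metric multidimensional scaling (Kruskal stress-1) with seeded random
restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import smacof

from .io_tables import CountTable, ValidationError

__all__ = [
    "DiversityResult",
    "AnosimResult",
    "NmdsResult",
    "shannon_weaver",
    "simpson_reciprocal",
    "diversity_table",
    "bray_curtis",
    "anosim",
    "nmds",
]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon_weaver: float
    simpson_reciprocal: float


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    grouping_label: str


@dataclass
class NmdsResult:
    """Best-of-restarts non-metric MDS embedding and its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_iterations: int
    converged: bool
    seed: int


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValidationError("all-zero count vector; diversity undefined")
    return c / total


def shannon_weaver(counts, base: float | None = None) -> float:
    """Shannon-Weaver index H = -sum p ln p over nonzero proportions.

    Natural log by default (``base`` overrides).
    """
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson_reciprocal(counts) -> float:
    """Simpson reciprocal 1/D = 1 / sum p², in [1, k] for k observed features."""
    p = _proportions(counts)
    return float(1.0 / (p @ p))


def diversity_table(table: CountTable) -> list[DiversityResult]:
    """Per-sample diversity indices for a count table."""
    return [
        DiversityResult(
            sample_id=s,
            shannon_weaver=shannon_weaver(table.data[s]),
            simpson_reciprocal=simpson_reciprocal(table.data[s]),
        )
        for s in table.samples
    ]


def bray_curtis(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample x sample Bray-Curtis dissimilarity matrix.

    Input is feature x sample; a pair of all-zero samples is an error (the
    denominator vanishes).
    """
    df = table.data if isinstance(table, CountTable) else table
    if df.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    zero = df.columns[df.sum(axis=0) == 0].tolist()
    if len(zero) >= 2:
        raise ValidationError(f"all-zero sample pair(s) among {zero}: Bray-Curtis undefined")
    d = squareform(pdist(df.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


def _check_square(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(
        dissimilarity.to_numpy() if isinstance(dissimilarity, pd.DataFrame) else dissimilarity,
        dtype=float,
    )
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"dissimilarity matrix must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix is not symmetric")
    return d


def _anosim_r(rank_condensed: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    r_within = rank_condensed[within].mean()
    r_between = rank_condensed[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dissimilarity: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
    grouping_label: str = "group",
) -> AnosimResult:
    """Analysis of similarity on a dissimilarity matrix.

    Ranks all pairwise dissimilarities (ties get average ranks) and compares
    between-group to within-group mean ranks.  The permutation null shuffles
    group labels; with ``exhaustive`` every distinct label permutation is
    enumerated (feasible for small n) and the p-value is the exact fraction
    of permutations with R >= observed.
    """
    d = _check_square(dissimilarity)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValidationError(f"{labels.shape[0]} group labels for {n} samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValidationError(f"group(s) of size 1: {small}")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    codes = np.searchsorted(uniq, labels)

    def within_mask(perm_codes: np.ndarray) -> np.ndarray:
        return perm_codes[iu[0]] == perm_codes[iu[1]]

    observed = _anosim_r(ranks, within_mask(codes), n)

    if exhaustive:
        seen: set[tuple[int, ...]] = set()
        count_ge = 0
        total = 0
        for perm in _permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _anosim_r(ranks, within_mask(np.array(perm)), n) >= observed - 1e-12:
                count_ge += 1
        return AnosimResult(
            r_statistic=observed,
            p_value=count_ge / total,
            n_permutations=total,
            grouping_label=grouping_label,
        )

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _anosim_r(ranks, within_mask(perm), n) >= observed - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(
        r_statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        grouping_label=grouping_label,
    )


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    n_restarts: int = 20,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1 with monotone regression.

    Runs ``n_restarts`` seeded random initializations and keeps the lowest
    final stress.  Coordinates are centered at the origin and rotated to
    their principal axes (with a deterministic sign convention) so repeated
    runs with one seed are reproducible and plots have a stable orientation.
    Non-convergence is flagged, not raised.
    """
    d = _check_square(dissimilarity)
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"embedding dimension k={k} must satisfy 1 <= k < n={n}")
    coords, stress, n_iter = smacof(
        d,
        metric=False,
        n_components=k,
        init=None,
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=int(seed) % (2**31),
        return_n_iter=True,
        normalized_stress=True,
    )
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation; flip signs so each axis's largest-|loading|
    # coordinate is positive
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    frame = pd.DataFrame(coords, index=index, columns=[f"nmds{j + 1}" for j in range(k)])
    return NmdsResult(
        coordinates=frame,
        stress=float(stress),
        n_iterations=int(n_iter),
        converged=bool(n_iter < max_iter),
        seed=int(seed),
    )
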