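"""Module-level contrast testing against a random-sampling null.

The contrast statistic of a gene module is the mean log2 fold of its
members minus the mean fold of the total gene set.  Its two-tailed
significance comes from a distribution-free null: many random same-size
gene subsets are drawn without replacement from the universe and the
observed |contrast| is ranked among the sampled ones.  Multiple testing
across a module collection is adjusted with Storey-Tibshirani q-values.

A brute-force enumerator over all same-size subsets is provided as an
independent oracle for small universes.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from heatmod.errors import ValidationError
from heatmod.gene_sets import GeneSetCollection
from heatmod.preprocess import FoldTable

logger = logging.getLogger(__name__)

#: tie tolerance when ranking |T_b| against |T_obs|
_TIE_EPS = 1e-12

#: largest number of subsets the exact enumerator will visit
ENUMERATION_CAP = 1_000_000

#: q-value bands reported in output tables
SIGNIF_BANDS = ((0.001, "q<0.001"), (0.01, "q<0.01"))


@dataclass
class ContrastResult:
    set_id: str
    name: str
    m: int
    mean_fold_module: float
    mean_fold_total: float
    contrast: float
    p_value: float
    q_value: float
    signif_band: str


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-module RNG seed, independent of collection order."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _member_indices(folds: FoldTable, members: Iterable[str]) -> np.ndarray:
    members = list(members)
    if not members:
        raise ValidationError("module has no members")
    indexer = folds.table.index.get_indexer(members)
    if (indexer < 0).any():
        missing = [m for m, i in zip(members, indexer) if i < 0]
        raise ValidationError(f"module members not in fold universe: {missing[:5]}")
    return indexer


def contrast_statistic(folds: FoldTable, members: Iterable[str]) -> float:
    """mean(log2 fold over members) - mean(log2 fold over all genes)."""
    idx = _member_indices(folds, members)
    arr = folds.log2_fold.to_numpy()
    return float(arr[idx].mean() - arr.mean())


def _sample_subset_means(
    arr: np.ndarray, m: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of B uniform without-replacement size-m subsets of ``arr``.

    Two vectorized strategies: rejection sampling of index tuples when
    collisions are rare (m^2 small relative to the universe), otherwise a
    random-key argpartition per draw.
    """
    n = arr.size
    if m == 1:
        return arr[rng.integers(0, n, size=B)]
    if m * m <= n:  # expected collision rate <= ~50%, rejection is cheap
        idx = rng.integers(0, n, size=(B, m))
        bad = np.any(np.diff(np.sort(idx, axis=1), axis=1) == 0, axis=1)
        while bad.any():
            where = np.flatnonzero(bad)
            idx[where] = rng.integers(0, n, size=(where.size, m))
            resampled = np.sort(idx[where], axis=1)
            bad[where] = np.any(np.diff(resampled, axis=1) == 0, axis=1)
        return arr[idx].mean(axis=1)
    means = np.empty(B)
    chunk = max(1, int(4_000_000 // n))
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        means[start : start + b] = arr[idx].mean(axis=1)
    return means


def sampling_null_pvalue(
    folds: FoldTable,
    members: Iterable[str],
    B: int = 20_000,
    rng_seed: int = 0,
) -> float:
    """Two-tailed sampling p-value for a module's contrast.

    Draws ``B`` without-replacement subsets of the module's size from the
    universe and returns p = (1 + #{|T_b| >= |T_obs|}) / (B + 1); the +1
    correction keeps p strictly positive.  Deterministic under a fixed
    seed.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    idx = _member_indices(folds, members)
    arr = folds.log2_fold.to_numpy()
    m, n = idx.size, arr.size
    if m >= n:
        raise ValidationError(f"module size {m} must be smaller than universe size {n}")
    grand = arr.mean()
    obs = abs(arr[idx].mean() - grand)
    rng = np.random.default_rng(rng_seed)
    means = _sample_subset_means(arr, m, B, rng)
    count = int(np.count_nonzero(np.abs(means - grand) >= obs - _TIE_EPS))
    return (1 + count) / (B + 1)


def exact_permutation_pvalue(
    folds: FoldTable, members: Iterable[str], cap: int = ENUMERATION_CAP
) -> float:
    """Exact two-tailed p by enumerating every same-size subset.

    p = #{subsets S : |T_S| >= |T_obs|} / C(N, m); the observed subset is
    one of the enumerated subsets, so p > 0 by construction.  Usable only
    when C(N, m) is within the enumeration cap.
    """
    idx = _member_indices(folds, members)
    arr = folds.log2_fold.to_numpy()
    m, n = idx.size, arr.size
    if m >= n:
        raise ValidationError(f"module size {m} must be smaller than universe size {n}")
    total = math.comb(n, m)
    if total > cap:
        raise ValidationError(
            f"C({n}, {m}) = {total} exceeds the enumeration cap; use sampling_null_pvalue"
        )
    grand = arr.mean()
    obs = abs(arr[idx].mean() - grand)
    count = 0
    for subset in combinations(range(n), m):
        if abs(arr[list(subset)].mean() - grand) >= obs - _TIE_EPS:
            count += 1
    return count / total


def storey_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    on the grid lambda = 0.05, 0.10, ..., 0.95, smoothed with a cubic
    least-squares fit evaluated at lambda = 0.95 and clamped to (0, 1].
    With fewer than 100 tests the estimate is unstable and pi0 is forced
    to 1 (conservative).  q_i = pi0 * min_{p_j >= p_i} p_j * m / rank(p_j);
    output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m < 100:
        logger.info("storey_qvalues: %d tests < 100, forcing pi0 = 1", m)
        pi0 = 1.0
    else:
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeffs, 0.95))
        pi0 = min(pi0, 1.0)
        if pi0 <= 0.0:
            logger.warning("storey_qvalues: smoothed pi0 <= 0, clamping")
            pi0 = 1e-8
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _band(q: float) -> str:
    for cut, label in SIGNIF_BANDS:
        if q < cut:
            return label
    return ""


def run_contrast_analysis(
    folds: FoldTable,
    gsc: GeneSetCollection,
    B: int = 20_000,
    rng_seed: int = 0,
) -> list[ContrastResult]:
    """Contrast test for every module in a collection, with joint q-values.

    Per-module RNG streams are derived from the master seed and the set
    id, so each module's p-value is independent of collection order.
    Results are sorted by q-value, then |contrast| descending, then set
    id for stable ties.
    """
    if len(gsc) == 0:
        return []
    arr = folds.log2_fold.to_numpy()
    grand = float(arr.mean())
    stats: list[tuple[str, str, int, float, float, float]] = []
    for gs in gsc:
        contrast = contrast_statistic(folds, gs.members)
        if len(gs) == arr.size:  # module == universe: contrast is 0 by identity
            p = 1.0
        else:
            p = sampling_null_pvalue(
                folds, gs.members, B=B, rng_seed=derive_seed(rng_seed, gs.set_id)
            )
        stats.append((gs.set_id, gs.name, len(gs), contrast + grand, contrast, p))
    qvals = storey_qvalues([s[5] for s in stats])
    results = [
        ContrastResult(
            set_id=set_id,
            name=name,
            m=m,
            mean_fold_module=mean_mod,
            mean_fold_total=grand,
            contrast=contrast,
            p_value=p,
            q_value=float(q),
            signif_band=_band(float(q)),
        )
        for (set_id, name, m, mean_mod, contrast, p), q in zip(stats, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.contrast), r.set_id))
    return results
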