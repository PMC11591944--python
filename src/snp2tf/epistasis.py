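"""Mutual-information epistasis detection for quantitative traits.

Single SNPs and SNP pairs are scored by their mutual information with the
phenotype.  For a continuous trait the MI between a discrete genotype (or
the 9-state composite genotype of a pair) and the phenotype is estimated
with the k-nearest-neighbour estimator for mixed discrete-continuous data
(digamma form): for each point, the distance to its k-th neighbour *within
its genotype class* defines a ball, and

    I = psi(N) - <psi(N_c)> + <psi(k_i)> - <psi(m_i)>  (nats, /ln 2 for bits)

where N_c is the class size and m_i the number of points of any class inside
the ball.  Pair scores are background-corrected with the average-product
correction (APC) before ranking, which removes the shared per-SNP background
association that would otherwise dominate the pair ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .containers import MISSING

__all__ = [
    "MIResult",
    "EpistaticPair",
    "mi_discrete",
    "mi_mixed",
    "pair_mi",
    "apc_correct",
    "detect_epistasis",
]

_LN2 = np.log(2.0)


@dataclass
class MIResult:
    """MI of one SNP (or pair) with the phenotype, in bits."""

    snp_id: str | tuple[str, str]
    mi: float
    n_used: int

    @property
    def mi_clamped(self) -> float:
        return max(0.0, self.mi)


@dataclass
class EpistaticPair:
    """Unordered SNP pair with raw and background-corrected scores."""

    snp_a: str
    snp_b: str
    mi_pair: float
    corrected: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.snp_b < self.snp_a:
            self.snp_a, self.snp_b = self.snp_b, self.snp_a


def _complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    mask = (x != MISSING) & ~np.isnan(y.astype(float))
    return x[mask], y[mask]


def mi_discrete(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete variables."""
    x, y = _complete(np.asarray(x), np.asarray(y, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 complete observations, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("each variable needs >= 2 distinct values")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
    return float(terms.sum())


def _mixed_mi_sorted(codes: np.ndarray, y: np.ndarray, k: int,
                     y_sorted: np.ndarray, psi_table: np.ndarray) -> float:
    """Core nearest-neighbour estimator; inputs are complete and jittered.

    ``y_sorted`` is the full sample sorted once by the caller; ``psi_table``
    caches digamma at integer arguments.  Classes with a single member are
    dropped; k shrinks to (class size - 1) in small classes.  Returns nats.
    """
    order = np.lexsort((y, codes))
    cs = codes[order]
    ys = y[order]
    # class boundaries in the grouped arrays
    starts = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1]])
    ends = np.r_[starts[1:], cs.size]
    radii = np.empty(cs.size)
    k_all = np.empty(cs.size, dtype=np.int64)
    n_class = np.empty(cs.size, dtype=np.int64)
    keep = np.zeros(cs.size, dtype=bool)
    for s, e in zip(starts, ends):
        size = e - s
        n_class[s:e] = size
        if size < 2:
            continue
        keep[s:e] = True
        kk = min(k, size - 1)
        k_all[s:e] = kk
        grp = ys[s:e]
        # distance to the kk-th nearest neighbour in a sorted 1-D array:
        # minimise over the kk+1 windows of length kk+1 containing each point
        d = np.full(size, np.inf)
        for t in range(kk + 1):
            lo = np.arange(size) - t
            hi = lo + kk
            valid = (lo >= 0) & (hi < size)
            cand = np.full(size, np.inf)
            cand[valid] = np.maximum(
                grp[valid] - grp[lo[valid]], grp[hi[valid]] - grp[valid]
            )
            d = np.minimum(d, cand)
        radii[s:e] = d
    if not keep.any():
        raise ValueError("no genotype class with >= 2 members")
    ysk = ys[keep]
    rk = radii[keep]
    # m counts neighbours of any class within the closed ball, excluding the
    # point itself.  The k-th in-class neighbour sits exactly on the boundary,
    # where float rounding of ysk +/- rk makes its membership unstable (e.g.
    # under rescaling of y).  The caller standardizes y, so an absolute
    # shrink of 1e-13 — far above the ~1e-16 rounding slack of O(1) values,
    # far below the 1e-10 tie-breaking jitter — deterministically excludes
    # the boundary neighbour; the self count then stands in for it:
    # m = (strict interior neighbours) + 1.
    r = np.maximum(rk - 1e-13, 0.0)
    m = np.searchsorted(y_sorted, ysk + r, side="right") - np.searchsorted(
        y_sorted, ysk - r, side="left"
    )
    n_used = int(keep.sum())
    mi = (
        psi_table[n_used]
        - psi_table[n_class[keep]].mean()
        + psi_table[k_all[keep]].mean()
        - psi_table[m].mean()
    )
    return float(mi)


def _psi_table(n: int) -> np.ndarray:
    tab = np.empty(n + 1)
    tab[0] = np.nan
    tab[1:] = digamma(np.arange(1, n + 1))
    return tab


def _jitter(y: np.ndarray, seed: int) -> np.ndarray:
    """Standardize (MI is affine-invariant) and add a tiny seeded jitter.

    Standardizing first makes the estimate bit-stable under rescaling of the
    trait (distance comparisons otherwise flip on float rounding), and the
    1e-10 jitter breaks exact phenotype ties.
    """
    sd = y.std() or 1.0
    y = (y - y.mean()) / sd
    rng = np.random.default_rng(seed)
    return y + 1e-10 * rng.standard_normal(y.size)


def _effectively_discrete(y: np.ndarray) -> bool:
    """True when y has so few distinct values that the k-NN density
    assumption breaks (<= 32 values and <= 10% of the sample size)."""
    n_unique = np.unique(y).size
    return n_unique <= 32 and n_unique * 10 <= y.size


def mi_mixed(x: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0) -> float:
    """k-NN mutual information (bits) between genotype codes and a trait.

    Invariant under strictly monotone transforms of ``y`` up to estimator
    noise; may be slightly negative on independent data (unbiasedness, not
    non-negativity, is the estimator's contract).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    x, y = _complete(np.asarray(x), np.asarray(y, dtype=float))
    if np.unique(x).size < 2:
        raise ValueError("genotype column is constant among complete pairs")
    if _effectively_discrete(y):
        # a near-degenerate trait (e.g. a noiseless two-class architecture)
        # violates the continuous-density assumption of the neighbour
        # estimator; the plug-in on the exact values is unbiased there
        return mi_discrete(x, y)
    y = _jitter(y, seed)
    y_sorted = np.sort(y)
    psi = _psi_table(x.size)
    return _mixed_mi_sorted(x.astype(np.int64), y, k, y_sorted, psi) / _LN2


def pair_mi(xa: np.ndarray, xb: np.ndarray, y: np.ndarray, k: int = 3,
            seed: int = 0) -> float:
    """MI (bits) between the 9-state composite genotype of a pair and y."""
    xa = np.asarray(xa)
    xb = np.asarray(xb)
    mask = (xa != MISSING) & (xb != MISSING)
    composite = np.where(mask, 3 * xa + xb, MISSING)
    return mi_mixed(composite, np.asarray(y, dtype=float), k=k, seed=seed)


def apc_correct(pair_mi_values: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Average-product correction of a sparse pair->MI map.

    corrected(i,j) = MI(i,j) - mean_i * mean_j / mean_all, where mean_i is
    the mean MI over pairs involving SNP i.  A single-pair input returns 0
    by convention (no background to estimate).
    """
    if not pair_mi_values:
        return {}
    if len(pair_mi_values) == 1:
        return {pair: 0.0 for pair in pair_mi_values}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (a, b), v in pair_mi_values.items():
        for s in (a, b):
            sums[s] = sums.get(s, 0.0) + v
            counts[s] = counts.get(s, 0) + 1
    mean_all = sum(pair_mi_values.values()) / len(pair_mi_values)
    out = {}
    for (a, b), v in pair_mi_values.items():
        if mean_all == 0.0:
            out[(a, b)] = v
            continue
        background = (sums[a] / counts[a]) * (sums[b] / counts[b]) / mean_all
        out[(a, b)] = v - background
    return out


def detect_epistasis(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    screen_fraction: float = 0.01,
    min_screen: int = 50,
    k: int = 3,
    seed: int = 0,
    ifs_max_k: int | None = 50,
    cv_folds: int = 5,
    n_trees: int = 100,
) -> tuple[list[EpistaticPair], "object | None"]:
    """Rank epistatic SNP pairs for one trait.

    Stages: (1) single-SNP MI screen keeping the top ``screen_fraction`` of
    SNPs (at least ``min_screen``); (2) all within-screen pairs scored by
    the composite-genotype MI; (3) average-product correction; (4) ranking
    by corrected score; (5) optionally, incremental feature selection over
    the ranked pairs (forest on composite pair codes scored by out-of-fold
    Pearson r) to suggest how many pairs to retain.

    Returns the ranked pair list and the IFS curve (None when skipped).
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    m = X.shape[1]
    if m != len(snp_ids):
        raise ValueError("snp_ids length must match X columns")
    n_keep = max(min(min_screen, m), int(np.ceil(screen_fraction * m)))
    n_keep = min(n_keep, m)
    if n_keep < 2:
        raise ValueError("screening keeps fewer than 2 SNPs")

    yj = _jitter(y, seed)
    y_sorted = np.sort(yj)
    psi = _psi_table(y.size)
    single = np.empty(m)
    for j in range(m):
        xj = X[:, j].astype(np.int64)
        single[j] = _mixed_mi_sorted(xj, yj, k, y_sorted, psi) / _LN2
    order = np.argsort(-single, kind="stable")
    screened = np.sort(order[:n_keep])

    pair_scores: dict[tuple[str, str], float] = {}
    for ja, jb in itertools.combinations(screened, 2):
        comp = (3 * X[:, ja] + X[:, jb]).astype(np.int64)
        mi = _mixed_mi_sorted(comp, yj, k, y_sorted, psi) / _LN2
        a, b = sorted((snp_ids[ja], snp_ids[jb]))
        pair_scores[(a, b)] = mi
    # clamp at 0 before background correction: the APC ratio
    # mean_i*mean_j/mean_all is only meaningful for a non-negative score
    # matrix, and near-zero global means otherwise amplify estimator noise
    corrected = apc_correct({p: max(0.0, v) for p, v in pair_scores.items()})

    ranked = sorted(
        corrected.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
    )
    pairs = [
        EpistaticPair(a, b, mi_pair=pair_scores[(a, b)],
                      corrected=c, rank=r + 1)
        for r, ((a, b), c) in enumerate(ranked)
    ]

    curve = None
    if ifs_max_k:
        from .rf import IFSCurve, incremental_feature_selection_matrix

        idx = {s: j for j, s in enumerate(snp_ids)}
        features = np.column_stack(
            [
                (3 * X[:, idx[p.snp_a]] + X[:, idx[p.snp_b]]).astype(float)
                for p in pairs[: min(ifs_max_k, len(pairs))]
            ]
        )
        curve = incremental_feature_selection_matrix(
            features, y, max_k=features.shape[1], cv_folds=cv_folds,
            seed=seed, n_trees=n_trees,
        )
    return pairs, curve
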