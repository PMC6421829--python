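"""Distance-based PERMANOVA with repeated-rarefaction pooling.

The single-covariate pseudo-F follows the McArdle-Anderson formulation:
Gower-center the matrix of -D^2/2, project onto the covariate's hat matrix,
and take the ratio of model to residual trace sums of squares.  On
Euclidean distances this reproduces classical ANOVA exactly.

Significance comes from permuting the covariate across samples.  To keep
the rarefaction step from dictating the answer, the count table is rarefied
R times; each rarefied table yields its own observed statistic and its own
permutation draw, and the per-rarefaction exceedance counts are pooled into
a single p-value with one continuity correction:

    p = (1 + sum_r #{k : F_{r,k} >= F_obs,r - eps_r}) / (1 + R*K)

Permuted statistics numerically tied with the observed one count as
exceedances ("epsilon correction", eps = sqrt(machine eps) * max(1, |F|)),
which keeps p-values from becoming anti-conservative through floating-point
ties.  The +1 continuity correction means p is never exactly 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_rng
from .beta import pairwise_dissimilarity
from .tables import CountTable, DistanceMatrix
from .tree import PhyloTree

__all__ = [
    "PermanovaResult",
    "gower_center",
    "pseudo_f",
    "permanova_single",
    "permanova_rarefied",
    "pool_exceedances",
]

log = logging.getLogger("benthodiv.permanova")

_EPS_BASE = math.sqrt(np.finfo(float).eps)


@dataclass
class PermanovaResult:
    """Pseudo-F, R-squared and permutation p for one covariate."""

    covariate: str
    F: float
    R2: float
    p: float
    df_model: int
    df_resid: int
    n_perm: int
    n_rarefactions: int
    epsilon: float
    measure: str = ""
    seed: int | None = None
    trace: pd.DataFrame | None = field(default=None, repr=False)


def gower_center(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Double-centered inner-product matrix G from a distance matrix.

    A = -D*D/2 elementwise; G = (I - 11'/n) A (I - 11'/n).  tr(G) equals
    the total sum of squares (1/n) sum_{i<j} D_ij^2 (Huygens identity).
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dv.shape[0]
    A = -0.5 * Dv * Dv
    row = A.mean(axis=1, keepdims=True)
    colm = A.mean(axis=0, keepdims=True)
    return A - row - colm + A.mean()


def _design(x) -> tuple[np.ndarray, int]:
    """Design matrix [intercept | covariate columns] and its rank."""
    x = np.asarray(x)
    n = x.shape[0]
    if np.issubdtype(x.dtype, np.number):
        if np.isnan(x.astype(float)).any():
            raise ValueError("covariate contains missing values; drop those samples first")
        if np.ptp(x.astype(float)) == 0:
            raise ValueError("covariate is constant: model is rank-deficient")
        X = np.column_stack([np.ones(n), x.astype(float)])
    else:
        levels, codes = np.unique(x, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("covariate is constant: model is rank-deficient")
        dummies = np.eye(len(levels))[codes]
        X = np.column_stack([np.ones(n), dummies[:, 1:]])
    rank = int(np.linalg.matrix_rank(X))
    return X, rank


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def pseudo_f(G: np.ndarray, x) -> tuple[float, float]:
    """Pseudo-F and R-squared of a single covariate on a centered matrix.

    SS_model = tr(HGH), SS_resid = tr((I-H)G(I-H)) with H the covariate's
    hat matrix; since H is idempotent both reduce to traces of GH.  A
    degenerate G (all samples identical) yields F = 0, R2 = 0.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    X, rank = _design(x)
    if len(x) != n:
        raise ValueError("covariate length does not match distance matrix")
    ss_total = float(np.trace(G))
    if abs(ss_total) < 1e-12:
        return 0.0, 0.0
    H = _hat(X)
    ss_model = float(np.trace(G @ H))
    ss_resid = ss_total - ss_model
    # a perfect fit leaves a residual that is zero up to round-off; clamp it
    # so F becomes +inf instead of a sign-flipped artefact
    if ss_resid < 1e-12 * max(abs(ss_total), 1.0):
        ss_resid = 0.0
    df_m = rank - 1
    df_r = n - rank
    if df_r <= 0:
        raise ValueError("no residual degrees of freedom")
    F = math.inf if ss_resid == 0.0 else (ss_model / df_m) / (ss_resid / df_r)
    return float(F), float(min(max(ss_model / ss_total, 0.0), 1.0))


def _model_ss_numeric(G: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """SS_model for each column of centered covariates Xc (vectorized).

    For a single centered covariate xc, tr(GH) = xc' G xc / (xc' xc) because
    G is double-centered (the intercept direction contributes nothing).
    """
    GX = G @ Xc
    num = np.einsum("ij,ij->j", Xc, GX)
    den = np.einsum("ij,ij->j", Xc, Xc)
    return num / den


def _permuted_f_numeric(G: np.ndarray, x: np.ndarray, perms: np.ndarray) -> np.ndarray:
    n = G.shape[0]
    ss_total = float(np.trace(G))
    if abs(ss_total) < 1e-12:  # degenerate: every permutation ties at F = 0
        return np.zeros(perms.shape[0])
    xc = x - x.mean()
    Xp = xc[perms].T  # n x K
    ss_m = _model_ss_numeric(G, Xp)
    ss_resid = ss_total - ss_m
    ss_resid = np.where(ss_resid < 1e-12 * max(abs(ss_total), 1.0), 0.0, ss_resid)
    df_r = n - 2
    with np.errstate(divide="ignore"):
        return np.where(ss_resid == 0.0, np.inf, ss_m / (ss_resid / df_r))


def _permuted_f_general(G: np.ndarray, x, perms: np.ndarray) -> np.ndarray:
    out = np.empty(perms.shape[0])
    x = np.asarray(x)
    for k, perm in enumerate(perms):
        out[k], _ = pseudo_f(G, x[perm])
    return out


def _permutation_f(G: np.ndarray, x, perms: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if np.issubdtype(x.dtype, np.number):
        return _permuted_f_numeric(G, x.astype(float), perms)
    return _permuted_f_general(G, x, perms)


def epsilon_for(F_obs: float) -> float:
    """Relative tie tolerance for the >= comparison on permuted statistics."""
    if not math.isfinite(F_obs):
        return _EPS_BASE
    return _EPS_BASE * max(1.0, abs(F_obs))


def pool_exceedances(exceedances: int, n_total: int) -> float:
    """One continuity-corrected p from pooled permutation exceedance counts.

    Isolated so the pooling rule across rarefactions can be swapped without
    touching the resampling machinery.
    """
    return (1 + exceedances) / (1 + n_total)


def _draw_perms(rng: np.random.Generator, n: int, K: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(K)])


def permanova_single(
    D: DistanceMatrix | np.ndarray,
    x,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    covariate: str = "x",
) -> PermanovaResult:
    """PERMANOVA of one covariate on a fixed distance matrix.

    ``exhaustive=True`` replaces random draws with complete enumeration of
    all n! relabelings (p = #{F* >= F_obs - eps} / n!, identity included);
    only sensible for very small n.
    """
    measure = D.measure if isinstance(D, DistanceMatrix) else ""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = Dv.shape[0]
    if len(x) != n:
        raise ValueError("covariate length does not match distance matrix")
    G = gower_center(Dv)
    _, rank = _design(x)
    F_obs, R2 = pseudo_f(G, x)
    eps = epsilon_for(F_obs)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        F_perm = _permutation_f(G, x, perms)
        p = float((F_perm >= F_obs - eps).sum() / len(perms))
        K = len(perms)
    elif n_perm > 0:
        rng = derive_rng(seed, "perm", 0)
        perms = _draw_perms(rng, n, n_perm)
        F_perm = _permutation_f(G, x, perms)
        exceed = int((F_perm >= F_obs - eps).sum())
        p = pool_exceedances(exceed, n_perm)
        K = n_perm
    else:
        p, K = float("nan"), 0
    return PermanovaResult(
        covariate=covariate, F=F_obs, R2=R2, p=p,
        df_model=rank - 1, df_resid=n - rank,
        n_perm=K, n_rarefactions=1, epsilon=eps, measure=measure, seed=seed,
    )


def permanova_rarefied(
    table: CountTable,
    x,
    measure: str,
    tree: PhyloTree | None = None,
    depth: int = 9058,
    rarefactions: int = 999,
    n_perm: int = 999,
    seed: int | None = None,
    permute_per_rarefaction: bool = True,
    covariate: str = "x",
    keep_trace: bool = True,
) -> PermanovaResult:
    """Repeated-rarefaction PERMANOVA of one covariate.

    For each of ``rarefactions`` iterations the table is rarefied to
    ``depth`` with a derived child seed, the distance matrix rebuilt, and
    the observed pseudo-F compared against ``n_perm`` freshly drawn label
    permutations (set ``permute_per_rarefaction=False`` to reuse one
    permutation set across all rarefactions).  Exceedance counts are pooled
    into the overall p; reported F and R2 are means across rarefactions.
    """
    from .alpha import rarefy_counts

    x = np.asarray(x)
    n = table.n_samples
    if len(x) != n:
        raise ValueError("covariate length does not match sample count")
    _, rank = _design(x)
    R, K = rarefactions, n_perm
    shared_perms = None
    if not permute_per_rarefaction:
        shared_perms = _draw_perms(derive_rng(seed, "perm", 0), n, K)
    rows = []
    total_exceed = 0
    for r in range(R):
        rng_r = derive_rng(seed, "rarefy", r)
        rarefied = rarefy_counts(table, depth, rng=rng_r)
        Dv = pairwise_dissimilarity(rarefied.counts, measure, tree, table.otu_ids)
        G = gower_center(Dv)
        F_obs, R2 = pseudo_f(G, x)
        eps = epsilon_for(F_obs)
        if K > 0:
            perms = shared_perms if shared_perms is not None else _draw_perms(
                derive_rng(seed, "perm", r), n, K
            )
            F_perm = _permutation_f(G, x, perms)
            exceed = int((F_perm >= F_obs - eps).sum())
        else:
            exceed = 0
        total_exceed += exceed
        rows.append((r, F_obs, R2, exceed, eps))
    trace = pd.DataFrame(
        rows, columns=["rarefaction", "F", "R2", "exceedances", "epsilon"]
    )
    p = pool_exceedances(total_exceed, R * K) if K > 0 else float("nan")
    result = PermanovaResult(
        covariate=covariate,
        F=float(trace["F"].mean()),
        R2=float(trace["R2"].mean()),
        p=p,
        df_model=rank - 1,
        df_resid=n - rank,
        n_perm=K,
        n_rarefactions=R,
        epsilon=float(trace["epsilon"].mean()),
        measure=measure,
        seed=seed,
        trace=trace if keep_trace else None,
    )
    log.info(
        "PERMANOVA %s ~ %s (%s): F=%.4f R2=%.4f p=%.4g (R=%d, K=%d)",
        measure, covariate, "rarefied", result.F, result.R2, result.p, R, K,
    )
    return result
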