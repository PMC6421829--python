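"""Alpha diversity: rarefaction, richness, Shannon, Faith's PD, curves,
Michaelis-Menten coverage, and the repeated-rarefaction averaging protocol.

The analysis convention is: filter out libraries shallower than the
rarefaction depth, rarefy every remaining library WITHOUT replacement to a
common depth, compute richness S, Shannon H' (natural log), and Faith's
phylogenetic diversity (root-inclusive), repeat over many rarefaction
iterations, and report per-sample means.  Per-sample coverage is the
observed richness divided by the asymptote of a Michaelis-Menten curve
y = d*x / (e + x) fitted to the (mean) analytic rarefaction curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import gammaln

from ._utils import derive_rng
from .tables import CountTable
from .tree import EdgeStructure, PhyloTree

__all__ = [
    "rarefy_counts",
    "richness",
    "shannon_index",
    "faith_pd",
    "rarefaction_curve",
    "species_accumulation",
    "MMFit",
    "fit_michaelis_menten",
    "coverage_estimate",
    "AlphaProfile",
    "alpha_profile",
]

log = logging.getLogger("benthodiv.alpha")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy_counts(
    table: CountTable,
    depth: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Subsample every library to exactly ``depth`` reads without replacement.

    The rarefied count vector of a sample is a multivariate hypergeometric
    draw from its read pool, so each taxon's rarefied count has mean
    depth * N_i / N.  Zero columns are retained.  Samples shallower than
    ``depth`` are an error — drop them first (see
    :func:`benthodiv.env_stats.drop_low_depth`).
    """
    depths = table.depths()
    shallow = depths[depths < depth]
    if len(shallow):
        raise ValueError(
            f"samples shallower than rarefaction depth {depth}: "
            + ", ".join(f"{s} ({d})" for s, d in shallow.items())
        )
    if rng is None:
        rng = derive_rng(seed, "rarefy")
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CountTable(out, list(table.sample_ids), list(table.otu_ids),
                      dict(table.fraction) if table.fraction else None)


# ---------------------------------------------------------------------------
# per-sample indices
# ---------------------------------------------------------------------------

def richness(sample_counts) -> int:
    """Number of taxa with count > 0."""
    counts = np.asarray(sample_counts)
    return int(np.count_nonzero(counts > 0))


def shannon_index(sample_counts) -> float:
    """Shannon diversity H' = -sum p_i ln p_i in nats (0 ln 0 := 0)."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _present_otus(sample_counts, otu_ids) -> tuple[np.ndarray, list[str]]:
    if isinstance(sample_counts, pd.Series):
        otu_ids = list(sample_counts.index.astype(str))
        counts = sample_counts.to_numpy()
    else:
        counts = np.asarray(sample_counts)
        if otu_ids is None:
            raise ValueError("otu_ids required when counts is a bare array")
        otu_ids = list(otu_ids)
    return counts, otu_ids


def faith_pd(sample_counts, tree: PhyloTree, otu_ids=None) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Sum of branch lengths of the minimal subtree connecting the present
    taxa and the root, i.e. the total length of every edge with at least
    one present descendant tip.
    """
    counts, otu_ids = _present_otus(sample_counts, otu_ids)
    present = [o for o, c in zip(otu_ids, counts) if c > 0]
    tips = set(tree.tip_labels)
    for o in present:
        if o not in tips:
            raise KeyError(f"zOTU {o!r} has counts but is not a tip of the tree")
    structure = tree.edge_structure(otu_ids, strict=False)
    mask = np.asarray(counts) > 0
    on_path = structure.incidence @ mask  # edges with >=1 present descendant
    return float(structure.lengths[on_path > 0].sum())


def _faith_pd_matrix(counts: np.ndarray, structure: EdgeStructure) -> np.ndarray:
    present = (counts > 0)
    edge_on = structure.incidence.astype(np.float64) @ present.T.astype(np.float64)
    return (structure.lengths[:, None] * (edge_on > 0)).sum(axis=0)


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------

def _log_choose(a: np.ndarray, k: float) -> np.ndarray:
    return gammaln(a + 1.0) - gammaln(k + 1.0) - gammaln(a - k + 1.0)


@dataclass
class RarefactionCurve:
    """Analytic expected-richness curve E[S_n] for one sample."""

    sample_id: str
    n: np.ndarray
    expected_richness: np.ndarray


def expected_richness(sample_counts, n) -> np.ndarray:
    """Hypergeometric expectation of richness in a subsample of size n.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] over taxa with N_i > 0;
    no resampling involved.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = counts.sum()
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if (n > N).any():
        raise ValueError(f"subsample size exceeds library depth {N}")
    if (n < 0).any():
        raise ValueError("subsample size must be non-negative")
    out = np.empty(n.shape, dtype=float)
    for k_idx, nn in enumerate(n):
        rem = N - counts  # pool sizes excluding taxon i
        with np.errstate(invalid="ignore"):
            lp = _log_choose(rem.astype(float), float(nn)) - float(
                _log_choose(np.array([float(N)]), float(nn))[0]
            )
        p_absent = np.where(rem >= nn, np.exp(lp), 0.0)
        out[k_idx] = float((1.0 - p_absent).sum())
    return out


def rarefaction_curve(sample_counts, grid, sample_id: str = "") -> RarefactionCurve:
    grid = np.atleast_1d(np.asarray(grid, dtype=np.int64))
    return RarefactionCurve(sample_id, grid, expected_richness(sample_counts, grid))


def species_accumulation(table: CountTable, k_grid=None) -> pd.DataFrame:
    """Sample-based expected species accumulation (the 'exact' method).

    E[S(k)] = sum_i [1 - C(T - t_i, k) / C(T, k)] where T is the number of
    samples and t_i the number of samples in which zOTU i occurs.
    """
    T = table.n_samples
    if T < 1:
        raise ValueError("need at least one sample")
    if k_grid is None:
        k_grid = np.arange(1, T + 1)
    k_grid = np.atleast_1d(np.asarray(k_grid, dtype=np.int64))
    if (k_grid > T).any():
        raise ValueError(f"k exceeds the number of samples ({T})")
    t = (table.counts > 0).sum(axis=0)
    t = t[t > 0].astype(float)
    rows = []
    for k in k_grid:
        rem = T - t
        with np.errstate(invalid="ignore"):
            lp = _log_choose(rem, float(k)) - float(
                _log_choose(np.array([float(T)]), float(k))[0]
            )
        p_absent = np.where(rem >= k, np.exp(lp), 0.0)
        rows.append((int(k), float((1.0 - p_absent).sum())))
    return pd.DataFrame(rows, columns=["k", "expected_richness"])


# ---------------------------------------------------------------------------
# Michaelis-Menten coverage
# ---------------------------------------------------------------------------

@dataclass
class MMFit:
    """Least-squares fit of the saturating curve y = d*x / (e + x).

    ``asymptote`` (d) estimates total richness; ``half_saturation`` (e) is
    the effort at which half the asymptote is reached.
    """

    asymptote: float
    half_saturation: float
    residual_ss: float
    converged: bool
    message: str = ""


def fit_michaelis_menten(x, y) -> MMFit:
    """Fit y = d*x/(e+x) by least squares.

    Initialised at d0 = max(y) and e0 = the x whose y is closest to d0/2;
    relative parameter tolerance 1e-8.  A constant-y input is degenerate
    (e is unidentifiable) and is reported as non-converged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a Michaelis-Menten fit")
    if (x <= 0).any():
        raise ValueError("x values must be positive")
    if np.ptp(y) == 0:
        return MMFit(float(y[0]), float("nan"), 0.0, False,
                     "constant response: half-saturation unidentifiable")
    d0 = float(np.max(y))
    e0 = float(x[np.argmin(np.abs(y - d0 / 2.0))])

    def resid(theta):
        d, e = theta
        return d * x / (e + x) - y

    res = least_squares(
        resid, x0=[d0, max(e0, 1e-9)], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-10, ftol=1e-12, gtol=1e-12,
    )
    d, e = res.x
    return MMFit(float(d), float(e), float(np.sum(res.fun ** 2)),
                 bool(res.success), res.message)


def coverage_estimate(s_obs: float, fit: MMFit) -> float:
    """Coverage (%) = 100 * observed richness / fitted asymptote.

    Values above 100 can occur when the observed richness exceeds the
    fitted asymptote; they are returned as-is with a warning, never
    silently clamped.
    """
    if not fit.converged:
        raise ValueError("coverage requires a converged Michaelis-Menten fit")
    pct = 100.0 * float(s_obs) / fit.asymptote
    if pct > 100.0:
        warnings.warn(
            f"observed richness {s_obs} exceeds fitted asymptote "
            f"{fit.asymptote:.3f}: coverage {pct:.2f}% > 100%",
            stacklevel=2,
        )
    return pct


# ---------------------------------------------------------------------------
# repeated-rarefaction alpha profile
# ---------------------------------------------------------------------------

@dataclass
class AlphaProfile:
    """Per-sample alpha indices averaged over rarefaction iterations."""

    data: pd.DataFrame  # columns: richness, shannon, faith_pd, coverage, coverage_exceeds
    depth: int
    iterations: int
    seed: int | None
    mm_fits: dict[str, MMFit] = field(default_factory=dict)
    mean_curves: pd.DataFrame | None = None


def _curve_grid(depth: int, n_points: int = 24) -> np.ndarray:
    grid = np.unique(np.round(np.geomspace(1, depth, n_points)).astype(np.int64))
    return grid


def alpha_profile(
    table: CountTable,
    tree: PhyloTree | None,
    depth: int,
    iterations: int = 100,
    seed: int | None = None,
    coverage_method: str = "mean_curve",
    curve_points: int = 24,
) -> AlphaProfile:
    """Rarefy ``iterations`` times and average richness, Shannon and PD.

    Each iteration rarefies the table with its own derived child seed and
    evaluates all indices on that rarefied table; the arithmetic mean across
    iterations is reported.  Coverage comes from a Michaelis-Menten fit per
    sample, either on the mean analytic rarefaction curve across iterations
    (default) or as the mean of per-iteration coverages
    (``coverage_method="per_iteration"``).
    """
    if coverage_method not in ("mean_curve", "per_iteration"):
        raise ValueError(f"unknown coverage_method {coverage_method!r}")
    structure = tree.edge_structure(table.otu_ids, strict=False) if tree else None
    if tree is not None:
        tips = set(tree.tip_labels)
        present_any = np.asarray(table.counts).sum(axis=0) > 0
        missing = [o for o, p in zip(table.otu_ids, present_any) if p and o not in tips]
        if missing:
            raise KeyError(f"zOTU(s) with counts missing from the tree: {missing[:5]}")
    grid = _curve_grid(depth, curve_points)
    n = table.n_samples
    rich = np.zeros((iterations, n))
    shan = np.zeros((iterations, n))
    pd_vals = np.full((iterations, n), np.nan)
    curves = np.zeros((iterations, n, grid.size))
    cov_iter = np.full((iterations, n), np.nan)
    for it in range(iterations):
        rng = derive_rng(seed, "alpha-rarefy", it)
        rt = rarefy_counts(table, depth, rng=rng)
        counts = rt.counts
        rich[it] = (counts > 0).sum(axis=1)
        p = counts / depth
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        shan[it] = -plogp.sum(axis=1)
        if structure is not None:
            pd_vals[it] = _faith_pd_matrix(counts, structure)
        for i in range(n):
            curves[it, i] = expected_richness(counts[i], grid)
        if coverage_method == "per_iteration":
            for i in range(n):
                fit = fit_michaelis_menten(grid.astype(float), curves[it, i])
                if fit.converged:
                    cov_iter[it, i] = 100.0 * rich[it, i] / fit.asymptote

    mean_curves = curves.mean(axis=0)
    cols: dict[str, np.ndarray] = {
        "richness": rich.mean(axis=0),
        "shannon": shan.mean(axis=0),
        "faith_pd": pd_vals.mean(axis=0),
    }
    coverage = np.full(n, np.nan)
    exceeds = np.zeros(n, dtype=bool)
    fits: dict[str, MMFit] = {}
    for i, sid in enumerate(table.sample_ids):
        if coverage_method == "mean_curve":
            fit = fit_michaelis_menten(grid.astype(float), mean_curves[i])
            fits[sid] = fit
            if fit.converged:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    coverage[i] = coverage_estimate(cols["richness"][i], fit)
        else:
            coverage[i] = np.nanmean(cov_iter[:, i])
        exceeds[i] = coverage[i] > 100.0
    cols["coverage"] = coverage
    cols["coverage_exceeds"] = exceeds
    data = pd.DataFrame(cols, index=pd.Index(table.sample_ids, name="sample"))
    mean_curve_df = pd.DataFrame(
        mean_curves, index=pd.Index(table.sample_ids, name="sample"), columns=grid
    )
    log.info("alpha profile at depth %d over %d iterations for %d samples",
             depth, iterations, n)
    return AlphaProfile(data, depth, iterations, seed, fits, mean_curve_df)
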