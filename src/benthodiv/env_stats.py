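"""Spearman machinery, depth filtering, chlorophyll integration, and the
environment screens (covariate intercorrelations, alpha-diversity screen,
beta-diversity PERMANOVA screen, function-profile screen).

All screens treat the DNA (entire community) and RNA (active community)
arms separately, handle missing covariate values pairwise-complete, and
flag significance at p <= 0.05 with no multiple-testing correction by
default (a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import derive_rng
from .alpha import AlphaProfile, rarefy_counts
from .beta import MEASURES, pairwise_dissimilarity
from .permanova import (
    epsilon_for,
    gower_center,
    pool_exceedances,
    pseudo_f,
    _draw_perms,
    _permutation_f,
)
from .tables import CountTable, EnvTable, FunctionTable
from .tree import PhyloTree

__all__ = [
    "CorrelationResult",
    "spearman_test",
    "correlation_matrix",
    "drop_low_depth",
    "integrate_chlorophyll",
    "alpha_env_screen",
    "beta_env_screen",
    "function_screen",
    "benjamini_hochberg",
]

log = logging.getLogger("benthodiv.env_stats")

DEFAULT_ALPHA = 0.05
#: excluded by default: below quantification limit at most transect sites
DEFAULT_EXCLUDED_PROPERTIES = ("ammonium", "phosphate")


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p: float
    n: int
    significant: bool
    method: str  # "exact" or "t-approx"


@lru_cache(maxsize=4)
def _all_perms(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int16)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! rank permutations (no ties)."""
    n = len(rx)
    perms = _all_perms(n)
    d = rx[None, :] - ry[perms]
    ssd = (d.astype(float) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * ssd / (n * (n * n - 1))
    return float((np.abs(rho) >= abs(rho_obs) - 1e-12).mean())


def spearman_test(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Missing pairs are dropped (pairwise-complete).  rho is Pearson's
    correlation on midranks.  The p-value is exact (full enumeration of the
    n! rank permutations) when n <= 9 and there are no ties, otherwise the
    t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    use_exact = (method == "exact") or (method == "auto" and n <= 9 and not has_ties)
    if method == "exact" and (n > 9 or has_ties):
        raise ValueError("exact p requires n <= 9 and no ties")
    if use_exact:
        p = _exact_spearman_p(rx, ry, rho)
        how = "exact"
    else:
        denom = max(1.0 - rho * rho, 1e-300)
        t = rho * np.sqrt((n - 2) / denom)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        how = "t-approx"
    return CorrelationResult(names[0], names[1], rho, p, n, p <= alpha, how)


@dataclass
class CorrelationMatrix:
    """All pairwise Spearman tests among environmental properties."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def tidy(self, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
        rows = []
        props = list(self.rho.columns)
        for i, a in enumerate(props):
            for b in props[i + 1:]:
                rows.append(
                    (a, b, self.rho.loc[a, b], self.p.loc[a, b],
                     int(self.n.loc[a, b]), self.p.loc[a, b] <= alpha)
                )
        return pd.DataFrame(
            rows, columns=["property_a", "property_b", "rho", "p", "n", "significant"]
        )


def correlation_matrix(
    env: EnvTable | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    exclude: Sequence[str] = DEFAULT_EXCLUDED_PROPERTIES,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations among covariates, pairwise-complete.

    The diagonal is rho = 1, p = 0 by convention; rho and p are symmetric.
    """
    df = env.data if isinstance(env, EnvTable) else env
    df = df.drop(columns=[c for c in exclude if c in df.columns])
    props = list(df.columns)
    if len(props) < 2:
        raise ValueError("need at least two properties")
    k = len(props)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(df))
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman_test(
                df[props[i]].to_numpy(), df[props[j]].to_numpy(),
                alpha=alpha, names=(props[i], props[j]),
            )
            rho[i, j] = rho[j, i] = res.rho
            p[i, j] = p[j, i] = res.p
            n[i, j] = n[j, i] = res.n
    idx = pd.Index(props)
    return CorrelationMatrix(
        pd.DataFrame(rho, idx, idx), pd.DataFrame(p, idx, idx), pd.DataFrame(n, idx, idx)
    )


def drop_low_depth(table: CountTable, min_depth: int) -> tuple[CountTable, dict]:
    """Remove libraries with fewer than ``min_depth`` reads.

    Mirrors the pre-analysis removal of under-sequenced RNA libraries;
    returns the filtered table and a report naming what was removed.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depths = table.depths()
    removed = depths[depths < min_depth]
    kept = [s for s in table.sample_ids if s not in removed.index]
    if not kept:
        raise ValueError(
            f"all {table.n_samples} samples fall below min_depth={min_depth}"
        )
    report = {
        "min_depth": int(min_depth),
        "removed": {s: int(d) for s, d in removed.items()},
        "n_removed": int(len(removed)),
        "n_kept": len(kept),
    }
    if len(removed):
        log.info(
            "removed %d low-depth sample(s) below %d reads: %s",
            len(removed), min_depth,
            ", ".join(f"{s} ({d})" for s, d in removed.items()),
        )
    return table.select_samples(kept), report


def integrate_chlorophyll(profile, max_depth: float = 500.0) -> float:
    """Sum chlorophyll concentrations measured at depths <= ``max_depth`` m.

    The summed upper-water-column chlorophyll is the proxy used for primary
    productivity above each station.  ``profile`` is a DataFrame with
    ``depth`` and ``concentration`` columns (or a 2-column array).
    """
    if isinstance(profile, pd.DataFrame):
        depth = profile["depth"].to_numpy(dtype=float)
        conc = profile["concentration"].to_numpy(dtype=float)
    else:
        arr = np.asarray(profile, dtype=float)
        depth, conc = arr[:, 0], arr[:, 1]
    if depth.size == 0:
        raise ValueError("empty chlorophyll profile")
    if (depth < 0).any():
        raise ValueError("negative depths in chlorophyll profile")
    return float(conc[depth <= max_depth].sum())


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; screens default to unadjusted)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _screen_properties(env: EnvTable, properties, exclude) -> list[str]:
    if properties is None:
        properties = [c for c in env.properties if c not in exclude]
    return list(properties)


def alpha_env_screen(
    profiles: Mapping[str, AlphaProfile],
    env: EnvTable,
    properties: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude: Sequence[str] = DEFAULT_EXCLUDED_PROPERTIES,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman screen of every alpha index against every covariate.

    ``profiles`` maps fraction label ("DNA"/"RNA") to its alpha profile;
    fractions are never pooled.  A constant index yields an NA row with a
    diagnostic note rather than a hard failure.
    """
    indices = ["richness", "shannon", "faith_pd", "coverage"]
    rows = []
    for fraction in sorted(profiles):
        profile = profiles[fraction]
        samples = list(profile.data.index)
        envf = env.aligned_to(samples)
        props = _screen_properties(envf, properties, exclude)
        for index in indices:
            vals = profile.data[index].to_numpy(dtype=float)
            for prop in props:
                cov = envf.data[prop].to_numpy(dtype=float)
                try:
                    res = spearman_test(vals, cov, alpha=alpha, names=(index, prop))
                    rows.append((index, prop, fraction, res.rho, res.p,
                                 res.n, res.significant, ""))
                except ValueError as err:
                    rows.append((index, prop, fraction, np.nan, np.nan,
                                 int(np.isfinite(cov).sum()), False, str(err)))
    out = pd.DataFrame(
        rows,
        columns=["response", "property", "fraction", "rho", "p", "n",
                 "significant", "note"],
    )
    if adjust:
        ok = out["p"].notna()
        out.loc[ok, "p_adjusted"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
        out["significant"] = out.get("p_adjusted", out["p"]) <= alpha
    return out


def beta_env_screen(
    table: CountTable,
    env: EnvTable,
    tree: PhyloTree | None,
    depths: Mapping[str, int],
    rarefactions: int = 999,
    n_perm: int = 999,
    seed: int | None = None,
    measures: Sequence[str] = MEASURES,
    properties: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude: Sequence[str] = DEFAULT_EXCLUDED_PROPERTIES,
) -> pd.DataFrame:
    """Repeated-rarefaction PERMANOVA of every (property, measure, fraction).

    Each fraction arm is filtered to its rarefaction depth first (removed
    libraries are logged), then one shared sequence of rarefied tables per
    fraction feeds all measures and properties, which keeps the screen exact
    but avoids re-rarefying per cell.  Samples with a missing value in the
    tested covariate are dropped for that covariate only.
    """
    if any(m.startswith("unifrac") for m in measures) and tree is None:
        raise ValueError("UniFrac measures requested but no tree supplied")
    arms = table.split_fractions() if table.fraction else {"all": table}
    rows = []
    for fraction in sorted(arms):
        depth = int(depths[fraction]) if fraction in depths else int(min(depths.values()))
        sub, report = drop_low_depth(arms[fraction], depth)
        envf = env.aligned_to(sub.sample_ids)
        props = _screen_properties(envf, properties, exclude)
        n = sub.n_samples
        # per-property complete-case masks and permutation draws
        masks = {}
        for prop in props:
            vals = envf.data[prop].to_numpy(dtype=float)
            masks[prop] = np.isfinite(vals)
        acc: dict[tuple[str, str], dict] = {
            (prop, m): {"F": [], "R2": [], "exceed": 0}
            for prop in props for m in measures
        }
        for r in range(rarefactions):
            rng_r = derive_rng(seed, f"screen-rarefy-{fraction}", r)
            rarefied = rarefy_counts(sub, depth, rng=rng_r)
            for m in measures:
                Dv = pairwise_dissimilarity(rarefied.counts, m, tree, sub.otu_ids)
                for prop in props:
                    mask = masks[prop]
                    vals = envf.data[prop].to_numpy(dtype=float)[mask]
                    G = gower_center(Dv[np.ix_(mask, mask)])
                    F_obs, R2 = pseudo_f(G, vals)
                    eps = epsilon_for(F_obs)
                    perms = _draw_perms(
                        derive_rng(seed, f"screen-perm-{fraction}-{prop}", r),
                        int(mask.sum()), n_perm,
                    )
                    F_perm = _permutation_f(G, vals, perms)
                    cell = acc[(prop, m)]
                    cell["F"].append(F_obs)
                    cell["R2"].append(R2)
                    cell["exceed"] += int((F_perm >= F_obs - eps).sum())
        for prop in props:
            for m in measures:
                cell = acc[(prop, m)]
                p = pool_exceedances(cell["exceed"], rarefactions * n_perm)
                rows.append(
                    (prop, fraction, m, float(np.mean(cell["F"])),
                     float(np.mean(cell["R2"])), p, p <= alpha,
                     int(masks[prop].sum()), rarefactions, n_perm)
                )
    return pd.DataFrame(
        rows,
        columns=["property", "fraction", "measure", "F", "R2", "p",
                 "significant", "n", "rarefactions", "permutations"],
    )


def function_screen(
    functions: FunctionTable,
    env: EnvTable,
    n_perm: int = 999,
    seed: int | None = None,
    properties: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude: Sequence[str] = DEFAULT_EXCLUDED_PROPERTIES,
) -> pd.DataFrame:
    """PERMANOVA of predicted functional profiles against each covariate.

    Functional profiles are relative abundances, so no rarefaction is done;
    the distance is weighted Bray-Curtis.  Fractions (taken from the
    environment table's fraction labels) are screened separately.
    """
    samples = functions.sample_ids
    envf = env.aligned_to(samples)
    if envf.fraction is not None:
        groups = {
            frac: [s for s in samples if envf.fraction[s] == frac]
            for frac in sorted(envf.fraction.unique())
        }
    else:
        groups = {"all": samples}
    rows = []
    for fraction, ids in groups.items():
        if len(ids) < 3:
            continue
        sub = functions.data.loc[ids].to_numpy(dtype=float)
        enva = envf.aligned_to(ids)
        props = _screen_properties(enva, properties, exclude)
        Dv = _bray_matrix(sub)
        for prop in props:
            vals = enva.data[prop].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            G = gower_center(Dv[np.ix_(mask, mask)])
            F_obs, R2 = pseudo_f(G, vals[mask])
            eps = epsilon_for(F_obs)
            perms = _draw_perms(
                derive_rng(seed, f"fn-perm-{fraction}-{prop}", 0),
                int(mask.sum()), n_perm,
            )
            F_perm = _permutation_f(G, vals[mask], perms)
            p = pool_exceedances(int((F_perm >= F_obs - eps).sum()), n_perm)
            rows.append((prop, fraction, "bray_weighted", F_obs, R2, p,
                         p <= alpha, int(mask.sum())))
    return pd.DataFrame(
        rows,
        columns=["property", "fraction", "measure", "F", "R2", "p",
                 "significant", "n"],
    )


def _bray_matrix(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(mat[i] - mat[i + 1:]).sum(axis=1)
        tot = (mat[i] + mat[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            D[i, i + 1:] = np.where(tot > 0, diff / tot, 0.0)
    return D + D.T
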