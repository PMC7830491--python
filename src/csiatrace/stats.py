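"""Group-comparison statistics for corrected per-sample isotope values.

The battery mirrors standard practice in isotope ecology: variance-
homogeneity diagnostics (Levene, Bartlett) to justify the parametric or
rank-based branch; Kruskal-Wallis with pairwise Wilcoxon rank-sum post hoc
and Benjamini-Hochberg adjustment for delta15N; additive two-way ANOVA with
sequential (Type-I) sums of squares and Tukey HSD for per-AA comparisons;
distance-based PERMANOVA (adonis-style sequential partitioning on Euclidean
distances, free row permutation) for the multivariate essential-AA delta13C
fingerprint; and non-metric multidimensional scaling for ordination.

The PERMANOVA partitioning is implemented here from first principles
(Gower-centered distance matrix, projection sums of squares); univariate
tests delegate to scipy/statsmodels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TestResult",
    "PermanovaResult",
    "OrdinationResult",
    "kruskal_wallis",
    "pairwise_wilcoxon_bh",
    "bh_adjust",
    "two_way_anova_tukey",
    "permanova",
    "nmds",
    "variance_checks",
]


@dataclass
class TestResult:
    """A single hypothesis test: statistic, p, and the groups involved."""

    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {str(g): values[groups == g] for g in pd.unique(groups)}


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H (midrank tie correction, chi-square p).

    Delegates to the standard implementation; all-identical input is the
    degenerate case H = 0, p = 1 (flagged) rather than an error.
    """
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need >= 2 groups")
    arrays = list(by.values())
    if len(np.unique(np.concatenate(arrays))) < 2:
        warnings.warn("all values identical: Kruskal-Wallis degenerate", stacklevel=2)
        return TestResult(
            test="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            groups=tuple(by),
            n_per_group=tuple(len(a) for a in arrays),
            note="degenerate: all values identical",
        )
    stat, p = sps.kruskal(*arrays)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        groups=tuple(by),
        n_per_group=tuple(len(a) for a in arrays),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pairwise_wilcoxon_bh(values, groups, exact_max_n: int = 50) -> list[TestResult]:
    """All pairwise two-sided Wilcoxon rank-sum tests with BH adjustment
    across the pairwise family.

    The exact null distribution is used when both groups have fewer than
    ``exact_max_n`` observations and the pooled data are tie-free; the
    normal approximation (with tie correction) otherwise.  Pairs with a
    group of n < 2 are skipped with a warning.
    """
    by = _split_groups(values, groups)
    results: list[TestResult] = []
    for a, b in itertools.combinations(by, 2):
        xa, xb = by[a], by[b]
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group with n < 2", stacklevel=2)
            continue
        pooled = np.concatenate([xa, xb])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (tie_free and max(len(xa), len(xb)) < exact_max_n) else "asymptotic"
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        results.append(
            TestResult(
                test="wilcoxon_rank_sum",
                statistic=float(stat),
                p_value=float(p),
                groups=(a, b),
                n_per_group=(len(xa), len(xb)),
                note=method,
            )
        )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results


@dataclass
class AnovaResult:
    """Additive two-way ANOVA with sequential SS, plus Tukey HSD per factor."""

    table: pd.DataFrame  # rows: factor_a, factor_b, Residual; columns df, sum_sq, mean_sq, F, p
    tukey: dict[str, pd.DataFrame]
    alpha: float


def two_way_anova_tukey(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
) -> AnovaResult:
    """Additive (no-interaction) two-way ANOVA, sequential (Type-I) SS in the
    order ``factor_a`` then ``factor_b``, with Tukey HSD on each factor.

    An empty cell in the two-factor design is an error (the additive fit
    would silently extrapolate); a constant response yields F = 0, p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    full = set(itertools.product(data[factor_a].unique(), data[factor_b].unique()))
    empty = sorted(full - set(cells.index))
    if empty:
        raise ValueError(f"empty design cells: {empty}")

    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        dfa = data[factor_a].nunique() - 1
        dfb = data[factor_b].nunique() - 1
        table = pd.DataFrame(
            {
                "df": [dfa, dfb, len(y) - 1 - dfa - dfb],
                "sum_sq": [0.0, 0.0, 0.0],
                "mean_sq": [0.0, 0.0, 0.0],
                "F": [0.0, 0.0, np.nan],
                "p": [1.0, 1.0, np.nan],
            },
            index=[factor_a, factor_b, "Residual"],
        )
        return AnovaResult(table=table, tukey={}, alpha=alpha)

    model = smf.ols(f"Q('{response}') ~ C(Q('{factor_a}')) + C(Q('{factor_b}'))", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    anova = anova.rename(
        index={f"C(Q('{factor_a}'))": factor_a, f"C(Q('{factor_b}'))": factor_b}
    )
    table = pd.DataFrame(
        {
            "df": anova["df"].astype(int),
            "sum_sq": anova["sum_sq"],
            "mean_sq": anova["sum_sq"] / anova["df"],
            "F": anova["F"],
            "p": anova["PR(>F)"],
        }
    )
    tukey = {}
    for f in (factor_a, factor_b):
        if data[f].nunique() >= 2:
            res = pairwise_tukeyhsd(y, data[f].astype(str).to_numpy(), alpha=alpha)
            tukey[f] = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return AnovaResult(table=table, tukey=tukey, alpha=alpha)


@dataclass
class PermanovaResult:
    """Adonis-style PERMANOVA table with per-factor permutation p-values."""

    factors: list[str]
    df: dict[str, int]
    sum_sq: dict[str, float]
    mean_sq: dict[str, float]
    pseudo_f: dict[str, float]
    r_squared: dict[str, float]
    p_value: dict[str, float]
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Table formatted with the conventional adonis column layout."""
        rows = []
        for f in self.factors:
            rows.append(
                [f, self.df[f], self.sum_sq[f], self.mean_sq[f], self.pseudo_f[f], self.r_squared[f], self.p_value[f]]
            )
        rows.append(
            ["Residuals", self.df["Residuals"], self.sum_sq["Residuals"], self.mean_sq["Residuals"],
             np.nan, self.r_squared["Residuals"], np.nan]
        )
        rows.append(["Total", self.df["Total"], self.sum_sq["Total"], np.nan, np.nan, 1.0, np.nan])
        return pd.DataFrame(rows, columns=["term", "Df", "Sum Sqs", "Mean Sqs", "F. Model", "R2", "p"]).set_index("term")


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d_squared @ J


def _hat(X: np.ndarray) -> np.ndarray:
    # projection onto the column space of X via thin QR
    q, _ = np.linalg.qr(X)
    return q @ q.T


def _dummy(levels: np.ndarray) -> np.ndarray:
    cats = pd.unique(levels)
    return np.column_stack([(levels == c).astype(float) for c in cats[1:]])


def _ge_with_ties(f_perm: np.ndarray, f_obs: np.ndarray) -> np.ndarray:
    """Count a permuted statistic as >= the observed one, treating values
    equal to relative precision as ties."""
    with np.errstate(invalid="ignore"):
        return (f_perm >= f_obs) | np.isclose(f_perm, f_obs, rtol=1e-9, atol=1e-12)


def _pseudo_f(ss: np.ndarray, ss_res: float, df_arr: np.ndarray, df_res: int, ss_total: float) -> np.ndarray:
    """Per-term pseudo-F.  A residual SS that is zero to relative precision
    (a perfectly explained partition) is treated as exactly zero, yielding
    an infinite F for any term with positive SS -- float noise at the 1e-14
    level must not scramble permutation tie counting on degenerate toys."""
    eps = 1e-10 * max(abs(ss_total), 1.0)
    if ss_res <= eps:
        return np.where(ss > eps, np.inf, 0.0)
    return (ss / df_arr) / (ss_res / df_res)


def permanova(
    data,
    factors: Mapping[str, Sequence] | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: str = "free",
    precomputed: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances.

    Sequential (adonis-style) partitioning of the Gower-centered distance
    matrix for an additive multi-factor model, in the given factor order.
    Pseudo-F per factor uses the residual mean square of the full model.
    p-values come from free permutation of sample rows, with the observed
    configuration counted in numerator and denominator; ``permutations=
    "exact"`` enumerates every relabeling (n <= 9 only), in which case the
    observed identity permutation is part of the enumeration.

    ``data`` is a samples x variables matrix, or a distance matrix when
    ``precomputed`` is true.
    """
    if isinstance(factors, pd.DataFrame):
        factor_items = [(c, factors[c].to_numpy()) for c in factors.columns]
    else:
        factor_items = [(k, np.asarray(v)) for k, v in factors.items()]

    X = np.asarray(data, dtype=float)
    D = X if precomputed else squareform(pdist(X, metric="euclidean"))
    n = D.shape[0]
    for name, lv in factor_items:
        if len(lv) != n:
            raise ValueError(f"factor {name!r} length {len(lv)} != n samples {n}")
    if n_perm < 99 and permutations == "free":
        warnings.warn(f"n_perm = {n_perm} gives coarse p-value resolution", stacklevel=2)

    G = _gower_center(D**2)
    names = [name for name, _ in factor_items]
    dfs = {name: len(pd.unique(lv)) - 1 for name, lv in factor_items}
    df_res = n - 1 - sum(dfs.values())
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    # Sequential projectors: H_0 = intercept, H_k adds factor k's dummies.
    # They depend only on the design, not on G, so they are built once and
    # each (permuted) G costs a handful of elementwise products.
    dummies = [_dummy(lv) for _, lv in factor_items]
    ones = np.ones((n, 1))
    Xcur = ones
    H_prev = _hat(Xcur)
    projectors = []
    for Z in dummies:
        Xcur = np.hstack([Xcur, Z])
        H_cur = _hat(Xcur)
        projectors.append(H_cur - H_prev)
        H_prev = H_cur
    resid_projector = np.eye(n) - H_prev

    def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        """Sequential SS per term and residual SS for a (permuted) G,
        via tr(P G) = sum(P * G) for symmetric G."""
        ss = np.array([np.sum(P * Gm) for P in projectors])
        return ss, float(np.sum(resid_projector * Gm))

    ss_obs, ss_res_obs = term_stats(G)
    ss_total = float(np.trace(G))
    ms = {name: float(ss_obs[k] / dfs[name]) for k, name in enumerate(names)}
    ms_res = ss_res_obs / df_res
    df_arr = np.array([dfs[nm] for nm in names], dtype=float)
    f_obs = _pseudo_f(ss_obs, ss_res_obs, df_arr, df_res, ss_total)

    # Permutation null: permute rows/columns of G (equivalently relabel samples).
    if permutations == "exact":
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        count = np.zeros(len(names))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            Gp = G[np.ix_(idx, idx)]
            ss_p, ss_res_p = term_stats(Gp)
            f_p = _pseudo_f(ss_p, ss_res_p, df_arr, df_res, ss_total)
            count += _ge_with_ties(f_p, f_obs)
            total += 1
        pvals = count / total
        n_used = total
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(names))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            ss_p, ss_res_p = term_stats(Gp)
            f_p = _pseudo_f(ss_p, ss_res_p, df_arr, df_res, ss_total)
            count += _ge_with_ties(f_p, f_obs)
        pvals = (count + 1.0) / (n_perm + 1.0)
        n_used = n_perm
        exhaustive = False

    sum_sq = {name: float(ss_obs[k]) for k, name in enumerate(names)}
    sum_sq["Residuals"] = float(ss_res_obs)
    sum_sq["Total"] = ss_total
    df_out = dict(dfs)
    df_out["Residuals"] = df_res
    df_out["Total"] = n - 1
    mean_sq = dict(ms)
    mean_sq["Residuals"] = float(ms_res)
    r2 = {name: float(ss_obs[k] / ss_total) for k, name in enumerate(names)}
    r2["Residuals"] = float(ss_res_obs / ss_total)
    return PermanovaResult(
        factors=names,
        df=df_out,
        sum_sq=sum_sq,
        mean_sq=mean_sq,
        pseudo_f={name: float(f_obs[k]) for k, name in enumerate(names)},
        r_squared=r2,
        p_value={name: float(pvals[k]) for k, name in enumerate(names)},
        n_perm=n_used,
        seed=seed,
        exhaustive=exhaustive,
    )


@dataclass
class OrdinationResult:
    """A 2-D non-metric MDS embedding.  Only inter-point distance ranks are
    interpretable; the configuration is arbitrary up to rigid motion."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    seed: int | None

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be >= 0")


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    G = _gower_center(D**2)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    distance_matrix: np.ndarray,
    dims: int = 2,
    seed: int | None = None,
    n_random_starts: int = 20,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 by isotonic-regression
    majorization (SMACOF), with random starts plus one metric (classical
    scaling) start; the lowest-stress solution is kept."""
    from sklearn.manifold import smacof

    D = np.asarray(distance_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or (D < 0).any():
        raise ValueError("distance matrix must be square, symmetric, non-negative")

    best_coords, best_stress = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero-stress exact fits
        coords, stress, n_it = smacof(
            D,
            metric=False,
            n_components=dims,
            init=_classical_mds(D, dims),
            n_init=1,
            max_iter=max_iter,
            random_state=seed,
            normalized_stress=True,
            return_n_iter=True,
        )
        best_coords, best_stress, best_iter = coords, float(stress), n_it
        if n_random_starts > 0:
            coords, stress, n_it = smacof(
                D,
                metric=False,
                n_components=dims,
                n_init=n_random_starts,
                max_iter=max_iter,
                random_state=seed,
                normalized_stress=True,
                return_n_iter=True,
            )
            if stress < best_stress:
                best_coords, best_stress, best_iter = coords, float(stress), n_it
    return OrdinationResult(
        coordinates=best_coords,
        stress=best_stress,
        converged=best_iter < max_iter,
        seed=seed,
    )


def variance_checks(values, groups) -> dict[str, TestResult]:
    """Levene (center = median) and Bartlett variance-homogeneity tests,
    reported to justify the parametric vs rank-based branch.  Groups of
    n < 2 are dropped; constant data are flagged as degenerate."""
    by = {g: a for g, a in _split_groups(values, groups).items() if len(a) >= 2}
    if len(by) < 2:
        raise ValueError("need >= 2 groups with n >= 2")
    arrays = list(by.values())
    names = tuple(by)
    ns = tuple(len(a) for a in arrays)
    if len(np.unique(np.concatenate(arrays))) < 2:
        warnings.warn("constant data: variance tests degenerate", stacklevel=2)
        degenerate = TestResult(
            test="degenerate", statistic=float("nan"), p_value=float("nan"),
            groups=names, n_per_group=ns, note="constant data",
        )
        return {"levene": degenerate, "bartlett": degenerate}
    lev_stat, lev_p = sps.levene(*arrays, center="median")
    bar_stat, bar_p = sps.bartlett(*arrays)
    return {
        "levene": TestResult("levene_median", float(lev_stat), float(lev_p), names, ns),
        "bartlett": TestResult("bartlett", float(bar_stat), float(bar_p), names, ns),
    }
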