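"""Rank-based association statistics for age–alteration analyses.

The toolkit mirrors the classical R workflow for cohort association screens:
Spearman rank correlation with permutation-quality p-values (exact enumeration
at small n, AS 89 Edgeworth expansion at moderate n, t-approximation with
ties), percentile bootstrap confidence intervals for rho (B=1000 by default),
Wilcoxon rank-sum and Fisher exact tests for two-group comparisons,
Benjamini–Hochberg FDR within each analysis family, and local median curves
over an age axis (±10-year windows by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "LocalMedianCurve",
    "spearman_rho",
    "spearman_test",
    "bootstrap_rho_ci",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "local_median_curve",
    "assign_age_groups",
    "stratified_age_correlation",
    "gene_wise_age_correlation",
    "load_by_mutation_status",
]


@dataclass
class AssociationResult:
    """One Spearman association row: rho, bootstrap CI, p, and (optionally) q."""

    variable: str
    n: int
    rho: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "rho": self.rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "flag": self.flag,
        }


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman_rho(x, y) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (average ranks on ties)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# p-values: exact enumeration (n<=9, no ties), AS 89 Edgeworth (moderate n),
# t-approximation fallback (ties or large n)
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 9
_EDGEWORTH_MAX_N = 1290
_S_DISTRIBUTIONS: dict[int, np.ndarray] = {}


def _s_distribution(n: int) -> np.ndarray:
    """Counts of S = sum of squared rank differences over all n! permutations."""
    dist = _S_DISTRIBUTIONS.get(n)
    if dist is None:
        base = np.arange(1, n + 1)
        max_s = n * (n * n - 1) // 3
        counts = np.zeros(max_s + 1, dtype=np.int64)
        for perm in itertools.permutations(range(1, n + 1)):
            counts[int(np.sum((base - perm) ** 2))] += 1
        dist = _S_DISTRIBUTIONS[n] = counts
    return dist


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p: P(|rho_perm| >= |rho_obs|), tie-free."""
    counts = _s_distribution(n)
    m = n * (n * n - 1) / 3.0  # S at rho = -1; rho = 1 - 6S/(n(n^2-1)) = 1 - 2S/m
    s_values = np.arange(counts.size)
    rho_perm = 1.0 - 2.0 * s_values / m
    mask = np.abs(rho_perm) >= abs(rho) - 1e-12
    return float(counts[mask].sum() / counts.sum())


def _rho_excess_kurtosis(n: int) -> float:
    """Exact excess kurtosis of Spearman's rho under the permutation null.

    Follows from the exact fourth moment
    E[rho^4] = 3(25n^3 - 38n^2 - 35n + 72) / (25 n (n+1) (n-1)^3)
    together with Var(rho) = 1/(n-1); the closed form reproduces full
    permutation enumeration exactly for n = 5..9.
    """
    e4 = 3.0 * (25.0 * n**3 - 38.0 * n**2 - 35.0 * n + 72.0) / (25.0 * n * (n + 1) * (n - 1))
    return e4 - 3.0


def _edgeworth_spearman_p(rho: float, n: int) -> float:
    """Two-sided Edgeworth-corrected permutation p-value (tie-free ranks).

    rho is standardized by its exact null sd 1/sqrt(n-1) with a half-step
    continuity correction (S moves in steps of 2, i.e. rho in steps of
    12/(n^3-n)); the symmetric-case Edgeworth term uses the exact null excess
    kurtosis. In the extreme tail the correction can push the tail mass to
    <= 0 (rho is platykurtic), in which case the t-approximation is used
    instead of reporting an exact zero.
    """
    x = (abs(rho) - 6.0 / (n**3 - n)) * math.sqrt(n - 1.0)
    g2 = _rho_excess_kurtosis(n)
    tail = sps.norm.sf(x) + g2 / 24.0 * (x**3 - 3.0 * x) * sps.norm.pdf(x)
    if tail <= 0.0:
        return _t_approx_spearman_p(rho, n)
    return float(min(1.0, 2.0 * tail))


def _t_approx_spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2.0) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _spearman_p(rho: float, n: int, has_ties: bool) -> float:
    if math.isnan(rho):
        return float("nan")
    if has_ties or n > _EDGEWORTH_MAX_N:
        p = _t_approx_spearman_p(rho, n)
    elif n <= _EXACT_MAX_N:
        p = _exact_spearman_p(rho, n)
    else:
        p = _edgeworth_spearman_p(rho, n)
    # a permutation p-value is never exactly 0 (|rho|=1 hits the t-approx limit)
    return max(p, 5e-324)


def spearman_test(
    x,
    y,
    variable: str = "",
    ci: bool = True,
    B: int = 1000,
    seed: int | None = None,
) -> AssociationResult:
    """Spearman association of two variables with permutation-quality p-value.

    Pairwise-complete observations are used; n >= 4 is required. A constant
    vector yields an undefined rho and a flagged result rather than an error.
    The 95% CI is a percentile bootstrap over B paired resamples.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 4:
        return AssociationResult(variable, n, float("nan"), flag="n<4")
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return AssociationResult(variable, n, rho, flag="constant")
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    p = _spearman_p(rho, n, has_ties)
    lo = hi = float("nan")
    if ci:
        lo, hi = bootstrap_rho_ci(x, y, B=B, seed=seed)
    return AssociationResult(variable, n, rho, lo, hi, p)


def _rowwise_spearman(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two equal-shape (B, n) rank matrices."""
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xc, yc)
    den = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_rho_ci(
    x, y, B: int = 1000, seed: int | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for Spearman rho over B paired resamples.

    Degenerate replicates (a resampled vector is constant, so rho is
    undefined) are skipped. Deterministic given ``seed``.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 4:
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    xr = sps.rankdata(x[idx], axis=1)
    yr = sps.rankdata(y[idx], axis=1)
    rho_b = _rowwise_spearman(xr, yr)
    rho_b = rho_b[np.isfinite(rho_b)]
    if rho_b.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rho_b, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order-preserving).

    NaN entries are passed through as NaN; all finite entries must lie in
    (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        vals = p[ok]
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when both groups have <= 25 observations and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U statistic of the first group, p). Completely tied
    data gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= 25:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table (zero margin → p = 1)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


@dataclass
class LocalMedianCurve:
    """Median of a variable in sliding age windows, with bootstrap 95% CIs."""

    grid: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    window_halfwidth: float
    n_in_window: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.grid,
                "median": self.median,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n": self.n_in_window,
            }
        )


def local_median_curve(
    ages,
    values,
    halfwidth: float = 10.0,
    B: int = 1000,
    seed: int | None = None,
    grid=None,
    min_n: int = 3,
) -> LocalMedianCurve:
    """Local median of ``values`` along the age axis.

    At each grid age g the median of observations with |age − g| <= halfwidth
    is taken; its 95% CI is a percentile bootstrap of the within-window sample.
    Grid points with fewer than ``min_n`` observations are NaN. Default grid:
    integer ages spanning the data.
    """
    ages, values = _complete_pairs(ages, values)
    if ages.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if grid is None:
        grid = np.arange(math.floor(ages.min()), math.floor(ages.max()) + 1)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    med = np.full(grid.size, np.nan)
    lo = np.full(grid.size, np.nan)
    hi = np.full(grid.size, np.nan)
    n_in = np.zeros(grid.size, dtype=int)
    for i, g in enumerate(grid):
        window = values[np.abs(ages - g) <= halfwidth]
        n_in[i] = window.size
        if window.size < min_n:
            continue
        med[i] = np.median(window)
        boot = np.median(window[rng.integers(0, window.size, size=(B, window.size))], axis=1)
        lo[i], hi[i] = np.quantile(boot, [0.025, 0.975])
    return LocalMedianCurve(grid, med, lo, hi, halfwidth, n_in)


#: age-class edges used for subgroup screens; intervals are left-open
#: right-closed, e.g. (50, 60]
AGE_GROUP_EDGES = (50, 60, 70, 80)


def assign_age_groups(ages, edges: tuple[float, ...] = AGE_GROUP_EDGES) -> pd.Series:
    """Bin ages into left-open right-closed classes: <=50, 50-60, …, >80."""
    ages = pd.Series(ages)
    bins = [-np.inf, *edges, np.inf]
    labels = [f"<={edges[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(edges[:-1], edges[1:])]
    labels += [f">{edges[-1]}"]
    return pd.cut(ages, bins=bins, labels=labels, right=True)


def stratified_age_correlation(
    values,
    ages,
    strata,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-stratum Spearman of values vs age, plus a global row, BH across rows.

    Strata with n < 4 are emitted with undefined statistics. Observations with
    a missing stratum label still enter the global row.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    ages = pd.Series(np.asarray(ages, dtype=float))
    strata = pd.Series(strata).astype(object).reset_index(drop=True)
    if strata.dropna().empty:
        raise ValueError("no stratum labels supplied")
    rows = [spearman_test(values, ages, variable="global", B=B, seed=seed)]
    levels = pd.unique(strata.dropna())
    for k, level in enumerate(levels):
        mask = (strata == level).to_numpy()
        rows.append(
            spearman_test(
                values[mask], ages[mask], variable=str(level), B=B,
                seed=None if seed is None else seed + k + 1,
            )
        )
    table = pd.DataFrame([r.to_dict() for r in rows]).set_index("variable")
    table["q_value"] = bh_fdr(table["p_value"])
    return table


def gene_wise_age_correlation(
    matrix: pd.DataFrame,
    ages: pd.Series,
    ci: bool = False,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spearman of each gene row vs age, BH-FDR across genes.

    ``matrix`` is gene×patient; its columns are aligned to ``ages``'s index.
    Genes with constant values are flagged and excluded from the FDR family.
    Bootstrap CIs are off by default (one screen may span thousands of genes).
    """
    common = matrix.columns.intersection(ages.index)
    if common.empty:
        raise ValueError("no overlap between matrix columns and age roster")
    sub = matrix[common].to_numpy(dtype=float)
    age_vec = ages.loc[common].to_numpy(dtype=float)
    rows = []
    for g, gene in enumerate(matrix.index):
        res = spearman_test(
            sub[g], age_vec, variable=str(gene), ci=ci, B=B,
            seed=None if seed is None else seed + g,
        )
        rows.append(res.to_dict())
    table = pd.DataFrame(rows).set_index("variable")
    table.index.name = "gene"
    table["q_value"] = bh_fdr(table["p_value"])
    return table


def load_by_mutation_status(
    loads: pd.Series,
    gene_status: pd.DataFrame,
    age_groups: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Wilcoxon of load in mutated vs wild-type patients, per gene per age group.

    ``gene_status`` is a gene×patient boolean matrix (True = mutated);
    ``age_groups`` a per-patient categorical. Within each age group, BH-FDR is
    applied across genes; groups where either arm is empty are flagged. Also
    returns, per group, the fraction of patients with >=1 listed gene mutated.
    """
    patients = loads.index.intersection(gene_status.columns).intersection(age_groups.index)
    if patients.empty:
        raise ValueError("no common patients across loads, status and age groups")
    loads = loads.loc[patients]
    status = gene_status[patients].astype(bool)
    groups = pd.Series(age_groups).loc[patients]
    rows = []
    fractions = {}
    for group in pd.unique(groups.dropna()):
        members = patients[(groups == group).to_numpy()]
        fractions[str(group)] = float(status[members].any(axis=0).mean())
        for gene in status.index:
            mutated = status.loc[gene, members]
            a = loads.loc[members[mutated.to_numpy()]]
            b = loads.loc[members[~mutated.to_numpy()]]
            if a.empty or b.empty:
                rows.append((str(gene), str(group), a.size, b.size, np.nan, np.nan, "empty-arm"))
                continue
            stat, p = wilcoxon_rank_sum(a, b)
            rows.append((str(gene), str(group), a.size, b.size, stat, p, ""))
    table = pd.DataFrame(
        rows, columns=["gene", "age_group", "n_mutated", "n_wildtype", "statistic", "p_value", "flag"]
    )
    table["q_value"] = np.nan
    for group in table["age_group"].unique():
        mask = table["age_group"] == group
        table.loc[mask, "q_value"] = bh_fdr(table.loc[mask, "p_value"])
    return table, pd.Series(fractions, name="fraction_any_mutated")
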