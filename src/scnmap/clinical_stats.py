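"""Group comparisons and clinical correlation tables.

Links seed and peak-cluster volumes to cognitive and neuropsychiatric
scores: Mann-Whitney U for two-group comparisons of continuous variables,
Spearman correlations (optionally adjusted for confounders via partial
correlation on ranks), Hardy-Weinberg equilibrium checks of the genotype
distribution, Neuropsychiatric Inventory (NPI) totals, and the assembly of
per-stratum correlation tables with significance flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MannWhitneyResult",
    "SpearmanResult",
    "mann_whitney",
    "spearman",
    "hwe_chisq",
    "npi_total",
    "CorrelationTables",
    "build_correlation_tables",
    "group_comparison_table",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact enumeration null when both samples have n <= 12 and no
    ties are present; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 12 and y.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    dof: int
    n_covariates: int = 0


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    adjust: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
) -> SpearmanResult:
    """Spearman correlation, optionally adjusted for confounders.

    Unadjusted: Pearson correlation of average ranks.  Adjusted: partial
    correlation of the rank-transformed x and y given the rank-transformed
    covariates (residualize both on the covariate ranks, correlate the
    residuals).  p is from the t approximation with n - 2 - k degrees of
    freedom, k the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    k = 0
    if adjust is not None:
        cov_df = pd.DataFrame(adjust)
        k = cov_df.shape[1]
        Z = np.column_stack(
            [np.ones(n)]
            + [stats.rankdata(np.asarray(cov_df[c], dtype=float)) for c in cov_df.columns]
        )
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            raise ValueError("correlation undefined after adjustment (constant ranks)")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    dof = n - 2 - k
    if dof <= 0:
        raise ValueError("not enough observations for the covariate set")
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) >= 1.0:
        p = 0.0
    else:
        t_stat = rho_c * np.sqrt(dof / (1.0 - rho_c**2))
        p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    return SpearmanResult(rho_c, p, n, dof, k)


def hwe_chisq(n_GG: int, n_GA: int, n_AA: int) -> tuple[float, float]:
    """Hardy-Weinberg 1-dof chi-square from genotype counts.

    Expected counts are n*p^2, 2npq, n*q^2 at the observed allele
    frequency p = (2 GG + GA) / 2n.  Monomorphic samples return chi2 = 0.
    """
    counts = np.array([n_GG, n_GA, n_AA], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p_hat = (2 * counts[0] + counts[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    if p_hat == 0.0 or q_hat == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def npi_total(items: Sequence[Sequence[int]]) -> int:
    """NPI total: sum of frequency x severity over the 12 items (0-144).

    ``items`` is 12 pairs (frequency 0-4, severity 0-3); out-of-range
    values raise.
    """
    arr = np.asarray(items, dtype=int)
    if arr.shape != (12, 2):
        raise ValueError(f"expected 12 (frequency, severity) pairs, got shape {arr.shape}")
    freq, sev = arr[:, 0], arr[:, 1]
    if np.any((freq < 0) | (freq > 4)):
        raise ValueError("frequency items must be in 0..4")
    if np.any((sev < 0) | (sev > 3)):
        raise ValueError("severity items must be in 0..3")
    return int((freq * sev).sum())


@dataclass
class CorrelationTables:
    """Spearman and linear-regression tables: tests x (volume, stratum).

    ``rho``/``p_raw``/``p_adj``/``n`` share a MultiIndex column layout of
    (volume, stratum); ``flags`` marks 'a' (p<0.05) and 'b' (p<0.01) on
    the BH-adjusted p.  ``slope``/``slope_p`` hold the parallel per-cell
    linear-regression (score on volume) results.
    """

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame
    slope: pd.DataFrame
    slope_p: pd.DataFrame
    adjust_covariates: tuple[str, ...] = ()


def _flag(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "a"
    return ""


def build_correlation_tables(
    cohort: pd.DataFrame,
    volumes: pd.DataFrame,
    tests: Sequence[str],
    strata: Sequence[str] = ("G", "AA"),
    stratum_col: str = "stratum",
    adjust: Sequence[str] = ("age", "education"),
    fdr_q: float = 0.05,
) -> CorrelationTables:
    """Per-stratum correlation tables of behavioural tests against volumes.

    For every (test, volume, stratum) cell, computes the adjusted Spearman
    correlation (confounder set defaults to age + education) plus a plain
    linear-regression slope and p of score on volume.  Missing scores are
    handled pairwise-complete with the per-cell n reported.  Within each
    (volume, stratum) column the Spearman p-values are BH-adjusted across
    tests; flags mark adjusted p < 0.05 ('a') and < 0.01 ('b').
    """
    if not set(volumes.index) >= set(cohort.index):
        raise ValueError("volumes must be indexed like the cohort table")
    columns = pd.MultiIndex.from_product(
        [list(volumes.columns), list(strata)], names=["volume", "stratum"]
    )
    shape = (len(tests), len(columns))
    rho = pd.DataFrame(np.full(shape, np.nan), index=list(tests), columns=columns)
    p_raw = rho.copy()
    n_tab = rho.copy()
    slope = rho.copy()
    slope_p = rho.copy()

    for vol_name in volumes.columns:
        for stratum in strata:
            sel = cohort[stratum_col] == stratum
            sub = cohort.loc[sel]
            vols = volumes.loc[sub.index, vol_name]
            for test in tests:
                if test not in cohort.columns:
                    raise ValueError(f"score column {test!r} missing from cohort")
                pair = pd.DataFrame(
                    {"v": np.asarray(vols, dtype=float),
                     "s": np.asarray(sub[test], dtype=float)},
                    index=sub.index,
                )
                cov_cols = [c for c in adjust if c in sub.columns]
                for c in cov_cols:
                    pair[c] = np.asarray(sub[c], dtype=float)
                pair = pair.dropna()
                cell = (vol_name, stratum)
                n_tab.loc[test, cell] = len(pair)
                if len(pair) < 4 + len(cov_cols):
                    continue
                try:
                    res = spearman(
                        pair["v"], pair["s"],
                        adjust=pair[cov_cols] if cov_cols else None,
                    )
                except ValueError:
                    continue
                rho.loc[test, cell] = res.rho
                p_raw.loc[test, cell] = res.p
                lin = stats.linregress(pair["v"], pair["s"])
                slope.loc[test, cell] = lin.slope
                slope_p.loc[test, cell] = lin.pvalue

    # BH across tests within each (volume, stratum) column
    p_adj = p_raw.copy()
    for cell in columns:
        col = p_raw[cell]
        ok = col.notna()
        if ok.sum():
            _, adj, *_ = multipletests(col[ok], alpha=fdr_q, method="fdr_bh")
            p_adj.loc[ok, cell] = adj
    flags = p_adj.map(_flag)
    return CorrelationTables(
        rho=rho, p_raw=p_raw, p_adj=p_adj, n=n_tab, flags=flags,
        slope=slope, slope_p=slope_p,
        adjust_covariates=tuple(adjust),
    )


def group_comparison_table(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    stratum_col: str = "stratum",
    strata: tuple[str, str] = ("G", "AA"),
) -> pd.DataFrame:
    """Demographics-style comparison: per-group mean (SD) and Mann-Whitney p."""
    rows = []
    a, b = strata
    for var in variables:
        xa = cohort.loc[cohort[stratum_col] == a, var].dropna()
        xb = cohort.loc[cohort[stratum_col] == b, var].dropna()
        res = mann_whitney(xa, xb)
        rows.append(
            {
                "variable": var,
                f"mean_{a}": xa.mean(),
                f"sd_{a}": xa.std(ddof=1),
                f"mean_{b}": xb.mean(),
                f"sd_{b}": xb.std(ddof=1),
                "test": f"mann-whitney-{res.method}",
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
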