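"""Group statistics: mixed-design repeated-measures ANOVA, effect sizes,
partial correlations, FDR correction and a-priori sample-size computation.

The mixed rmANOVA is implemented with the univariate sums-of-squares
approach on orthonormal within-subject contrasts, which yields
Greenhouse–Geisser epsilons and the Mauchly sphericity test from the same
contrast covariance. It supports one or two within-subject factors crossed
with an optional between-subject factor, one observation per design cell
per subject, balanced groups. pingouin backs the ANCOVA change-score model
and partial correlations; statsmodels backs Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult", "mixed_rmanova", "ancova_change", "posthoc_pairwise",
    "cohens_d", "partial_correlation", "fdr_correct", "analytic_power",
    "required_sample_size", "standardized_mean_difference", "SmdResult",
]


@dataclass
class AnovaResult:
    """Per-effect F table with sphericity diagnostics and optional post-hocs."""

    table: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    design: dict = field(default_factory=dict)

    def effect(self, source: str) -> pd.Series:
        hit = self.table[self.table["Source"] == source]
        if hit.empty:
            raise KeyError(f"no effect {source!r}; have "
                           f"{list(self.table['Source'])}")
        return hit.iloc[0]

    def p(self, source: str) -> float:
        row = self.effect(source)
        return float(row["p_GG"] if row["GG_applied"] else row["p"])


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) × k orthonormal rows spanning the mean-zero subspace."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    return q[:, : k - 1].T


def _gg_mauchly(Z: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Greenhouse–Geisser epsilon and Mauchly p from contrast scores Z."""
    q = Z.shape[1]
    if q == 1:
        return 1.0, 1.0
    # covariance pooled within groups
    resid = np.vstack([Z[groups == g] - Z[groups == g].mean(axis=0)
                       for g in np.unique(groups)])
    dof = len(Z) - len(np.unique(groups))
    S = resid.T @ resid / dof
    tr = np.trace(S)
    eps = tr ** 2 / (q * np.trace(S @ S))
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    # Mauchly's W
    eig = np.linalg.eigvalsh(S)
    eig = np.maximum(eig, 1e-300)
    W = np.prod(eig) / (np.mean(eig) ** q)
    f = 1.0 - (2 * q ** 2 + q + 2) / (6.0 * q * dof)
    chi2 = -f * dof * np.log(max(W, 1e-300))
    df_m = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df_m))
    return eps, p


def mixed_rmanova(data: pd.DataFrame, dv: str,
                  within: str | list[str], between: str | None = None,
                  subject: str = "participant",
                  covariate: str | None = None,
                  mauchly_alpha: float = 0.05,
                  posthoc: bool = False) -> AnovaResult:
    """Mixed-design repeated-measures ANOVA.

    Parameters
    ----------
    data : long-format table, one row per subject × within-cell.
    dv : dependent variable column.
    within : one or two within-subject factor columns.
    between : optional between-subject factor column.
    covariate : optional subject-level covariate; delegates to the
        change-score ANCOVA model (requires a two-level within factor).
    mauchly_alpha : Greenhouse–Geisser correction is applied to an effect
        when its Mauchly sphericity p falls below this threshold.
    """
    within = [within] if isinstance(within, str) else list(within)
    if covariate is not None:
        return ancova_change(data, dv, covariate, within[0], between, subject)
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")

    levels = {w: sorted(data[w].unique()) for w in within}
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean", dropna=False)
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing design cells for subject(s) {bad}")
    # order columns as the cartesian product of factor levels
    cells = list(itertools.product(*[levels[w] for w in within]))
    wide = wide[[c if len(within) > 1 else c[0] for c in cells]]
    Y = wide.to_numpy()
    n_subj, p_cells = Y.shape

    if between is not None:
        gmap = data.groupby(subject)[between].first()
        groups = gmap.loc[wide.index].to_numpy()
    else:
        groups = np.zeros(n_subj, dtype=int)
    uniq = np.unique(groups)
    G = len(uniq)
    if n_subj - G < 1:
        raise ValueError("not enough subjects for the error terms")

    rows = []

    # between-subject effect and its error (subject means, weight p_cells)
    m = Y.mean(axis=1)
    grand = m.mean()
    gmeans = {g: m[groups == g].mean() for g in uniq}
    ss_b = p_cells * sum((groups == g).sum() * (gmeans[g] - grand) ** 2
                         for g in uniq)
    ss_sb = p_cells * sum(((m[groups == g] - gmeans[g]) ** 2).sum()
                          for g in uniq)
    df_b, df_sb = G - 1, n_subj - G
    if between is not None:
        F = (ss_b / df_b) / (ss_sb / df_sb) if ss_sb > 0 else np.inf
        rows.append({"Source": between, "SS": ss_b, "df1": df_b, "df2": df_sb,
                     "F": F, "p": float(sps.f.sf(F, df_b, df_sb)),
                     "eps_GG": np.nan, "Mauchly_p": np.nan,
                     "GG_applied": False, "p_GG": np.nan})

    # within effects: every non-empty subset of within factors
    contrasts = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    ones = {w: np.full((1, len(levels[w])), 1.0 / np.sqrt(len(levels[w])))
            for w in within}
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            K = np.array([[1.0]])
            for w in within:
                K = np.kron(K, contrasts[w] if w in subset else ones[w])
            Z = Y @ K.T
            q = K.shape[0]
            zbar = Z.mean(axis=0)
            zg = {g: Z[groups == g].mean(axis=0) for g in uniq}
            ss_w = n_subj * float(zbar @ zbar)
            ss_wb = sum((groups == g).sum() * float((zg[g] - zbar) @ (zg[g] - zbar))
                        for g in uniq)
            ss_err = sum(float(((Z[groups == g] - zg[g]) ** 2).sum())
                         for g in uniq)
            df_err = q * (n_subj - G)
            eps, mauchly_p = _gg_mauchly(Z, groups)
            gg = mauchly_p < mauchly_alpha

            name = " * ".join(subset)
            specs = [(name, ss_w, q)]
            if between is not None:
                specs.append((f"{name} * {between}", ss_wb, q * (G - 1)))
            mse = ss_err / df_err
            for src, ss, df1 in specs:
                F = (ss / df1) / mse
                p = float(sps.f.sf(F, df1, df_err))
                p_gg = float(sps.f.sf(F, df1 * eps, df_err * eps))
                rows.append({"Source": src, "SS": ss, "df1": df1,
                             "df2": df_err, "F": F, "p": p, "eps_GG": eps,
                             "Mauchly_p": mauchly_p, "GG_applied": gg,
                             "p_GG": p_gg})

    table = pd.DataFrame(rows)
    result = AnovaResult(table, design={"within": within, "between": between,
                                        "subject": subject, "dv": dv})
    if posthoc:
        result.posthoc = _auto_posthoc(data, dv, within, between, subject,
                                       table, mauchly_alpha)
    return result


def _auto_posthoc(data, dv, within, between, subject, table,
                  alpha=0.05) -> pd.DataFrame:
    """Bonferroni pairwise comparisons for every significant effect."""
    frames = []
    for _, row in table.iterrows():
        p_use = row["p_GG"] if row["GG_applied"] else row["p"]
        if p_use >= alpha or " * " in str(row["Source"]):
            continue
        factor = row["Source"]
        paired = factor in within
        frames.append(posthoc_pairwise(data, dv, factor, subject, paired))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["factor", "A", "B", "t", "p",
                                       "p_bonf", "d"]))


def posthoc_pairwise(data: pd.DataFrame, dv: str, factor: str,
                     subject: str = "participant",
                     paired: bool = True) -> pd.DataFrame:
    """Bonferroni-corrected pairwise t-tests across the levels of a factor."""
    levels = sorted(data[factor].unique())
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        if paired:
            wide = data.pivot_table(index=subject, columns=factor, values=dv,
                                    aggfunc="mean")
            x, y = wide[a].dropna(), wide[b].dropna()
            t, p = sps.ttest_rel(x, y)
            d = cohens_d(x.to_numpy(), y.to_numpy(), paired=True)
        else:
            x = data.loc[data[factor] == a].groupby(subject)[dv].mean()
            y = data.loc[data[factor] == b].groupby(subject)[dv].mean()
            t, p = sps.ttest_ind(x, y)
            d = cohens_d(x.to_numpy(), y.to_numpy(), paired=False)
        rows.append({"factor": factor, "A": a, "B": b, "t": float(t),
                     "p": float(p), "p_bonf": min(1.0, float(p) * len(pairs)),
                     "d": d})
    return pd.DataFrame(rows)


def ancova_change(data: pd.DataFrame, dv: str, covariate: str,
                  within: str = "time", between: str | None = "group",
                  subject: str = "participant",
                  pre_level: str = "pre") -> AnovaResult:
    """Covariate model: post − pre change regressed on group + covariate.

    The subject-level covariate (e.g. baseline single-pulse MEP amplitude)
    enters as a between-participant regressor on the change scores.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean")
    levels = list(wide.columns)
    if len(levels) != 2:
        raise ValueError(f"change-score ANCOVA needs a 2-level within factor,"
                         f" got levels {levels}")
    post_level = [l for l in levels if l != pre_level][0]
    per_subj = data.groupby(subject).first()
    df = pd.DataFrame({
        "change": wide[post_level] - wide[pre_level],
        covariate: per_subj[covariate],
    })
    if between is not None:
        df[between] = per_subj[between]
        aov = pg.ancova(data=df.reset_index(), dv="change", covar=covariate,
                        between=between)
    else:
        raise ValueError("change-score ANCOVA requires a between factor")
    table = pd.DataFrame({
        "Source": aov["Source"], "SS": aov["SS"], "df1": aov["DF"],
        "df2": np.nan, "F": aov["F"], "p": aov["p_unc"],
        "eps_GG": np.nan, "Mauchly_p": np.nan, "GG_applied": False,
        "p_GG": np.nan})
    return AnovaResult(table, design={"model": "ancova_change", "dv": dv,
                                      "covariate": covariate})


# ---------------------------------------------------------------------------
# effect sizes, correlations, FDR

def cohens_d(x: np.ndarray, y: np.ndarray, paired: bool = False) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        diff = x - y
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of the paired differences")
        return float(diff.mean() / sd)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / pooled)


def partial_correlation(data: pd.DataFrame,
                        var_pairs: list[tuple[str, str]],
                        controls: list[str]) -> pd.DataFrame:
    """Partial r (and p) for each pair, controlling for ``controls``."""
    rows = []
    for x, y in var_pairs:
        if x == y:
            rows.append({"x": x, "y": y, "r": 1.0, "p": 0.0,
                         "n": int(data[x].notna().sum())})
            continue
        cols = [x, y, *controls]
        sub = data[cols].dropna()
        if len(sub) < len(controls) + 3:
            raise ValueError(f"too few complete cases for ({x}, {y}) given "
                             f"{len(controls)} control(s)")
        if controls:
            res = pg.partial_corr(data=sub, x=x, y=y, covar=list(controls))
        else:
            res = pg.corr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "r": float(res["r"].iloc[0]),
                     "p": float(res["p_val"].iloc[0]),
                     "n": int(res["n"].iloc[0])})
    return pd.DataFrame(rows)


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# power

def analytic_power(d: float, n: int, alpha: float = 0.05,
                   design: str = "paired") -> float:
    """Two-tailed t-test power from the noncentral t distribution.

    ``design``: 'paired'/'one-sample' (df = n−1, ncp = d√n) or 'two-sample'
    (n per group, df = 2n−2, ncp = d√(n/2)).
    """
    if design in ("paired", "one-sample"):
        df, ncp = n - 1, d * np.sqrt(n)
    elif design == "two-sample":
        df, ncp = 2 * n - 2, d * np.sqrt(n / 2.0)
    else:
        raise ValueError(f"unknown design {design!r}")
    if df < 1:
        return 0.0
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    if not np.isfinite(power):
        # extreme noncentrality overflows the nct evaluation; in that regime
        # |T| > tcrit iff chi_df < ncp*sqrt(df)/tcrit to high accuracy
        power = float(sps.chi2.cdf(df * (ncp / tcrit) ** 2, df))
    return power


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.8,
                         design: str = "paired", n_max: int = 100_000) -> int:
    """Smallest n whose analytic power reaches the target."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, n_max + 1):
        if analytic_power(d, n, alpha, design) >= power:
            return n
    raise RuntimeError(f"power {power} unreachable within n <= {n_max}")


@dataclass
class SmdResult:
    smd: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


def standardized_mean_difference(x: np.ndarray, y: np.ndarray,
                                 ci: float = 0.95) -> SmdResult:
    """Between-group standardized mean difference of change scores with CI."""
    d = cohens_d(x, y, paired=False)
    n1, n2 = len(x), len(y)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * (n1 + n2 - 2)))
    z = sps.norm.ppf(0.5 + ci / 2.0)
    return SmdResult(d, d - z * se, d + z * se, n1, n2)
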