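"""Group-level inference for the connectivity tables.

The central piece is a balanced mixed (split-plot) ANOVA supporting any
number of within-subject factors crossed with between-subject factors —
the study design is treatment × time (within) × sex (between), stratified by
ROI pair.  Sums of squares come from the classical inclusion–exclusion over
marginal totals, which for balanced complete designs coincides with Type
I/II/III.  Each within effect is tested against its interaction with subjects
(nested in the between groups); sphericity is checked with Mauchly's W and a
Greenhouse-Geisser adjustment of the degrees of freedom is reported alongside
(and used when sphericity is rejected).

Post-hoc machinery: Tukey's HSD on the studentized range distribution,
Hedges g effect sizes with the small-sample correction J = 1 − 3/(4·df − 1),
and paired / one-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "EffectSize",
    "TTestResult",
    "mixed_anova",
    "tukey_hsd",
    "hedges_g",
    "t_tests",
    "paired_t",
    "one_sample_t",
]


@dataclass
class AnovaResult:
    """Effects table plus per-within-effect sphericity diagnostics.

    ``table`` columns: effect, ss, df1, df2, ms, F, p, epsilon, df1_gg,
    df2_gg, p_gg, p_reported, error_ss, zero_variance.  ``p_reported`` follows
    the stated policy: the GG-corrected p whenever Mauchly rejects at the
    sphericity alpha (or always, under ``force_gg``), the raw p otherwise.
    """

    table: pd.DataFrame
    sphericity: pd.DataFrame
    within: tuple[str, ...]
    between: tuple[str, ...]
    design: str = ""
    errors: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]


@dataclass
class EffectSize:
    g: float
    ci: tuple[float, float]
    paired: bool
    degenerate: bool = False


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Balanced mixed ANOVA
# ---------------------------------------------------------------------------

def _subsets(items: Sequence[str]):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def _effect_name(term: Sequence[str]) -> str:
    return " × ".join(term)


def _check_design(d: pd.DataFrame, dv, within, between, subject) -> None:
    cols = [subject, *within, *between, dv]
    missing = [c for c in cols if c not in d.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    if d[dv].isna().any():
        raise ValueError("dv contains missing values")
    # each subject must sit in exactly one between cell
    if between:
        per_sub = d.groupby(subject, sort=False)[list(between)].nunique()
        bad = per_sub[(per_sub > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValueError(f"subjects appear in multiple between-groups: {bad}")
    # exactly one observation per subject × within cell
    counts = d.groupby([subject, *within], sort=False, observed=True).size()
    if (counts > 1).any():
        dup = counts[counts > 1].index.tolist()[:5]
        raise ValueError(f"non-unique subject rows per within-cell, e.g. {dup}")
    n_cells = int(np.prod([d[f].nunique() for f in within])) if within else 1
    per_sub_n = d.groupby(subject, sort=False).size()
    incomplete = per_sub_n[per_sub_n != n_cells]
    if len(incomplete):
        raise ValueError(
            f"missing within-cells for subjects {incomplete.index.tolist()}"
        )
    if between:
        group_sizes = d.groupby(list(between), sort=False)[subject].nunique()
        if (group_sizes < 2).any():
            raise ValueError("need ≥ 2 subjects per between-group")
        if group_sizes.nunique() != 1:
            raise ValueError("between-groups must be balanced (equal subject counts)")


def _marginal_ss(d: pd.DataFrame, dv: str, by: Sequence[str]) -> float:
    """R(u) = Σ over cells of ``by`` of (cell total)² / (cell size)."""
    if not by:
        return float(d[dv].sum() ** 2 / len(d))
    g = d.groupby(list(by), sort=False, observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels−1) × levels orthonormal rows spanning the complement of 1."""
    basis = np.eye(levels) - 1.0 / levels
    u, s, _ = np.linalg.svd(basis)
    return u[:, : levels - 1].T


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    between: Sequence[str] = (),
    subject: str = "subject",
    sphericity_alpha: float = 0.05,
    force_gg: bool = False,
) -> AnovaResult:
    """Balanced mixed ANOVA with all main effects and interactions.

    ``within`` factors are repeated over subjects; ``between`` factors group
    subjects; the design must be complete and balanced (one observation per
    subject × within-cell, equal group sizes).  Every within effect with more
    than one numerator df gets Mauchly's sphericity test and Greenhouse-
    Geisser-adjusted degrees of freedom; the reported p switches to the
    adjusted one when sphericity is rejected at ``sphericity_alpha`` (always,
    if ``force_gg``).  Two-level within factors satisfy sphericity trivially
    (ε = 1, Mauchly skipped).
    """
    within, between = tuple(within), tuple(between)
    d = data.copy()
    _check_design(d, dv, within, between, subject)
    factors = within + between
    n = len(d)
    n_subj = d[subject].nunique()
    levels = {f: d[f].nunique() for f in factors}
    n_groups = int(np.prod([levels[f] for f in between])) if between else 1

    # marginal-total building blocks
    def R(u: Sequence[str], with_subject: bool = False) -> float:
        by = list(u) + ([subject] if with_subject else [])
        return _marginal_ss(d, dv, by)

    ss_total = float(((d[dv] - d[dv].mean()) ** 2).sum())

    # effect sums of squares by inclusion-exclusion
    effects = [t for t in _subsets(factors) if t]
    ss_effect: dict[tuple[str, ...], float] = {}
    for term in effects:
        ss = 0.0
        for u in _subsets(term):
            ss += (-1) ** (len(term) - len(u)) * R(u)
        ss_effect[term] = max(ss, 0.0)

    # error strata: one per within-subset (∅ = subjects within groups)
    ss_error: dict[tuple[str, ...], float] = {}
    df_error: dict[tuple[str, ...], float] = {}
    for w in _subsets(within):
        ss = 0.0
        for u in _subsets(w):
            sign = (-1) ** (len(w) - len(u))
            ss += sign * (R(u, with_subject=True) - R(tuple(u) + between))
        ss_error[tuple(w)] = max(ss, 0.0)
        df_w = int(np.prod([levels[f] - 1 for f in w])) if w else 1
        df_error[tuple(w)] = df_w * (n_subj - n_groups)

    # sphericity diagnostics per within term with ≥ 2 numerator df
    sph_rows, eps_of, mauchly_p_of = [], {}, {}
    wide = d.pivot_table(index=subject, columns=list(within), values=dv,
                         observed=True) if within else None
    groups_of_subject = (
        d.groupby(subject, sort=False)[list(between)].first().astype(str).agg("|".join, axis=1)
        if between else pd.Series("all", index=d[subject].unique())
    )
    for w in _subsets(within):
        if not w:
            continue
        p_dim = int(np.prod([levels[f] - 1 for f in w]))
        if p_dim < 2:
            eps_of[tuple(w)] = 1.0
            mauchly_p_of[tuple(w)] = np.nan
            continue
        y, cell_cols = _within_means(wide, within, w)
        c = _kron_contrasts(cell_cols, w, d)
        scores = y @ c.T
        # pool covariance within between-groups
        resid = np.empty_like(scores)
        grp = groups_of_subject.loc[list(y.index)].to_numpy()
        for g in np.unique(grp):
            sel = grp == g
            resid[sel] = scores[sel] - scores[sel].mean(axis=0)
        dof = n_subj - n_groups
        s_mat = resid.T @ resid / dof
        tr = np.trace(s_mat)
        eps = float(tr**2 / (p_dim * np.trace(s_mat @ s_mat))) if tr > 0 else 1.0
        eps = float(np.clip(eps, 1.0 / p_dim, 1.0))
        det = float(np.linalg.det(s_mat))
        if det <= 0 or tr <= 0:
            w_stat, chi2, chi_df, p_m = np.nan, np.nan, np.nan, np.nan
        else:
            w_stat = det / (tr / p_dim) ** p_dim
            chi_df = p_dim * (p_dim + 1) / 2 - 1
            corr = 1.0 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * dof)
            chi2 = -dof * corr * np.log(w_stat)
            p_m = float(stats.chi2.sf(chi2, chi_df))
        eps_of[tuple(w)] = eps
        mauchly_p_of[tuple(w)] = p_m
        sph_rows.append({
            "effect": _effect_name(w), "mauchly_w": w_stat, "chi2": chi2,
            "df": chi_df, "p": p_m, "epsilon_gg": eps,
        })

    rows = []
    for term in effects:
        w = tuple(f for f in term if f in within)
        df1 = int(np.prod([levels[f] - 1 for f in term]))
        ss = ss_effect[term]
        err_ss, err_df = ss_error[w], df_error[w]
        eps = eps_of.get(w, 1.0)
        p_mauchly = mauchly_p_of.get(w, np.nan)
        zero_var = err_ss <= 1e-300
        if zero_var:
            f_val = p_val = p_gg = np.nan
        else:
            f_val = (ss / df1) / (err_ss / err_df)
            p_val = float(stats.f.sf(f_val, df1, err_df))
            p_gg = float(stats.f.sf(f_val, df1 * eps, err_df * eps))
        use_gg = force_gg or (np.isfinite(p_mauchly) and p_mauchly < sphericity_alpha)
        rows.append({
            "effect": _effect_name(term), "ss": ss, "df1": df1, "df2": err_df,
            "ms": ss / df1 if df1 else np.nan, "F": f_val, "p": p_val,
            "epsilon": eps, "df1_gg": df1 * eps, "df2_gg": err_df * eps,
            "p_gg": p_gg, "p_reported": p_gg if use_gg else p_val,
            "error_ss": err_ss, "zero_variance": zero_var,
        })
    table = pd.DataFrame(rows)
    errors = {
        _effect_name(w) or "subjects": {"ss": ss_error[w], "df": df_error[w]}
        for w in map(tuple, _subsets(within))
    }
    # bookkeeping identity: total = effects + all error strata (balanced design)
    decomposed = table["ss"].sum() + sum(e["ss"] for e in errors.values())
    if ss_total > 0 and abs(decomposed - ss_total) > 1e-6 * max(ss_total, 1.0):
        raise AssertionError(
            f"SS decomposition failed: {decomposed} vs total {ss_total}"
        )
    return AnovaResult(
        table=table,
        sphericity=pd.DataFrame(sph_rows),
        within=within, between=between,
        design=f"{len(within)}-within × {len(between)}-between",
        errors=errors,
    )


def _within_means(wide: pd.DataFrame, within: Sequence[str], w: Sequence[str]):
    """Subject × (cells of w) means, averaging over the other within factors."""
    y = wide.copy()
    if len(within) == 1:
        cols = [(c,) for c in y.columns]
    else:
        cols = list(y.columns)
    keep_idx = [within.index(f) for f in w]
    grouped: dict[tuple, list] = {}
    for col, full in zip(y.columns, cols):
        key = tuple(full[i] for i in keep_idx)
        grouped.setdefault(key, []).append(col)
    keys = sorted(grouped)
    out = np.column_stack([y[grouped[k]].mean(axis=1).to_numpy() for k in keys])
    return pd.DataFrame(out, index=y.index), keys


def _kron_contrasts(cell_keys: Sequence[tuple], w: Sequence[str], d: pd.DataFrame):
    """Kronecker product of per-factor orthonormal contrasts, ordered to match
    the sorted cell keys."""
    per_factor_levels = [sorted(d[f].unique()) for f in w]
    c = np.ones((1, 1))
    for lv in per_factor_levels:
        c = np.kron(c, _orthonormal_contrasts(len(lv)))
    expected = [tuple(k) for k in _cartesian(per_factor_levels)]
    if list(cell_keys) != expected:
        order = [expected.index(tuple(k)) for k in cell_keys]
        c = c[:, order]
    return c


def _cartesian(level_lists):
    out = [()]
    for lv in level_lists:
        out = [t + (x,) for t in out for x in lv]
    return out


# ---------------------------------------------------------------------------
# Post-hoc tests and effect sizes
# ---------------------------------------------------------------------------

def tukey_hsd(
    means: Mapping[str, float],
    mse: float,
    df_error: float,
    n_per_cell: int | Mapping[str, int],
) -> pd.DataFrame:
    """Tukey's HSD corrected p for every cell pair.

    q = |m_a − m_b| / sqrt(MSE/2 · (1/n_a + 1/n_b)) referred to the
    studentized range distribution with k cells and ``df_error`` df
    (Tukey-Kramer for unequal n).  Zero MSE flags every comparison degenerate.
    """
    cells = list(means)
    if len(cells) < 2:
        raise ValueError("need ≥ 2 cells")
    k = len(cells)
    rows = []
    for a, b in combinations(cells, 2):
        na = n_per_cell if isinstance(n_per_cell, int) else n_per_cell[a]
        nb = n_per_cell if isinstance(n_per_cell, int) else n_per_cell[b]
        diff = means[a] - means[b]
        if mse <= 0:
            rows.append({"cell_a": a, "cell_b": b, "diff": diff, "q": np.nan,
                         "p": np.nan, "degenerate": True})
            continue
        se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append({"cell_a": a, "cell_b": b, "diff": diff, "q": q,
                     "p": min(p, 1.0), "degenerate": False})
    return pd.DataFrame(rows)


def hedges_g(x, y, paired: bool = False, ci_level: float = 0.95) -> EffectSize:
    """Hedges g = J · (mean_x − mean_y) / s with J = 1 − 3/(4·df − 1).

    Unpaired: s is the pooled SD, df = n₁ + n₂ − 2.  Paired: s pools the two
    conditions' SDs (the convention that keeps paired and unpaired magnitudes
    comparable, rather than standardising by the difference SD), df = n − 1.
    The CI is the large-sample normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n ≥ 2 per sample")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must be matched")
    n1, n2 = len(x), len(y)
    if paired:
        df = n1 - 1
        s = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    else:
        df = n1 + n2 - 2
        s = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    diff = x.mean() - y.mean()
    if s == 0:
        return EffectSize(g=np.nan, ci=(np.nan, np.nan), paired=paired, degenerate=True)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * diff / s
    if paired:
        se = np.sqrt(1.0 / n1 + g**2 / (2.0 * (n1 - 1)))
    else:
        se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * df))
    zc = stats.norm.isf((1.0 - ci_level) / 2.0)
    return EffectSize(g=float(g), ci=(float(g - zc * se), float(g + zc * se)),
                      paired=paired)


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired t-test (degenerate-flagged on zero difference variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs matched samples with n ≥ 2")
    d = x - y
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return TTestResult(t=0.0, df=len(d) - 1, p=1.0)
        return TTestResult(t=np.nan, df=len(d) - 1, p=np.nan, degenerate=True)
    res = stats.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=len(x) - 1, p=float(res.pvalue))


def one_sample_t(x, mu: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test against ``mu``."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need n ≥ 2")
    if x.std(ddof=1) == 0:
        if np.isclose(x.mean(), mu):
            return TTestResult(t=0.0, df=len(x) - 1, p=1.0)
        return TTestResult(t=np.nan, df=len(x) - 1, p=np.nan, degenerate=True)
    res = stats.ttest_1samp(x, mu)
    return TTestResult(t=float(res.statistic), df=len(x) - 1, p=float(res.pvalue))


def t_tests(x, y=None, mu: float = 0.0, paired: bool = True) -> TTestResult:
    """Dispatch: paired (x vs y) or one-sample (x vs mu) two-tailed t-test."""
    if y is None:
        return one_sample_t(x, mu)
    if not paired:
        res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
        return TTestResult(t=float(res.statistic), df=len(x) + len(y) - 2,
                           p=float(res.pvalue))
    return paired_t(x, y)
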