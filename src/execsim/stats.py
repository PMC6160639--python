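"""Behavioral scoring and the ANOVA machinery.

Implements the full split-plot repeated-measures ANCOVA by explicit
projection algebra: Type-III sums of squares from effect-coded designs,
the within-participant stratum analyzed in an orthonormal contrast
space, Greenhouse-Geisser epsilon from the residual contrast covariance,
Mauchly's sphericity test, eta squared against the corrected total sum
of squares, and Bonferroni post hoc comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from execsim.core import (
    COND_DIVIDED,
    DISTRACTED_CONDITIONS,
    TASK_TYPES,
)

logger = logging.getLogger(__name__)

BLOCK_EXCLUSION_SDS = 3.0


# ---------------------------------------------------------------------------
# Block scoring and exclusion
# ---------------------------------------------------------------------------


def block_scores(scored_events: pd.DataFrame, participant: str = None) -> pd.DataFrame:
    """Percent correct per block (trials only; rest/instruction skipped)."""
    ev = scored_events[
        scored_events["task"].isin(["attention", "nback"])
        & (scored_events["condition"] != "rest")
    ]
    ev = ev.assign(_correct=ev["correct"].astype(float))
    out = (
        ev.groupby("block", sort=False)
        .agg(
            task_family=("task", "first"),
            condition=("condition", "first"),
            n_trials=("_correct", "size"),
            score=("_correct", "mean"),
        )
        .reset_index()
    )
    out["score"] *= 100.0
    out.insert(0, "participant", participant)
    return out


def exclude_outlier_blocks(blocks: pd.DataFrame, family_column: str = "task_family"):
    """Drop blocks scoring strictly below mean - 3 SD within a task family.

    The mean/SD are pooled over all blocks of the family (one global
    cutoff per family).  A block at exactly the cutoff is retained.
    Returns (retained blocks, exclusion log).
    """
    retained = []
    log = {}
    for family, grp in blocks.groupby(family_column, sort=False):
        scores = grp["score"].to_numpy(dtype=float)
        mean, sd = float(scores.mean()), float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
        cutoff = mean - BLOCK_EXCLUSION_SDS * sd
        keep = grp[grp["score"] >= cutoff]
        retained.append(keep)
        log[family] = dict(
            mean=mean,
            sd=sd,
            cutoff=cutoff,
            n_blocks=len(grp),
            n_removed=int(len(grp) - len(keep)),
        )
    out = pd.concat(retained, axis=0) if retained else blocks.iloc[:0]
    return out, log


def compute_task_scores(
    scored_events: pd.DataFrame, retained_blocks=None
) -> dict:
    """The four executive accuracy scores for one participant.

    DivA: divided-attention trials; DistrA: the three distracted
    conditions pooled; WM: 2-back nonswitch trials; ModSwi: post-switch
    trials of the 1- and 2-back levels pooled.  Scores with zero
    eligible trials come back as NaN with a warning.
    """
    ev = scored_events[
        scored_events["task"].isin(["attention", "nback"])
        & (scored_events["condition"] != "rest")
    ]
    if retained_blocks is not None:
        ev = ev[ev["block"].isin(set(retained_blocks))]

    selections = {
        "DivA": ev["condition"] == COND_DIVIDED,
        "DistrA": ev["condition"].isin(DISTRACTED_CONDITIONS),
        "WM": (ev["condition"] == "2back") & (ev["switch"] == "nonswitch"),
        "ModSwi": (ev["condition"].isin(["1back", "2back"]))
        & (ev["switch"] == "post_switch"),
    }
    scores = {}
    for name, sel in selections.items():
        sub = ev[sel]
        if len(sub) == 0:
            warnings.warn(f"no eligible trials for score {name}; returning NaN")
            scores[name] = np.nan
        else:
            scores[name] = 100.0 * sub["correct"].astype(float).mean()
    return scores


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is None:
        covariates = []
    if isinstance(covariates, pd.DataFrame):
        covariates = [covariates[c] for c in covariates.columns]
    for cov in covariates:
        arr = np.asarray(cov)
        if arr.dtype.kind in "OUSb":  # categorical -> dummy coding
            levels = pd.unique(arr)
            for lev in levels[1:]:
                cols.append((arr == lev).astype(float))
        else:
            arr = arr.astype(float)
            if np.ptp(arr) > 0:
                cols.append(arr)
    return np.column_stack(cols)


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of OLS residuals of x and y on the covariates.

    Returns ``(r, p)`` with df = n - 2 - #covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    design = _covariate_matrix(covariates, n)
    k = design.shape[1] - 1
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if df <= 0:
        return r, np.nan
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


# ---------------------------------------------------------------------------
# Design helpers (effect coding + Type-III projections)
# ---------------------------------------------------------------------------


def _effect_code(series: pd.Series) -> np.ndarray:
    values = np.asarray(series)
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        return np.empty((len(values), 0))
    cols = []
    for lev in levels[:-1]:
        col = np.where(values == lev, 1.0, 0.0)
        col[values == levels[-1]] = -1.0
        cols.append(col)
    return np.column_stack(cols)


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    return np.column_stack(cols) if cols else np.empty((a.shape[0], 0))


def _between_terms(df: pd.DataFrame, factors, covariate=None) -> dict:
    """Ordered term -> column-block mapping (effect coded, covariate centered)."""
    n = len(df)
    terms = {"intercept": np.ones((n, 1))}
    blocks = {}
    for f in factors:
        blocks[f] = _effect_code(df[f])
        terms[f] = blocks[f]
    for fa, fb in combinations(factors, 2):
        inter = _interaction(blocks[fa], blocks[fb])
        if inter.shape[1]:
            terms[f"{fa}:{fb}"] = inter
    if covariate is not None:
        cov = df[covariate].to_numpy(dtype=float)
        terms[covariate] = (cov - cov.mean())[:, None]
    return terms


def _projection(x: np.ndarray) -> np.ndarray:
    if x.shape[1] == 0:
        return np.zeros((x.shape[0], x.shape[0]))
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _type3_ss(terms: dict, response: np.ndarray) -> dict:
    """Type-III SS per term; response may be multi-column (SS = trace)."""
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    full = np.hstack(list(terms.values()))
    p_full = _projection(full)
    out = {}
    n = y.shape[0]
    for name in terms:
        others = [v for k, v in terms.items() if k != name]
        reduced = np.hstack(others) if others else np.empty((n, 0))
        p_red = _projection(reduced)
        delta = p_full - p_red
        out[name] = float(np.trace(y.T @ delta @ y))
    resid = np.eye(len(y)) - p_full
    out["__error__"] = float(np.trace(y.T @ resid @ y))
    out["__rank__"] = int(np.round(np.trace(p_full)))
    return out


def _term_df(terms: dict, name: str) -> int:
    return terms[name].shape[1]


# ---------------------------------------------------------------------------
# Greenhouse-Geisser and Mauchly
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(a: int) -> np.ndarray:
    """(a-1) x a matrix: orthonormal rows, each orthogonal to the constant."""
    base = np.eye(a) - np.ones((a, a)) / a
    q, _ = np.linalg.qr(base)
    return q[:, : a - 1].T


def greenhouse_geisser_epsilon(sigma: np.ndarray) -> float:
    """Epsilon from the residual covariance in orthonormal contrast space."""
    s = np.asarray(sigma, dtype=float)
    k = s.shape[0]  # = a - 1
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (k * tr2)
    return float(np.clip(eps, 1.0 / k, 1.0))


def mauchly_test(sigma: np.ndarray, n_error_df: int):
    """Mauchly's sphericity statistic with the chi-square approximation."""
    s = np.asarray(sigma, dtype=float)
    k = s.shape[0]
    a = k + 1
    if k < 2:
        return 1.0, 0.0, 0, 1.0
    det = np.linalg.det(s)
    tr = np.trace(s)
    if det <= 0 or tr <= 0:
        return 0.0, np.inf, int(a * (a - 1) / 2 - 1), 0.0
    w = det / (tr / k) ** k
    f = (2.0 * k**2 + k + 2.0) / (6.0 * k)
    chi2 = -(n_error_df - f) * np.log(w)
    df = int(k * (k + 1) / 2 - 1)
    p = float(sps.chi2.sf(chi2, df))
    return float(w), float(chi2), df, p


# ---------------------------------------------------------------------------
# Repeated-measures ANCOVA (split plot)
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # effect, SS, df1, df2, F, p, p_gg, epsilon, eta2
    posthoc: pd.DataFrame = None
    mauchly: dict = None
    epsilon: float = None
    dropped_subjects: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]


def rm_ancova(
    data: pd.DataFrame,
    dv: str = "score",
    within: str = "task",
    subject: str = "participant",
    between=(),
    covariate: str = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Split-plot repeated-measures AN(C)OVA.

    ``data`` is long format: one row per subject x within level, with
    between-factor and covariate values constant within subject.
    """
    between = list(between)
    levels = sorted(pd.unique(data[within]))
    a = len(levels)
    if a < 2:
        raise ValueError("within factor needs at least 2 levels")

    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.warning("rm_ancova: dropping %d incomplete subjects", len(dropped))
    meta_cols = between + ([covariate] if covariate else [])
    meta = (
        data.drop_duplicates(subset=[subject]).set_index(subject)[meta_cols]
        if meta_cols
        else pd.DataFrame(index=wide.index)
    )
    meta = meta.loc[complete.index]
    y = complete[levels].to_numpy(dtype=float)
    n = y.shape[0]

    if between:
        cells = meta.groupby(between, observed=True).size()
        full_index = pd.MultiIndex.from_product(
            [sorted(pd.unique(meta[f])) for f in between], names=between
        ) if len(between) > 1 else pd.Index(sorted(pd.unique(meta[between[0]])))
        missing = [c for c in full_index if c not in cells.index]
        if missing:
            raise ValueError(f"empty between-participant cells: {missing}")
        if (cells < 2).any():
            raise ValueError(
                f"between cells with < 2 subjects: {list(cells[cells < 2].index)}"
            )

    frame = meta.copy()
    terms = _between_terms(frame.reset_index(), between, covariate)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    # --- between stratum: subject means ---
    ym = y.mean(axis=1)
    ss_b = _type3_ss(terms, ym)
    rank_b = ss_b["__rank__"]
    df_sub_error = n - rank_b
    if df_sub_error <= 0:
        raise ValueError("no error degrees of freedom in the between stratum")
    ms_sub_error = a * ss_b["__error__"] / df_sub_error

    rows = []

    def add_row(effect, ss, df1, df2, ms_error, epsilon=None, within_effect=False):
        ms = ss / df1
        f_val = ms / ms_error if ms_error > 0 else np.inf
        p = float(sps.f.sf(f_val, df1, df2)) if np.isfinite(f_val) else 0.0
        p_gg = None
        if within_effect and epsilon is not None:
            p_gg = float(sps.f.sf(f_val, df1 * epsilon, df2 * epsilon))
        rows.append(
            dict(
                effect=effect,
                SS=ss,
                df1=df1,
                df2=df2,
                F=f_val,
                p=p,
                p_gg=p_gg,
                epsilon=epsilon if within_effect else None,
                eta2=ss / ss_total if ss_total > 0 else 0.0,
            )
        )

    for name in terms:
        if name == "intercept":
            continue
        add_row(name, a * ss_b[name], _term_df(terms, name), df_sub_error, ms_sub_error)

    # --- within stratum: orthonormal contrast scores ---
    c = _orthonormal_contrasts(a)
    z = y @ c.T
    ss_w = _type3_ss(terms, z)
    df_w_error = df_sub_error * (a - 1)
    ss_w_error = ss_w["__error__"]
    ms_w_error = ss_w_error / df_w_error

    sigma = None
    epsilon = 1.0
    if a > 2:
        full = np.hstack(list(terms.values()))
        p_full = _projection(full)
        resid = z - p_full @ z
        sigma = resid.T @ resid / df_sub_error
        epsilon = greenhouse_geisser_epsilon(sigma)
    w_stat, chi2, m_df, m_p = (
        mauchly_test(sigma, df_sub_error) if sigma is not None else (1.0, 0.0, 0, 1.0)
    )

    for name in terms:
        label = within if name == "intercept" else f"{within}:{name}"
        add_row(
            label,
            ss_w[name],
            _term_df(terms, name) * (a - 1),
            df_w_error,
            ms_w_error,
            epsilon=epsilon,
            within_effect=True,
        )

    effects = pd.DataFrame(rows)

    # --- Bonferroni post hoc on significant effects ---
    posthoc_rows = []
    eff_idx = effects.set_index("effect")
    for factor in between:
        if eff_idx.loc[factor, "p"] < alpha:
            posthoc_rows.extend(
                _between_posthoc(frame, ym, factor, ms_sub_error / a, df_sub_error)
            )
    use_p = "p_gg" if (a > 2 and m_p < alpha) else "p"
    p_within = eff_idx.loc[within, use_p]
    if p_within is not None and p_within < alpha:
        posthoc_rows.extend(_within_posthoc(y, levels))
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["factor", "level_a", "level_b", "mean_diff", "p_bonferroni"],
    )

    return AnovaResult(
        effects=effects,
        posthoc=posthoc,
        mauchly=dict(W=w_stat, chi2=chi2, df=m_df, p=m_p),
        epsilon=epsilon,
        dropped_subjects=dropped,
    )


def _between_posthoc(meta: pd.DataFrame, ym: np.ndarray, factor: str, mse, df_err):
    levels = sorted(pd.unique(meta[factor]))
    vals = pd.Series(ym, index=meta.index)
    groups = {lev: vals[meta[factor] == lev] for lev in levels}
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for la, lb in combinations(levels, 2):
        ga, gb = groups[la], groups[lb]
        diff = float(ga.mean() - gb.mean())
        se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
        t = diff / se if se > 0 else np.inf
        p = min(1.0, 2.0 * sps.t.sf(abs(t), df_err) * n_pairs)
        rows.append(
            dict(factor=factor, level_a=la, level_b=lb, mean_diff=diff, p_bonferroni=p)
        )
    return rows


def _within_posthoc(y: np.ndarray, levels):
    a = len(levels)
    n_pairs = a * (a - 1) // 2
    rows = []
    for i, j in combinations(range(a), 2):
        diff = y[:, i] - y[:, j]
        t, p = sps.ttest_1samp(diff, 0.0)
        rows.append(
            dict(
                factor="within",
                level_a=levels[i],
                level_b=levels[j],
                mean_diff=float(diff.mean()),
                p_bonferroni=min(1.0, float(p) * n_pairs),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Between-participants (univariate) ANOVA
# ---------------------------------------------------------------------------


def univariate_anova(
    data: pd.DataFrame, dv: str, factors, interaction: bool = True, alpha: float = 0.05
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with Type-III SS and Bonferroni
    pairwise comparisons on significant main effects."""
    factors = list(factors)
    df = data.dropna(subset=[dv] + factors).reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)
    terms = _between_terms(df, factors)
    if not interaction:
        terms = {k: v for k, v in terms.items() if ":" not in k}
    ss = _type3_ss(terms, y)
    rank = ss["__rank__"]
    n = len(y)
    df_err = n - rank
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss["__error__"] / df_err
    ss_total = float(((y - y.mean()) ** 2).sum())

    rows = []
    for name in terms:
        if name == "intercept":
            continue
        df1 = _term_df(terms, name)
        if df1 == 0:
            continue
        if mse > 0:
            f_val = (ss[name] / df1) / mse
        else:  # degenerate response: no variance anywhere
            f_val = 0.0 if ss[name] < 1e-12 else np.inf
        p = float(sps.f.sf(f_val, df1, df_err)) if np.isfinite(f_val) else 0.0
        rows.append(
            dict(
                effect=name,
                SS=ss[name],
                df1=df1,
                df2=df_err,
                F=f_val,
                p=p,
                p_gg=None,
                epsilon=None,
                eta2=ss[name] / ss_total if ss_total > 0 else 0.0,
            )
        )
    effects = pd.DataFrame(rows)

    posthoc_rows = []
    eff_idx = effects.set_index("effect")
    for factor in factors:
        if factor in eff_idx.index and eff_idx.loc[factor, "p"] < alpha:
            levels = sorted(pd.unique(df[factor]))
            n_pairs = len(levels) * (len(levels) - 1) // 2
            for la, lb in combinations(levels, 2):
                ga = y[df[factor] == la]
                gb = y[df[factor] == lb]
                diff = float(ga.mean() - gb.mean())
                se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
                t = diff / se if se > 0 else np.inf
                p = min(1.0, 2.0 * sps.t.sf(abs(t), df_err) * n_pairs)
                posthoc_rows.append(
                    dict(
                        factor=factor,
                        level_a=la,
                        level_b=lb,
                        mean_diff=diff,
                        p_bonferroni=p,
                    )
                )
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["factor", "level_a", "level_b", "mean_diff", "p_bonferroni"],
    )
    return AnovaResult(effects=effects, posthoc=posthoc)
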