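"""Repeated-measures inference: within-subjects ANOVA, effect sizes, power.

The ANOVA uses the classical univariate decomposition for balanced fully
within-subjects designs: every effect is tested against its interaction
with the subject factor.  Sphericity is handled via the Huynh-Feldt
epsilon (clipped at 1) and effect sizes are generalized eta squared with
all subject-related strata in the denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "PowerSpec",
    "rm_anova",
    "paired_ttest",
    "two_sample_ttest",
    "cohens_d",
    "rm_power",
    "rm_power_mc",
]


class InferenceError(ValueError):
    """Raised when a model cannot be estimated (too few subjects, no variance)."""


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon_hf: float
    p_uncorrected: float
    p_corrected: float
    eta2_g: float


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power scenario for a one-way within-subjects ANOVA."""

    n: int
    m: int
    f: float
    rho: float = 0.5
    alpha: float = 0.05
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 subjects and m >= 2 levels")
        if self.f < 0:
            raise ValueError("effect size f must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must lie in (0, 1]")


# ---------------------------------------------------------------------------
# balanced fully-within ANOVA
# ---------------------------------------------------------------------------


def _cell_array(
    table: pd.DataFrame, dv: str, within: list[str], subject: str
) -> tuple[np.ndarray, list[str], dict[str, list], list[str]]:
    """Pivot a tidy table into an array of cell means, subjects first axis.

    Subjects with any missing cell are dropped listwise; the dropped ids are
    returned for reporting.
    """
    df = table[[subject, *within, dv]].copy()
    df = df.dropna(subset=[dv])
    grouped = df.groupby([subject, *within], sort=True, observed=True)[dv].mean()
    wide = grouped.unstack(within) if within else grouped.to_frame()
    complete = wide.dropna(axis=0)
    dropped = sorted(set(wide.index) - set(complete.index))

    levels = {f: sorted(df[f].dropna().unique().tolist()) for f in within}
    n_cells = int(np.prod([len(levels[f]) for f in within]))
    if within and complete.shape[1] != n_cells:
        raise InferenceError("design is not fully crossed over the within factors")

    # reorder columns into the canonical factorial order
    if within:
        order = list(itertools.product(*[levels[f] for f in within]))
        cols = [c if isinstance(c, tuple) else (c,) for c in complete.columns]
        complete = complete.iloc[:, [cols.index(o) for o in order]]
    shape = (len(complete),) + tuple(len(levels[f]) for f in within)
    return (
        complete.to_numpy(dtype=float).reshape(shape),
        list(complete.index),
        levels,
        [str(s) for s in dropped],
    )


def _effect_ss(y: np.ndarray, axes: tuple[int, ...]) -> tuple[float, int]:
    """Sum of squares and df of the effect spanned by *axes* of a balanced array.

    Uses the Moebius (inclusion-exclusion) expansion over marginal means.
    """
    est = np.zeros_like(y)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            reduce_over = tuple(i for i in range(y.ndim) if i not in sub)
            marg = y.mean(axis=reduce_over, keepdims=True)
            sign = (-1) ** (len(axes) - r)
            est = est + sign * marg
    ss = float((est**2).sum())
    df = int(np.prod([y.shape[i] - 1 for i in axes])) if axes else 0
    return ss, df


def _normalized_contrasts(m: int) -> np.ndarray:
    """Orthonormal contrast matrix (m-1, m) orthogonal to the unit vector."""
    basis = np.eye(m) - 1.0 / m
    q, _ = np.linalg.qr(basis[:, : m - 1])
    return q.T  # rows orthonormal, each orthogonal to 1


def _hf_epsilon(z: np.ndarray, c: np.ndarray) -> float:
    """Huynh-Feldt epsilon from per-subject scores over effect cells.

    ``z`` has shape (n_subjects, n_cells); ``c`` is the (df, n_cells)
    orthonormal contrast matrix of the effect (Kronecker product of the
    per-factor contrasts for interactions).
    """
    n = z.shape[0]
    d = c.shape[0]
    if d == 0:
        return 1.0
    s = np.cov(z, rowvar=False, ddof=1)
    mmat = c @ np.atleast_2d(s) @ c.T
    tr = float(np.trace(mmat))
    denom = d * float((mmat * mmat).sum())
    if denom <= 0:
        return 1.0
    eps_gg = tr * tr / denom
    num = n * d * eps_gg - 2.0
    den = d * (n - 1 - d * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / d)))


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str = "subject",
) -> pd.DataFrame:
    """Fully within-subjects ANOVA on a tidy table of cell means.

    Parameters
    ----------
    table
        Tidy data frame with one row per subject x within-cell (replicates
        are averaged).  Subjects missing any cell are removed listwise.
    dv
        Column holding the dependent variable.
    within
        Name(s) of the within-subject factor column(s).
    subject
        Column identifying subjects.

    Returns
    -------
    DataFrame with one row per effect (main effects and all interactions),
    columns matching :class:`AnovaResult`, plus ``n_subjects`` and
    ``dropped_subjects``.
    """
    if isinstance(within, str):
        within = [within]
    y, subjects, levels, dropped = _cell_array(table, dv, within, subject)
    n = y.shape[0]
    if n < 2:
        raise InferenceError(f"need >= 2 complete subjects, have {n}")
    if float(np.var(y)) == 0.0:
        raise InferenceError("dependent variable has zero total variance")

    factor_axis = {f: i + 1 for i, f in enumerate(within)}  # axis 0 = subject

    # error strata: subject main effect and subject x effect interactions
    ss_subject, _ = _effect_ss(y, (0,))
    error_ss_all = ss_subject
    effects = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            axes = tuple(factor_axis[f] for f in combo)
            ss_eff, df_eff = _effect_ss(y, axes)
            ss_err, df_err = _effect_ss(y, (0, *axes))
            error_ss_all += ss_err
            effects.append((combo, axes, ss_eff, df_eff, ss_err, df_err))

    rows = []
    for combo, axes, ss_eff, df_eff, ss_err, df_err in effects:
        if df_err <= 0:
            raise InferenceError("no error degrees of freedom")
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_eff == 0.0:
            fval = 0.0
        elif ms_err == 0.0:
            fval = math.inf
        else:
            fval = ms_eff / ms_err
        p_unc = float(stats.f.sf(fval, df_eff, df_err))

        # per-subject scores over the effect's cells (average over other factors)
        other = tuple(
            i for i in range(1, y.ndim) if i not in axes
        )
        z = y.mean(axis=other) if other else y
        z = z.reshape(n, -1)
        contrasts = np.ones((1, 1))
        for f in combo:
            contrasts = np.kron(contrasts, _normalized_contrasts(len(levels[f])))
        eps = _hf_epsilon(z, contrasts)
        p_cor = float(stats.f.sf(fval, df_eff * eps, df_err * eps))

        eta2_g = ss_eff / (ss_eff + error_ss_all)
        rows.append(
            {
                "effect": "*".join(combo),
                "F": fval,
                "df_num": df_eff,
                "df_den": df_err,
                "epsilon_hf": eps,
                "p_uncorrected": p_unc,
                "p_corrected": p_cor,
                "eta2_g": eta2_g,
                "n_subjects": n,
                "dropped_subjects": ";".join(dropped),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests and Cohen's d
# ---------------------------------------------------------------------------


def cohens_d(x, y, design: str = "paired") -> float:
    """Cohen's d for paired or two-sample comparisons.

    paired: mean(x - y) / SD(x - y); two_sample: (mean x - mean y) / pooled SD.
    Returns ``nan`` when the relevant SD is zero (undefined effect size).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InferenceError("need >= 2 observations per sample")
    if design == "paired":
        if len(x) != len(y):
            raise InferenceError("paired samples must have equal length")
        diff = x - y
        sd = diff.std(ddof=1)
        return float(diff.mean() / sd) if sd > 0 else math.nan
    if design == "two_sample":
        nx, ny = len(x), len(y)
        pooled = math.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        )
        return float((x.mean() - y.mean()) / pooled) if pooled > 0 else math.nan
    raise ValueError(f"design must be 'paired' or 'two_sample', got {design!r}")


def paired_ttest(x, y) -> dict:
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "df": len(np.asarray(x)) - 1,
            "d": cohens_d(x, y, "paired")}


def two_sample_ttest(x, y) -> dict:
    t, p = stats.ttest_ind(x, y)
    return {"t": float(t), "p": float(p),
            "df": len(np.asarray(x)) + len(np.asarray(y)) - 2,
            "d": cohens_d(x, y, "two_sample")}


# ---------------------------------------------------------------------------
# a-priori power for the one-way within design
# ---------------------------------------------------------------------------


def rm_power(spec: PowerSpec) -> float:
    """Achieved power of the one-way within-subjects F test.

    Noncentrality ``lambda = f^2 * n * m / (1 - rho)``; the test statistic is
    referred to a noncentral F with (m-1)*eps and (n-1)(m-1)*eps degrees of
    freedom at the central critical value for ``alpha``.
    """
    df1 = (spec.m - 1) * spec.epsilon
    df2 = (spec.n - 1) * (spec.m - 1) * spec.epsilon
    lam = spec.f**2 * spec.n * spec.m / (1.0 - spec.rho)
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def rm_power_mc(
    spec: PowerSpec,
    n_reps: int = 50_000,
    rng: np.random.Generator | None = None,
    chunk: int = 2_000,
) -> float:
    """Monte-Carlo power estimate under a compound-symmetric alternative.

    Data model: Y_ij = mu_j + s_i + e_ij with Var(s) = rho, Var(e) = 1 - rho
    (unit total variance, correlation rho between levels) and level means
    with population SD equal to Cohen's f.  Each replicate runs the one-way
    within-subjects F test at ``alpha``.
    """
    rng = np.random.default_rng() if rng is None else rng
    n, m = spec.n, spec.m
    # equally spaced level means scaled to population SD f
    pattern = np.arange(m, dtype=float)
    pattern -= pattern.mean()
    sd = pattern.std()
    mu = pattern / sd * spec.f if sd > 0 else pattern

    fcrit = stats.f.ppf(1.0 - spec.alpha, m - 1, (n - 1) * (m - 1))
    hits = 0
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        subj = rng.normal(0.0, math.sqrt(spec.rho), size=(r, n, 1))
        err = rng.normal(0.0, math.sqrt(1.0 - spec.rho), size=(r, n, m))
        y = mu[None, None, :] + subj + err
        grand = y.mean(axis=(1, 2), keepdims=True)
        lvl = y.mean(axis=1, keepdims=True)
        sub = y.mean(axis=2, keepdims=True)
        ss_treat = (n * (lvl - grand) ** 2).sum(axis=(1, 2))
        ss_err = ((y - lvl - sub + grand) ** 2).sum(axis=(1, 2))
        fstat = (ss_treat / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))
        hits += int((fstat > fcrit).sum())
        done += r
    return hits / n_reps
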