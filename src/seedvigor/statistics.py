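"""Statistical integration layer: t-tests, two-way ANOVA with Tukey–Kramer
compact letter display, Pearson correlation matrices, and standardized PCA.

This module takes the replicate-level feature table assembled from the
germination, ROS and expression stages and reproduces the study-level
statistics: per-group comparisons against a control, a two-way
fixed-effects ANOVA with Tukey–Kramer post-hoc letters, a Pearson
correlation matrix with p-values, and a PCA on z-scored features for the
score plot / biplot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "LetterDisplay",
    "PCAResult",
    "t_test_vs_control",
    "tukey_kramer",
    "compact_letter_display",
    "anova_tukey_kramer",
    "pearson_matrix",
    "pca",
]

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    """The factorial design has empty cells; the requested model is inestimable."""


# ---------------------------------------------------------------------------
# Student t-tests vs control


def t_test_vs_control(
    values_by_group: dict[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided equal-variance Student t-test of each group against control.

    Returns a DataFrame with one row per non-control group (group, t, p,
    significant).  Every tested group and the control need >= 2
    observations.
    """
    if control_label not in values_by_group:
        raise InvalidInputError(f"control group {control_label!r} missing")
    ctrl = np.asarray(values_by_group[control_label], dtype=float)
    if ctrl.size < 2:
        raise InvalidInputError("control group needs >= 2 observations")
    rows = []
    for group, vals in values_by_group.items():
        if group == control_label:
            continue
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise InvalidInputError(f"group {group!r} needs >= 2 observations")
        if np.ptp(v) == 0 and np.ptp(ctrl) == 0:
            t, p = (np.inf, 0.0) if v[0] != ctrl[0] else (0.0, 1.0)
        else:
            res = sps.ttest_ind(v, ctrl, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"group": group, "t": t, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey–Kramer pairwise comparisons and compact letter display


def tukey_kramer(
    values_by_group: dict[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise comparisons of group means via the studentized range.

    Uses the pooled within-group variance and, for unequal group sizes, the
    Kramer correction ``SE = sqrt(MSE/2 * (1/n_i + 1/n_j))``.  P-values
    come from the studentized-range distribution with ``k`` groups and
    ``N - k`` error degrees of freedom, giving familywise control.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise InvalidInputError("every group needs >= 2 observations")
    k = len(groups)
    n_total = sum(a.size for a in arrays.values())
    df_err = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    rows = []
    for g1, g2 in combinations(groups, 2):
        a, b = arrays[g1], arrays[g2]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        rows.append({
            "group1": g1, "group2": g2, "meandiff": diff,
            "q": q, "p_adj": p, "reject": p < alpha,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LetterDisplay:
    group: str
    letters: str


def compact_letter_display(
    pairwise: pd.DataFrame, group_means: dict[str, float]
) -> list[LetterDisplay]:
    """Insert-and-absorb compact letter display from a pairwise table.

    Two groups share a letter if and only if their comparison is
    non-significant.  Groups are processed in descending order of mean
    (ties broken by label) so the letters read along the response scale.
    """
    order = sorted(group_means, key=lambda g: (-group_means[g], g))
    sig_pairs = [
        (str(r["group1"]), str(r["group2"]))
        for _, r in pairwise.iterrows() if bool(r["reject"])
    ]
    # insert step: start from one set holding every group; each significant
    # pair splits every set containing both (one copy drops each member)
    letter_sets: list[set[str]] = [set(order)]
    for g1, g2 in sig_pairs:
        next_sets: list[set[str]] = []
        for s in letter_sets:
            if g1 in s and g2 in s:
                next_sets.append(s - {g1})
                next_sets.append(s - {g2})
            else:
                next_sets.append(s)
        # absorb: drop empties, duplicates, and sets contained in another
        absorbed: list[set[str]] = []
        for s in next_sets:
            if s and not any(s < t for t in next_sets) and s not in absorbed:
                absorbed.append(s)
        letter_sets = absorbed
    # deterministic letter order: sets sorted by their best (highest-mean) member
    rank = {g: i for i, g in enumerate(order)}
    letter_sets.sort(key=lambda s: (min(rank[g] for g in s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, str] = {g: "" for g in order}
    for idx, s in enumerate(letter_sets):
        letter = alphabet[idx % len(alphabet)]
        for g in order:
            if g in s:
                assigned[g] += letter
    return [LetterDisplay(group=g, letters=assigned[g]) for g in order]


def anova_tukey_kramer(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = 0.05,
    letter_factor: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[LetterDisplay]]:
    """Two-way (or one-way) fixed-effects ANOVA plus Tukey–Kramer letters.

    Fits ``response ~ A * B`` with the interaction when every cell of the
    A x B layout is occupied and has replication; drops the interaction to
    an additive model when cells lack replication, and raises
    :class:`DegenerateDesignError` when cells are empty.  Post-hoc
    Tukey–Kramer comparisons and the compact letter display are computed on
    ``letter_factor`` (default: the first factor).
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise InvalidInputError("one or two factors are supported")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    for f in factors:
        if data[f].nunique() < 2:
            raise InvalidInputError(f"factor {f!r} needs >= 2 levels")
    df = data[[response, *factors]].dropna().copy()
    df = df.rename(columns={response: "_y", **{f: f"_f{i}" for i, f in enumerate(factors)}})

    if len(factors) == 2:
        cells = df.groupby(["_f0", "_f1"]).size()
        full = df["_f0"].nunique() * df["_f1"].nunique()
        if len(cells) < full:
            raise DegenerateDesignError("empty cells: two-way model inestimable")
        with_interaction = (cells >= 2).all()
        formula = "_y ~ C(_f0) * C(_f1)" if with_interaction else "_y ~ C(_f0) + C(_f1)"
    else:
        formula = "_y ~ C(_f0)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index=lambda s: s.replace("C(_f0)", factors[0]).replace(
        "C(_f1)", factors[1] if len(factors) == 2 else "_f1"))

    lf = letter_factor or factors[0]
    lf_col = f"_f{factors.index(lf)}"
    grouped = {str(g): grp["_y"].to_numpy() for g, grp in df.groupby(lf_col)}
    pairwise = tukey_kramer(grouped, alpha=alpha)
    means = {g: float(v.mean()) for g, v in grouped.items()}
    letters = compact_letter_display(pairwise, means)
    return anova, pairwise, letters


# ---------------------------------------------------------------------------
# Pearson correlation matrix


def pearson_matrix(
    data: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p-value matrices over feature columns.

    Pairwise-complete observations; p-values from the t-transform of r
    with n - 2 degrees of freedom.  Zero-variance columns yield NaN
    off-diagonals (logged), and pairs with fewer than 3 complete rows are
    NaN as well.
    """
    cols = list(columns) if columns is not None else [
        c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])
    ]
    r = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    np.fill_diagonal(r.values, 1.0)
    p = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    for c in cols:
        v = data[c].dropna()
        if v.size >= 2 and np.ptp(v.to_numpy()) == 0:
            logger.warning("column %s has zero variance; correlations undefined", c)
    for c1, c2 in combinations(cols, 2):
        sub = data[[c1, c2]].dropna()
        if len(sub) < 3:
            continue
        x, y = sub[c1].to_numpy(), sub[c2].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = sps.pearsonr(x, y)
        r.loc[c1, c2] = r.loc[c2, c1] = float(res.statistic)
        p.loc[c1, c2] = p.loc[c2, c1] = float(res.pvalue)
    return r, p


# ---------------------------------------------------------------------------
# PCA on z-scored features


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame              # rows x components
    loadings: pd.DataFrame            # features x components
    explained_variance_ratio: np.ndarray
    dropped_columns: tuple[str, ...]  # constant columns removed pre-scaling


def pca(
    data: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of z-score-standardized features via SVD.

    Features are standardized per column (correlation-matrix PCA — the
    inputs mix percents, days, uM and RFU), rows with any missing cell are
    dropped (listwise), and constant columns are removed with a warning.
    Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive.
    """
    cols = list(columns) if columns is not None else [
        c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])
    ]
    sub = data[cols].dropna()
    if len(sub) < 3 or len(cols) < 2:
        raise InvalidInputError("PCA needs >= 3 complete rows and >= 2 columns")
    X = sub.to_numpy(dtype=float)
    keep, dropped = [], []
    for j, c in enumerate(cols):
        if np.ptp(X[:, j]) == 0:
            dropped.append(c)
            logger.warning("constant column %s dropped before PCA", c)
        else:
            keep.append(j)
    if len(keep) < 2:
        raise InvalidInputError("fewer than 2 non-constant columns")
    cols = [cols[j] for j in keep]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(len(S), n_components) if n_components else len(S)
    var = S**2 / (len(sub) - 1)
    evr = var / var.sum()
    # sign convention: largest-|loading| entry of each component positive
    for i in range(len(S)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U * S)[:, :k], index=sub.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=cols, columns=comp_names)
    return PCAResult(
        scores=scores, loadings=loadings,
        explained_variance_ratio=evr[:k], dropped_columns=tuple(dropped),
    )
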