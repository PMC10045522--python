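"""Germination kinetics indices from daily count time courses.

A germination test scores, each day, the number of newly germinated seeds
out of a fixed number sown per replicate dish.  From one replicate's time
course (times ``t_i`` in days, new counts ``n_i``, ``N = sum(n_i)`` seeds
germinated, frequencies ``f_i = n_i / N``) seven standard indices are
computed:

* germinability ``G = 100 * N / total_seeds`` (percent of sown seeds),
* peak value ``PV = max_i (cumulative germinated up to t_i) / t_i``
  (seeds per day),
* mean germination time ``MGT = sum(n_i * t_i) / N`` (days),
* mean germination rate ``MGR = 1 / MGT`` (per day),
* coefficient of velocity ``CVG = 100 * MGR`` (percent per day),
* uncertainty index ``U = -sum(f_i * log2 f_i)`` (bits; Shannon entropy of
  the germination-day distribution),
* synchrony index ``Z = sum(C(n_i, 2)) / C(N, 2)`` (fraction of pairs of
  germinated seeds that germinated on the same day).

MGT, MGR and CVG are undefined when no seed germinates (reported as the
``n.d.`` marker, i.e. ``None``); U and Z take the value 0 in the degenerate
cases (N <= 1 for U, N < 2 for Z), matching how germination tables
conventionally print an all-zero heat-shock column as ``0 +/- 0``.

Non-germinated seeds are right-censored: they enter G and PV through the
total sown, but not MGT/MGR/CVG/U/Z, which are statistics of the germinated
fraction only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GerminationTimeCourse",
    "GerminationIndices",
    "TreatmentSummary",
    "germinability",
    "peak_value",
    "mean_germination_time",
    "mean_germination_rate",
    "coefficient_of_velocity",
    "uncertainty_index",
    "synchrony_index",
    "compute_indices",
    "summarize_treatment",
    "read_time_courses",
    "indices_table",
    "summary_table",
]

INDEX_NAMES = ("G", "PV", "MGT", "MGR", "CVG", "U", "Z")

#: indices that are undefined (printed "n.d.") when no seed germinates
ND_INDICES = frozenset({"MGT", "MGR", "CVG"})


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GerminationTimeCourse:
    """One replicate's daily germination counts.

    ``times`` are observation times in days (day 1 = first scoring) and
    ``counts`` the seeds newly germinated at each time.  Irregular
    monitoring intervals are supported; times must be strictly increasing
    and positive.
    """

    species: str
    treatment: str
    replicate: str
    total_seeds: int
    times: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.total_seeds <= 0:
            raise InvalidInputError("total_seeds must be a positive count")
        if len(self.times) != len(self.counts):
            raise InvalidInputError("times and counts must have equal length")
        if len(self.times) == 0:
            raise InvalidInputError("time course must have at least one observation")
        t = np.asarray(self.times)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing and > 0")
        if any(c < 0 for c in self.counts):
            raise InvalidInputError("counts must be non-negative")
        if sum(self.counts) > self.total_seeds:
            raise InvalidInputError(
                f"germinated total {sum(self.counts)} exceeds seeds sown {self.total_seeds}"
            )

    @property
    def n_germinated(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class GerminationIndices:
    """The seven indices for one replicate; None marks a not-defined value."""

    G: float
    PV: float
    MGT: Optional[float]
    MGR: Optional[float]
    CVG: Optional[float]
    U: float
    Z: float

    def as_dict(self) -> dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def germinability(tc: GerminationTimeCourse) -> float:
    """Percentage of sown seeds germinated by the end of the test."""
    return 100.0 * tc.n_germinated / tc.total_seeds


def peak_value(tc: GerminationTimeCourse) -> float:
    """Highest ratio of cumulative germinated seeds to elapsed time (seeds/day)."""
    cum = np.cumsum(tc.counts)
    if cum[-1] == 0:
        return 0.0
    return float(np.max(cum / np.asarray(tc.times)))


def mean_germination_time(tc: GerminationTimeCourse) -> Optional[float]:
    """Count-weighted mean germination day; None when no seed germinated."""
    n = tc.n_germinated
    if n == 0:
        return None
    return float(np.dot(tc.counts, tc.times) / n)


def mean_germination_rate(tc: GerminationTimeCourse) -> Optional[float]:
    """Reciprocal of MGT; None when MGT is undefined."""
    mgt = mean_germination_time(tc)
    return None if mgt is None else 1.0 / mgt


def coefficient_of_velocity(tc: GerminationTimeCourse) -> Optional[float]:
    """MGR expressed as a percentage; None when MGR is undefined."""
    mgr = mean_germination_rate(tc)
    return None if mgr is None else 100.0 * mgr


def uncertainty_index(tc: GerminationTimeCourse, base: float = 2.0) -> float:
    """Shannon entropy of the germination-day distribution (bits by default).

    Days with no germination contribute nothing.  Returns 0 when at most
    one seed germinated or all germination fell on one day.
    """
    n = np.asarray(tc.counts, dtype=float)
    total = n.sum()
    if total <= 1:
        return 0.0
    f = n[n > 0] / total
    return float(-np.sum(f * np.log(f)) / math.log(base))


def synchrony_index(tc: GerminationTimeCourse) -> float:
    """Fraction of germinated-seed pairs that share a germination day.

    ``Z = sum_i C(n_i, 2) / C(N, 2)``; 0 when fewer than two seeds
    germinated, 1 when all germination is synchronous.
    """
    counts = tc.counts
    total = sum(counts)
    if total < 2:
        return 0.0
    same_day = sum(c * (c - 1) // 2 for c in counts)
    return same_day / (total * (total - 1) // 2)


def compute_indices(tc: GerminationTimeCourse, entropy_base: float = 2.0) -> GerminationIndices:
    """All seven indices for one replicate time course."""
    return GerminationIndices(
        G=germinability(tc),
        PV=peak_value(tc),
        MGT=mean_germination_time(tc),
        MGR=mean_germination_rate(tc),
        CVG=coefficient_of_velocity(tc),
        U=uncertainty_index(tc, base=entropy_base),
        Z=synchrony_index(tc),
    )


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment mean +/- dispersion of each index across replicates.

    ``mean[k]`` / ``sd[k]`` are None when any replicate's index ``k`` is
    not-defined (an ``n.d.`` cell).  ``sig_vs_control`` is only populated
    when a control group was supplied.
    """

    treatment: str
    n_replicates: int
    mean: dict[str, Optional[float]]
    sd: dict[str, Optional[float]]
    sig_vs_control: dict[str, Optional[bool]] = field(default_factory=dict)
    p_vs_control: dict[str, Optional[float]] = field(default_factory=dict)


def _index_matrix(reps: Sequence[GerminationIndices]) -> dict[str, list[Optional[float]]]:
    return {k: [getattr(r, k) for r in reps] for k in INDEX_NAMES}


def summarize_treatment(
    replicate_indices: Sequence[GerminationIndices],
    treatment: str,
    control_indices: Optional[Sequence[GerminationIndices]] = None,
    alpha: float = 0.05,
    dispersion: str = "sd",
) -> TreatmentSummary:
    """Summarize replicate-level indices into a treatment row.

    Indices are computed per replicate and then averaged, never re-derived
    from pooled counts (so the summary MGR need not equal the reciprocal of
    the summary MGT, although each replicate satisfies the identity
    exactly).  Dispersion is the sample SD (``n-1``) by default, or SEM
    with ``dispersion="sem"``.  When ``control_indices`` is given, each
    index is compared to the control with a two-sided equal-variance
    Student t-test at ``alpha``.
    """
    if not replicate_indices:
        raise InvalidInputError("at least one replicate is required")
    if dispersion not in ("sd", "sem"):
        raise InvalidInputError("dispersion must be 'sd' or 'sem'")
    cols = _index_matrix(replicate_indices)
    n = len(replicate_indices)
    mean: dict[str, Optional[float]] = {}
    sd: dict[str, Optional[float]] = {}
    for k, vals in cols.items():
        if any(v is None for v in vals):
            mean[k] = None
            sd[k] = None
            continue
        arr = np.asarray(vals, dtype=float)
        mean[k] = float(arr.mean())
        s = float(arr.std(ddof=1)) if n > 1 else 0.0
        sd[k] = s / math.sqrt(n) if dispersion == "sem" else s
    sig: dict[str, Optional[bool]] = {}
    pvals: dict[str, Optional[float]] = {}
    if control_indices is not None:
        ctrl_cols = _index_matrix(control_indices)
        for k in INDEX_NAMES:
            a, b = cols[k], ctrl_cols[k]
            if any(v is None for v in a) or any(v is None for v in b) or len(a) < 2 or len(b) < 2:
                sig[k] = None
                pvals[k] = None
                continue
            if np.allclose(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0:
                # degenerate identical constant groups: no evidence of difference
                sig[k] = False
                pvals[k] = 1.0
                continue
            t = sps.ttest_ind(a, b, equal_var=True)
            pvals[k] = float(t.pvalue)
            sig[k] = bool(t.pvalue < alpha) if np.isfinite(t.pvalue) else False
    return TreatmentSummary(
        treatment=treatment, n_replicates=n, mean=mean, sd=sd,
        sig_vs_control=sig, p_vs_control=pvals,
    )


# ---------------------------------------------------------------------------
# tabular I/O

COUNTS_COLUMNS = ["species", "treatment", "replicate", "day", "new_germinated", "total_seeds"]


def read_time_courses(path_or_df) -> list[GerminationTimeCourse]:
    """Read long-format daily counts (one row per replicate x day).

    Expects columns ``species,treatment,replicate,day,new_germinated,
    total_seeds``.  Accepts a path or a DataFrame.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"counts table missing columns: {sorted(missing)}")
    out: list[GerminationTimeCourse] = []
    for (sp, trt, rep), grp in df.groupby(["species", "treatment", "replicate"], sort=True):
        grp = grp.sort_values("day")
        if grp["day"].duplicated().any():
            raise InvalidInputError(
                f"duplicate (replicate, day) rows for {sp}/{trt}/{rep}"
            )
        totals = grp["total_seeds"].unique()
        if len(totals) != 1:
            raise InvalidInputError(f"inconsistent total_seeds for {sp}/{trt}/{rep}")
        out.append(
            GerminationTimeCourse(
                species=str(sp), treatment=str(trt), replicate=str(rep),
                total_seeds=int(totals[0]),
                times=tuple(grp["day"].astype(float)),
                counts=tuple(grp["new_germinated"].astype(int)),
            )
        )
    return out


def indices_table(tcs: Sequence[GerminationTimeCourse]) -> pd.DataFrame:
    """Tidy per-replicate indices table (one row per replicate)."""
    rows = []
    for tc in tcs:
        row = {"species": tc.species, "treatment": tc.treatment, "replicate": tc.replicate}
        row.update(compute_indices(tc).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(
    tcs: Sequence[GerminationTimeCourse],
    control: Optional[str] = None,
    alpha: float = 0.05,
    dispersion: str = "sd",
) -> pd.DataFrame:
    """Treatment-level summary table (mean, sd, n, significance vs control).

    One row per treatment x index; ``n.d.`` cells carry NaN mean/sd and are
    flagged in the ``defined`` column.
    """
    by_trt: dict[str, list[GerminationIndices]] = {}
    for tc in tcs:
        by_trt.setdefault(tc.treatment, []).append(compute_indices(tc))
    ctrl = by_trt.get(control) if control is not None else None
    if control is not None and ctrl is None:
        raise InvalidInputError(f"control treatment {control!r} not present")
    rows = []
    for trt, reps in sorted(by_trt.items()):
        summ = summarize_treatment(
            reps, trt,
            control_indices=ctrl if trt != control else None,
            alpha=alpha, dispersion=dispersion,
        )
        for k in INDEX_NAMES:
            rows.append({
                "treatment": trt, "index": k,
                "mean": np.nan if summ.mean[k] is None else summ.mean[k],
                "sd": np.nan if summ.sd[k] is None else summ.sd[k],
                "n": summ.n_replicates,
                "defined": summ.mean[k] is not None,
                "sig_vs_control": summ.sig_vs_control.get(k),
            })
    return pd.DataFrame(rows)
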