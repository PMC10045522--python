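"""X0-method qPCR relative quantification with multi-reference normalization.

Threshold-cycle (Ct) values are exponentially related to the amount of
starting template: one cycle fewer means (1 + E) times more template, where
E is the amplification efficiency (E = 1 for perfect doubling).  The X0
method linearises Ct before any averaging or normalization:

    X0 = (1 + E) ** (-Ct)

up to an arbitrary multiplicative constant, which cancels in every relative
quantity.  Target X0 values are normalized by the geometric mean of the
reference-gene X0 values of the same sample, and treatment means are
expressed relative to the control mean (control = 1 by construction).

With a single reference gene and E = 1 this reduces exactly to the
classical 2^(-ddCt) fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CtRecord",
    "ExpressionResult",
    "ct_to_x0",
    "normalize_expression",
    "relative_to_control",
    "relative_expression_table",
    "read_ct_table",
]

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class CtRecord:
    sample: str
    treatment: str
    gene: str
    ct: float
    tech_replicate: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct) and self.ct > 0):
            raise InvalidInputError("ct must be positive and finite")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    treatment: str
    rel_expression: float     # fold vs control mean
    dispersion: float         # SD across biological replicates, fold scale
    n: int
    sig_vs_control: Optional[bool]
    p_vs_control: Optional[float]


def ct_to_x0(ct: float, efficiency: float = 1.0) -> float:
    """Starting-quantity estimate (arbitrary units) from a Ct value.

    ``efficiency`` is the per-cycle amplification efficiency as a fraction
    (1 = the product doubles each cycle); must be in (0, 1].
    """
    if not 0 < efficiency <= 1:
        raise InvalidInputError("efficiency must be in (0, 1]")
    return (1.0 + efficiency) ** (-ct)


def normalize_expression(target_x0: float, ref_x0_by_gene: Mapping[str, float]) -> float:
    """Divide a target X0 by the geometric mean of the reference X0 values."""
    if not ref_x0_by_gene:
        raise InvalidInputError("at least one reference gene is required")
    vals = list(ref_x0_by_gene.values())
    if target_x0 <= 0 or any(v <= 0 for v in vals):
        raise InvalidInputError("X0 values must be positive")
    geo = math.exp(sum(math.log(v) for v in vals) / len(vals))
    return target_x0 / geo


def _sample_normalized(
    records: Sequence[CtRecord],
    reference_genes: Sequence[str],
    efficiency: Mapping[str, float] | float,
    tech_average: str = "ct",
) -> pd.DataFrame:
    """Per-sample normalized quantities for every target gene.

    Technical replicates are averaged on the Ct scale before conversion by
    default (``tech_average="ct"``); ``"x0"`` averages after conversion.
    Samples missing a reference gene are dropped with a warning.
    """
    if tech_average not in ("ct", "x0"):
        raise InvalidInputError("tech_average must be 'ct' or 'x0'")
    df = pd.DataFrame([
        {"sample": r.sample, "treatment": r.treatment, "gene": r.gene, "ct": r.ct}
        for r in records
    ])

    def eff(gene: str) -> float:
        if isinstance(efficiency, Mapping):
            return float(efficiency.get(gene, 1.0))
        return float(efficiency)

    if tech_average == "ct":
        agg = df.groupby(["sample", "treatment", "gene"], as_index=False)["ct"].mean()
        agg["x0"] = [ct_to_x0(c, eff(g)) for c, g in zip(agg["ct"], agg["gene"])]
    else:
        df = df.assign(x0=[ct_to_x0(c, eff(g)) for c, g in zip(df["ct"], df["gene"])])
        agg = df.groupby(["sample", "treatment", "gene"], as_index=False)["x0"].mean()

    rows = []
    for (sample, treatment), grp in agg.groupby(["sample", "treatment"]):
        by_gene = dict(zip(grp["gene"], grp["x0"]))
        refs = {g: by_gene[g] for g in reference_genes if g in by_gene}
        if len(refs) < len(reference_genes):
            missing = set(reference_genes) - set(refs)
            logger.warning("sample %s dropped: missing reference gene(s) %s",
                           sample, sorted(missing))
            continue
        for g, x0 in by_gene.items():
            if g in reference_genes:
                continue
            rows.append({
                "sample": sample, "treatment": treatment, "gene": g,
                "norm_x0": normalize_expression(x0, refs),
            })
    return pd.DataFrame(rows)


def relative_to_control(
    normalized: pd.DataFrame, control_label: str, alpha: float = 0.05
) -> list[ExpressionResult]:
    """Express per-gene treatment means relative to the control mean.

    ``normalized`` must have columns sample/treatment/gene/norm_x0 with one
    row per biological sample x gene.  Per gene, each treatment's mean
    normalized quantity is divided by the control mean; the SD across
    biological replicates is propagated to the same fold scale, and a
    two-sided Student t-test on the normalized quantities flags
    significance vs control at ``alpha``.
    """
    if control_label not in set(normalized["treatment"]):
        raise InvalidInputError(f"control group {control_label!r} not present")
    results: list[ExpressionResult] = []
    for gene, gdf in normalized.groupby("gene", sort=True):
        ctrl_vals = gdf.loc[gdf["treatment"] == control_label, "norm_x0"].to_numpy()
        if ctrl_vals.size == 0:
            logger.warning("gene %s has no control samples; skipped", gene)
            continue
        ctrl_mean = ctrl_vals.mean()
        for trt, tdf in gdf.groupby("treatment", sort=True):
            vals = tdf["norm_x0"].to_numpy()
            fold = float(vals.mean() / ctrl_mean)
            sd = float(vals.std(ddof=1) / ctrl_mean) if vals.size > 1 else 0.0
            sig: Optional[bool] = None
            pval: Optional[float] = None
            if trt != control_label and vals.size >= 2 and ctrl_vals.size >= 2:
                if np.ptp(vals) == 0 and np.ptp(ctrl_vals) == 0:
                    pval = 1.0 if vals[0] == ctrl_vals[0] else 0.0
                else:
                    pval = float(sps.ttest_ind(vals, ctrl_vals, equal_var=True).pvalue)
                sig = bool(pval < alpha)
            results.append(ExpressionResult(
                gene=str(gene), treatment=str(trt), rel_expression=fold,
                dispersion=sd, n=int(vals.size), sig_vs_control=sig, p_vs_control=pval,
            ))
    return results


def relative_expression_table(
    records: Sequence[CtRecord],
    reference_genes: Sequence[str],
    control_label: str,
    efficiency: Mapping[str, float] | float = 1.0,
    alpha: float = 0.05,
    tech_average: str = "ct",
) -> pd.DataFrame:
    """End-to-end Ct -> relative-expression table (gene x treatment rows)."""
    norm = _sample_normalized(records, reference_genes, efficiency, tech_average)
    if norm.empty:
        raise InvalidInputError("no usable samples after normalization")
    res = relative_to_control(norm, control_label, alpha=alpha)
    return pd.DataFrame([
        {"gene": r.gene, "treatment": r.treatment, "rel_expression": r.rel_expression,
         "sd": r.dispersion, "n": r.n, "sig_vs_control": r.sig_vs_control,
         "p_vs_control": r.p_vs_control}
        for r in res
    ])


CT_COLUMNS = ["sample", "treatment", "gene", "tech_replicate", "ct"]


def read_ct_table(path_or_df, gene_set: Optional[Sequence[str]] = None) -> list[CtRecord]:
    """Read the qPCR CSV into CtRecords, dropping undetermined Ct values.

    Missing/non-positive Ct values (undetermined wells) are dropped with a
    warning, never imputed.  ``gene_set`` optionally restricts allowed gene
    labels (targets plus references).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"ct table missing columns: {sorted(missing)}")
    if gene_set is not None:
        unknown = set(df["gene"].unique()) - set(gene_set)
        if unknown:
            raise InvalidInputError(f"unknown gene labels: {sorted(unknown)}")
    records = []
    n_dropped = 0
    for _, r in df.iterrows():
        ct = pd.to_numeric(r["ct"], errors="coerce")
        if pd.isna(ct) or ct <= 0:
            n_dropped += 1
            continue
        records.append(CtRecord(
            sample=str(r["sample"]), treatment=str(r["treatment"]),
            gene=str(r["gene"]), ct=float(ct), tech_replicate=int(r["tech_replicate"]),
        ))
    if n_dropped:
        logger.warning("dropped %d undetermined Ct wells", n_dropped)
    return records
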