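"""ROS assay quantification: DCF fluorescence and FOX-1 peroxide assay.

Two noninvasive whole-seed measurements are supported:

* DCFH-DA fluorimetry — the dye is deacetylated by seed esterases and
  oxidised by reactive species to fluorescent DCF; readings are relative
  fluorescence units (RFU) and are reported baseline-subtracted against a
  dye-only negative technical control.
* FOX-1 spectrophotometry — peroxides oxidise Fe(II) to Fe(III), which
  complexes xylenol orange (absorbance maximum near 560 nm); sample
  absorbances are converted to hydroperoxide concentration [ROOH] (uM) by
  inverse prediction on a linear calibration curve fitted to H2O2
  standards (0, 1.25, 2.50, 5 uM).

The calibration line is fitted with a free intercept: the 0 uM standard is
a measured reagent blank with nonzero colour, so forcing the line through
the origin would bias every inverse prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FluorescenceReading",
    "AbsorbanceReading",
    "CalibrationCurve",
    "PeroxideResult",
    "subtract_baseline",
    "fit_calibration",
    "predict_concentration",
    "read_assay_table",
    "quantify_fox1",
    "quantify_dcf",
]

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    pass


class UnusableCalibrationError(ValueError):
    """The fitted calibration cannot support inverse prediction (zero slope)."""


@dataclass(frozen=True)
class FluorescenceReading:
    """Single-cycle fluorimeter output for one sample (RFU)."""

    sample: str
    treatment: str
    rfu_raw: float
    dye_conc_uM: float = 10.0
    incubation_min: float = 30.0
    rfu_net: Optional[float] = None
    negative_net: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.rfu_raw):
            raise InvalidInputError("rfu_raw must be finite")
        if self.dye_conc_uM <= 0 or self.incubation_min <= 0:
            raise InvalidInputError("assay parameters must be positive")


@dataclass(frozen=True)
class AbsorbanceReading:
    """A560 reading; standards carry their known H2O2 concentration."""

    sample: str
    treatment: str
    a560: float
    is_standard: bool = False
    standard_conc: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.a560):
            raise InvalidInputError("a560 must be finite")
        if self.is_standard:
            if self.standard_conc is None or self.standard_conc < 0:
                raise InvalidInputError("standards need standard_conc >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float          # AU per uM
    intercept: float      # AU
    r_squared: float
    n_points: int
    concentration_range: tuple[float, float]


@dataclass(frozen=True)
class PeroxideResult:
    sample: str
    treatment: str
    rooh_conc: float      # uM, clipped at 0
    extrapolated: bool
    clipped: bool


def subtract_baseline(
    readings: Sequence[FluorescenceReading], blank: FluorescenceReading
) -> list[FluorescenceReading]:
    """Subtract the dye-only blank's fluorescence from each reading.

    The blank must have been measured under the same dye concentration and
    incubation time.  Negative net values are kept (they are informative
    about blank drift) but flagged.
    """
    out = []
    for r in readings:
        if (r.dye_conc_uM, r.incubation_min) != (blank.dye_conc_uM, blank.incubation_min):
            raise InvalidInputError(
                f"assay parameters of {r.sample!r} do not match the blank"
            )
        net = r.rfu_raw - blank.rfu_raw
        out.append(replace(r, rfu_net=net, negative_net=net < 0))
    return out


def fit_calibration(standards: Sequence[AbsorbanceReading]) -> CalibrationCurve:
    """Ordinary least-squares line of A560 on standard concentration.

    Requires at least three standards spanning more than one concentration.
    Logs a warning when R^2 < 0.98 (a FOX-1 run that flat should be
    repeated), but still returns the fit.
    """
    std = [s for s in standards if s.is_standard]
    if len(std) < 3:
        raise InvalidInputError("calibration needs >= 3 standard readings")
    conc = np.array([s.standard_conc for s in std], dtype=float)
    a560 = np.array([s.a560 for s in std], dtype=float)
    if np.unique(conc).size < 2:
        raise InvalidInputError("standards must span >= 2 distinct concentrations")
    fit = sps.linregress(conc, a560)
    r2 = float(fit.rvalue**2)
    if r2 < 0.98:
        logger.warning("FOX-1 calibration R^2 = %.4f (< 0.98)", r2)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_points=len(std),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def predict_concentration(
    curve: CalibrationCurve, a560: float, sample: str = "", treatment: str = ""
) -> PeroxideResult:
    """Inverse prediction: concentration = (A560 - intercept) / slope.

    Negative predictions are clipped to 0 uM with the ``clipped`` flag set
    (a concentration cannot be negative; the raw value is recoverable from
    the curve).  Predictions outside the standards' concentration range are
    flagged ``extrapolated``.
    """
    if curve.slope == 0:
        raise UnusableCalibrationError("calibration slope is zero")
    raw = (a560 - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    clipped = raw < 0
    return PeroxideResult(
        sample=sample,
        treatment=treatment,
        rooh_conc=max(raw, 0.0),
        extrapolated=bool(raw < lo or raw > hi),
        clipped=bool(clipped),
    )


# ---------------------------------------------------------------------------
# tabular I/O

ASSAY_COLUMNS = ["sample", "treatment", "assay", "value", "is_standard", "standard_conc_uM"]


def read_assay_table(path_or_df) -> pd.DataFrame:
    """Read the plate-reader CSV (assay in {DCF, FOX1})."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"assay table missing columns: {sorted(missing)}")
    bad = set(df["assay"].unique()) - {"DCF", "FOX1"}
    if bad:
        raise InvalidInputError(f"unknown assay labels: {sorted(bad)}")
    return df


def quantify_fox1(df: pd.DataFrame) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Full FOX-1 quantification from the assay table.

    Fits the calibration on rows flagged as standards and inverse-predicts
    [ROOH] for every sample row.  Returns the per-sample result table and
    the fitted curve.
    """
    fox = df[df["assay"] == "FOX1"]
    standards = [
        AbsorbanceReading(
            sample=str(r["sample"]), treatment=str(r["treatment"]), a560=float(r["value"]),
            is_standard=True, standard_conc=float(r["standard_conc_uM"]),
        )
        for _, r in fox[fox["is_standard"].astype(bool)].iterrows()
    ]
    curve = fit_calibration(standards)
    rows = []
    for _, r in fox[~fox["is_standard"].astype(bool)].iterrows():
        res = predict_concentration(
            curve, float(r["value"]), sample=str(r["sample"]), treatment=str(r["treatment"])
        )
        if res.clipped:
            logger.info("FOX-1 sample %s: negative prediction clipped to 0", res.sample)
        rows.append({
            "sample": res.sample, "treatment": res.treatment,
            "rooh_conc_uM": res.rooh_conc,
            "extrapolated": res.extrapolated, "clipped": res.clipped,
        })
    return pd.DataFrame(rows), curve


def quantify_dcf(df: pd.DataFrame, blank_sample: str) -> pd.DataFrame:
    """Baseline-subtracted DCF fluorescence from the assay table.

    ``blank_sample`` names the dye-only negative technical control row;
    its RFU is subtracted from every other DCF reading in the batch.
    """
    dcf = df[df["assay"] == "DCF"]
    blanks = dcf[dcf["sample"] == blank_sample]
    if len(blanks) != 1:
        raise InvalidInputError(
            f"expected exactly one blank row named {blank_sample!r}, found {len(blanks)}"
        )
    blank = FluorescenceReading(
        sample=blank_sample, treatment="blank", rfu_raw=float(blanks.iloc[0]["value"])
    )
    readings = [
        FluorescenceReading(sample=str(r["sample"]), treatment=str(r["treatment"]),
                            rfu_raw=float(r["value"]))
        for _, r in dcf[dcf["sample"] != blank_sample].iterrows()
    ]
    net = subtract_baseline(readings, blank)
    return pd.DataFrame([
        {"sample": r.sample, "treatment": r.treatment,
         "rfu_net": r.rfu_net, "negative_net": r.negative_net}
        for r in net
    ])
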