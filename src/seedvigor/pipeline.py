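"""End-to-end orchestration: validate inputs, run every stage, join the
replicate-level feature table, and write the report bundle.

Stage order mirrors the experiment: germination indices -> ROS
quantification (DCF net fluorescence, FOX-1 [ROOH]) -> qPCR relative
expression -> replicate-level join -> statistical layer (t-tests already
embedded in the germination summary; ANOVA + Tukey–Kramer letters for the
ROS responses; Pearson matrix over ROS and expression; PCA over
germination + ROS features).

Assay and qPCR sample identifiers are expected as ``<treatment>_<k>``;
the trailing integer is the biological replicate used as the join key
against germination replicates.  All outputs are plain CSV plus a JSON run
manifest (config, package version, input digests) so a rerun with
identical inputs is byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import germination as germ
from . import qpcr as qx
from . import ros
from . import statistics as st

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_all"]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (all stages optional but ordered)."""

    counts_csv: Optional[str] = None
    assays_csv: Optional[str] = None
    ct_csv: Optional[str] = None
    outdir: str = "seedvigor_out"
    species: str = "soybean"
    control: str = "CTRL"
    reference_genes: tuple[str, ...] = ("CYP", "RP40S")
    gene_set: Optional[tuple[str, ...]] = None
    alpha: float = 0.05
    dispersion: str = "sd"          # "sd" or "sem" in summaries
    efficiency: float = 1.0          # qPCR amplification efficiency
    dcf_blank_sample: str = "blank"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "reference_genes" in raw:
            raw["reference_genes"] = tuple(raw["reference_genes"])
        if raw.get("gene_set") is not None:
            raw["gene_set"] = tuple(raw["gene_set"])
        return cls(**raw)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema- and invariant-check every configured input file.

    Collects row-level violations (negative counts, duplicate
    replicate-days, unknown genes, malformed headers) into the report;
    callers decide whether to abort.
    """
    rep = ValidationReport()
    if config.counts_csv is not None:
        try:
            df = pd.read_csv(config.counts_csv)
            missing = set(germ.COUNTS_COLUMNS) - set(df.columns)
            if missing:
                rep.violations.append(f"counts: missing columns {sorted(missing)}")
            else:
                for col in ("day", "new_germinated", "total_seeds"):
                    bad = pd.to_numeric(df[col], errors="coerce").isna()
                    for i in df.index[bad]:
                        rep.violations.append(f"counts row {i}: non-numeric {col}")
                if not rep.violations:
                    neg = df.index[df["new_germinated"] < 0]
                    for i in neg:
                        rep.violations.append(f"counts row {i}: negative new_germinated")
                    dup = df.duplicated(["species", "treatment", "replicate", "day"])
                    for i in df.index[dup]:
                        rep.violations.append(f"counts row {i}: duplicate replicate-day")
                    for key, grp in df.groupby(["species", "treatment", "replicate"]):
                        if grp["new_germinated"].sum() > grp["total_seeds"].iloc[0]:
                            rep.violations.append(
                                f"counts {key}: germinated exceeds total_seeds")
        except Exception as exc:  # malformed file
            rep.violations.append(f"counts: unreadable ({exc})")
    if config.assays_csv is not None:
        try:
            ros.read_assay_table(config.assays_csv)
        except Exception as exc:
            rep.violations.append(f"assays: {exc}")
    if config.ct_csv is not None:
        try:
            qx.read_ct_table(config.ct_csv, gene_set=config.gene_set)
        except Exception as exc:
            rep.violations.append(f"ct: {exc}")
    return rep


def _replicate_of(sample: str) -> str:
    """Biological replicate index from a ``<treatment>_<k>`` sample id."""
    return sample.rsplit("_", 1)[-1]


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict[str, object]:
    """Execute all configured stages and write the report bundle.

    Returns the in-memory results keyed by artifact name.  Stages whose
    input file is not configured are skipped with a log line; any stage
    failure propagates with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report.ok:
        raise ValidationError(
            f"{len(report.violations)} input violation(s): " + "; ".join(report.violations)
        )
    results: dict[str, object] = {}
    feature_frames: list[pd.DataFrame] = []

    # --- germination stage -------------------------------------------------
    if config.counts_csv is not None:
        try:
            tcs = germ.read_time_courses(config.counts_csv)
            idx = germ.indices_table(tcs)
            summ = germ.summary_table(tcs, control=config.control, alpha=config.alpha,
                                      dispersion=config.dispersion)
        except Exception as exc:
            raise RuntimeError(f"germination stage failed: {exc}") from exc
        idx.to_csv(out / "germination_indices.csv", index=False)
        summ.to_csv(out / "germination_summary.csv", index=False)
        results["indices"] = idx
        results["germination_summary"] = summ
        feat = idx.drop(columns=["species"]).set_index(["treatment", "replicate"])
        feature_frames.append(feat)
    else:
        logger.info("germination stage skipped (no counts file)")

    # --- ROS stage ---------------------------------------------------------
    if config.assays_csv is not None:
        try:
            assay_df = ros.read_assay_table(config.assays_csv)
            fox, curve = ros.quantify_fox1(assay_df)
            dcf = ros.quantify_dcf(assay_df, config.dcf_blank_sample)
        except Exception as exc:
            raise RuntimeError(f"ROS stage failed: {exc}") from exc
        fox.to_csv(out / "fox1_rooh.csv", index=False)
        dcf.to_csv(out / "dcf_rfu.csv", index=False)
        cal = pd.DataFrame([dataclasses.asdict(curve)])
        cal.to_csv(out / "fox1_calibration.csv", index=False)
        logger.info("FOX-1 calibration R^2 = %.4f", curve.r_squared)
        results["fox1"] = fox
        results["dcf"] = dcf
        results["calibration"] = curve
        fox_rep = (fox.assign(replicate=fox["sample"].map(_replicate_of))
                   .groupby(["treatment", "replicate"])["rooh_conc_uM"].mean()
                   .rename("FOX1").to_frame())
        dcf_rep = (dcf.assign(replicate=dcf["sample"].map(_replicate_of))
                   .groupby(["treatment", "replicate"])["rfu_net"].mean()
                   .rename("DCF").to_frame())
        feature_frames.append(fox_rep.join(dcf_rep, how="outer"))
    else:
        logger.info("ROS stage skipped (no assay file)")

    # --- qPCR stage --------------------------------------------------------
    if config.ct_csv is not None:
        try:
            records = qx.read_ct_table(config.ct_csv, gene_set=config.gene_set)
            expr = qx.relative_expression_table(
                records, list(config.reference_genes), config.control,
                efficiency=config.efficiency, alpha=config.alpha,
            )
            norm = qx._sample_normalized(records, list(config.reference_genes),
                                         config.efficiency)
        except Exception as exc:
            raise RuntimeError(f"qPCR stage failed: {exc}") from exc
        expr.to_csv(out / "relative_expression.csv", index=False)
        results["expression"] = expr
        # per-sample fold vs control mean, one column per gene, for the join
        ctrl_means = (norm[norm["treatment"] == config.control]
                      .groupby("gene")["norm_x0"].mean())
        norm = norm.assign(
            fold=norm["norm_x0"] / norm["gene"].map(ctrl_means),
            replicate=norm["sample"].map(_replicate_of),
        )
        wide = norm.pivot_table(index=["treatment", "replicate"], columns="gene",
                                values="fold")
        wide.columns.name = None
        feature_frames.append(wide)
    else:
        logger.info("qPCR stage skipped (no Ct file)")

    # --- join + statistical layer -----------------------------------------
    if feature_frames:
        features = feature_frames[0]
        for f in feature_frames[1:]:
            features = features.join(f, how="outer")
        features = features.reset_index()
        features.to_csv(out / "features.csv", index=False)
        results["features"] = features

        numeric = [c for c in features.columns
                   if c not in ("treatment", "replicate")
                   and pd.api.types.is_numeric_dtype(features[c])]
        # ANOVA + letters per ROS response, treatments as the lettered factor
        letter_rows = []
        for response in ("FOX1", "DCF"):
            if response not in features.columns:
                continue
            sub = features[["treatment", response]].dropna()
            counts = sub.groupby("treatment").size()
            if counts.size >= 2 and (counts >= 2).all():
                grouped = {t: g[response].to_numpy() for t, g in sub.groupby("treatment")}
                pw = st.tukey_kramer(grouped, alpha=config.alpha)
                means = {t: float(v.mean()) for t, v in grouped.items()}
                for ld in st.compact_letter_display(pw, means):
                    letter_rows.append({"response": response, "group": ld.group,
                                        "mean": means[ld.group], "letters": ld.letters})
                pw.assign(response=response).to_csv(
                    out / f"tukey_{response.lower()}.csv", index=False)
        if letter_rows:
            letters = pd.DataFrame(letter_rows)
            letters.to_csv(out / "letters.csv", index=False)
            results["letters"] = letters

        corr_cols = [c for c in numeric if c not in germ.INDEX_NAMES]
        if len(corr_cols) >= 2:
            r, p = st.pearson_matrix(features, corr_cols)
            r.to_csv(out / "pearson_r.csv")
            p.to_csv(out / "pearson_p.csv")
            results["pearson_r"], results["pearson_p"] = r, p

        pca_cols = [c for c in ("G", "PV", "MGT", "Z", "FOX1", "DCF") if c in numeric]
        pca_input = features.dropna(subset=pca_cols) if pca_cols else pd.DataFrame()
        if len(pca_cols) >= 2 and len(pca_input) >= 3:
            res = st.pca(pca_input, pca_cols)
            scores = res.scores.copy()
            scores.insert(0, "treatment", pca_input["treatment"].to_numpy())
            scores.insert(1, "replicate", pca_input["replicate"].to_numpy())
            scores.to_csv(out / "pca_scores.csv", index=False)
            res.loadings.to_csv(out / "pca_loadings.csv")
            pd.DataFrame({"component": res.loadings.columns,
                          "explained_variance_ratio":
                          res.explained_variance_ratio}).to_csv(
                out / "pca_variance.csv", index=False)
            results["pca"] = res

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "package_version": __version__,
        "inputs": {
            name: _digest(p) for name, p in
            (("counts", config.counts_csv), ("assays", config.assays_csv),
             ("ct", config.ct_csv)) if p is not None
        },
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
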