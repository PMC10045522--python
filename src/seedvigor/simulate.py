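"""Synthetic-data generator for the seed-vigor pipeline.

Emulates the measurement design the pipeline expects — germination tests of
20 seeds x 3 replicate dishes scored daily (3 days for soybean, 5 for
wheat, 6 for tomato), FOX-1 plate readings with H2O2 calibration standards
at 0/1.25/2.50/5 uM, DCF fluorimetry with a dye-only blank, and qPCR Ct
triplicates for seven target genes against two reference genes — so every
pipeline stage is testable without laboratory data and parameter recovery
can be verified against known truths.

Scenarios are phenomenological: each seed germinates independently with a
final probability, and its germination day is a discretized unimodal
(gamma) variable truncated to the monitoring window; seeds whose latent
day falls after the window are silently censored, exactly as an unobserved
seed in a real test.  All randomness flows through one seeded
``numpy.random.Generator`` per call; a fixed seed reproduces output
bit-for-bit.

The ``paper_like_*`` templates encode the qualitative structure of a
hydropriming study: heat-shocked (HS) seeds never germinate and carry the
highest ROS load, hydroprimed (HP) seeds germinate faster and more
synchronously than untreated controls (CTRL) and carry the lowest ROS, and
ROS-turnover genes are upregulated after imbibition and after dry-back.
Effect sizes are order-of-magnitude defaults, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .germination import GerminationTimeCourse
from .qpcr import CtRecord

__all__ = [
    "GerminationScenario",
    "AssayScenario",
    "QpcrScenario",
    "simulate_germination",
    "simulate_assays",
    "simulate_ct",
    "expected_mgt",
    "paper_like_germination",
    "paper_like_assays",
    "paper_like_qpcr",
    "write_paper_like_bundle",
    "MONITORING_DAYS",
]

#: daily-monitoring window length per species (days)
MONITORING_DAYS = {"soybean": 3, "wheat": 5, "tomato": 6}


class InvalidScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class GerminationScenario:
    """Truth for one treatment's germination time courses."""

    treatment: str
    p_germ: float                 # final germination probability per seed
    mgt_true: float               # mean of the latent germination-day distribution (days)
    dispersion: float = 0.6      # SD of the latent distribution (days); 0 = point mass
    n_seeds: int = 20
    n_replicates: int = 3
    monitoring_days: int = 3
    species: str = "soybean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_germ <= 1:
            raise InvalidScenarioError("p_germ must be in [0, 1]")
        if not 0 < self.mgt_true <= self.monitoring_days:
            raise InvalidScenarioError("mgt_true must lie in (0, monitoring_days]")
        if self.dispersion < 0:
            raise InvalidScenarioError("dispersion must be >= 0")


def _day_pmf(scenario: GerminationScenario) -> np.ndarray:
    """Probability of each latent germination day 1..monitoring_days.

    The continuous gamma (mean ``mgt_true``, SD ``dispersion``) is
    discretized by rounding to the nearest day with a floor of day 1; the
    entries do not sum to 1 — the remainder is the censored mass beyond
    the window.
    """
    D = scenario.monitoring_days
    if scenario.dispersion == 0:
        pmf = np.zeros(D)
        d = int(round(scenario.mgt_true))
        d = min(max(d, 1), D)
        pmf[d - 1] = 1.0
        return pmf
    shape = (scenario.mgt_true / scenario.dispersion) ** 2
    scale = scenario.dispersion**2 / scenario.mgt_true
    dist = sps.gamma(a=shape, scale=scale)
    edges = np.arange(0.5, D + 1.0)  # 0.5, 1.5, ..., D+0.5
    cdf = dist.cdf(edges)
    pmf = np.diff(cdf)
    pmf[0] = cdf[1]  # day 1 absorbs all mass below 1.5
    return pmf


def expected_mgt(scenario: GerminationScenario) -> float:
    """Analytic mean germination day conditional on germinating in-window.

    This is the censoring-adjusted truth the pipeline's MGT estimate
    converges to as replication grows.
    """
    pmf = _day_pmf(scenario)
    total = pmf.sum()
    if total == 0:
        raise InvalidScenarioError("no in-window germination mass")
    days = np.arange(1, scenario.monitoring_days + 1)
    return float((days * pmf).sum() / total)


def simulate_germination(
    scenario: GerminationScenario, rng: Optional[np.random.Generator] = None
) -> list[GerminationTimeCourse]:
    """Draw the scenario's replicate time courses.

    Each seed germinates with probability ``p_germ``; germinating seeds
    draw a latent continuous day, which is rounded to the nearest
    monitoring day (floor day 1) and censored when it falls after the
    window.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.rng_seed)
    D = scenario.monitoring_days
    out = []
    for rep in range(1, scenario.n_replicates + 1):
        counts = np.zeros(D, dtype=int)
        n_germ = rng.binomial(scenario.n_seeds, scenario.p_germ)
        if scenario.dispersion == 0:
            day = min(max(int(round(scenario.mgt_true)), 1), D)
            counts[day - 1] = n_germ
        else:
            shape = (scenario.mgt_true / scenario.dispersion) ** 2
            scale = scenario.dispersion**2 / scenario.mgt_true
            latent = rng.gamma(shape, scale, size=n_germ)
            days = np.maximum(np.rint(latent).astype(int), 1)
            for d in days[days <= D]:
                counts[d - 1] += 1
        out.append(GerminationTimeCourse(
            species=scenario.species, treatment=scenario.treatment,
            replicate=str(rep), total_seeds=scenario.n_seeds,
            times=tuple(float(d) for d in range(1, D + 1)),
            counts=tuple(int(c) for c in counts),
        ))
    return out


# ---------------------------------------------------------------------------
# plate-reader assays


@dataclass(frozen=True)
class AssayScenario:
    """Truth for FOX-1 and DCF plate readings across treatments."""

    rooh_true: Mapping[str, float]            # uM per treatment
    rfu_true: Mapping[str, float]             # net RFU per treatment
    cv: float = 0.10                          # coefficient of variation of true signals
    cal_slope: float = 0.10                   # AU per uM
    cal_intercept: float = 0.05               # AU (reagent blank colour)
    cal_noise_sd: float = 0.005               # AU measurement noise
    blank_rfu: float = 200.0                  # dye-only fluorescence
    n_samples: int = 3                        # biological samples per treatment
    n_seeds_per_sample: int = 5               # FOX-1 seed replicates per sample
    standard_concs: tuple[float, ...] = (0.0, 1.25, 2.50, 5.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rooh_true.values()):
            raise InvalidScenarioError("true [ROOH] means must be >= 0")
        if any(v < 0 for v in self.rfu_true.values()):
            raise InvalidScenarioError("true RFU means must be >= 0")
        if self.cv < 0:
            raise InvalidScenarioError("cv must be >= 0")


def simulate_assays(
    scenario: AssayScenario, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Emit the plate-reader table (DCF + FOX1 rows, standards included).

    FOX-1 sample absorbances are generated from per-seed true [ROOH]
    (lognormal around the treatment mean with the scenario CV) through the
    true calibration line plus measurement noise; DCF readings are the
    blank plus lognormal net fluorescence.  Sample ids are
    ``<treatment>_<k>`` so downstream joins can recover the replicate.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.rng_seed)
    rows = []

    def lognorm(mean: float, size: int) -> np.ndarray:
        if mean == 0 or scenario.cv == 0:
            return np.full(size, mean)
        sigma = np.sqrt(np.log1p(scenario.cv**2))
        mu = np.log(mean) - sigma**2 / 2
        return rng.lognormal(mu, sigma, size=size)

    for conc in scenario.standard_concs:
        a = scenario.cal_intercept + scenario.cal_slope * conc
        a += rng.normal(0, scenario.cal_noise_sd)
        rows.append({"sample": f"std_{conc:g}", "treatment": "standard", "assay": "FOX1",
                     "value": a, "is_standard": True, "standard_conc_uM": conc})
    for trt, mean in scenario.rooh_true.items():
        for k in range(1, scenario.n_samples + 1):
            true_c = lognorm(mean, scenario.n_seeds_per_sample)
            a = (scenario.cal_intercept + scenario.cal_slope * true_c
                 + rng.normal(0, scenario.cal_noise_sd, size=true_c.size))
            for val in a:
                rows.append({"sample": f"{trt}_{k}", "treatment": trt, "assay": "FOX1",
                             "value": float(val), "is_standard": False,
                             "standard_conc_uM": np.nan})
    rows.append({"sample": "blank", "treatment": "blank", "assay": "DCF",
                 "value": scenario.blank_rfu, "is_standard": False,
                 "standard_conc_uM": np.nan})
    for trt, mean in scenario.rfu_true.items():
        net = lognorm(mean, scenario.n_samples)
        for k, val in enumerate(net, 1):
            rows.append({"sample": f"{trt}_{k}", "treatment": trt, "assay": "DCF",
                         "value": scenario.blank_rfu + float(val), "is_standard": False,
                         "standard_conc_uM": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrScenario:
    """Truth for qPCR Ct generation.

    ``fold_true`` maps gene -> treatment -> true fold change vs control;
    reference genes sit at a stable baseline perturbed by
    ``ref_stability_sd`` per sample, and every well receives technical
    noise of SD ``tech_sd`` across ``n_tech`` replicate reactions.
    """

    fold_true: Mapping[str, Mapping[str, float]]
    control: str = "CTRL"
    reference_genes: tuple[str, ...] = ("CYP", "RP40S")
    baseline_ct: float = 26.0                 # control-target Ct
    ref_ct: float = 21.0                      # reference-gene Ct
    ref_stability_sd: float = 0.10            # cycles, per-sample reference wobble
    tech_sd: float = 0.10                     # cycles, per-well technical noise
    bio_sd: float = 0.15                      # cycles, per-sample biological wobble
    efficiency: float = 1.0
    n_bio: int = 3
    n_tech: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for g in self.fold_true.values() for f in g.values()):
            raise InvalidScenarioError("fold changes must be > 0")
        if min(self.ref_stability_sd, self.tech_sd, self.bio_sd) < 0:
            raise InvalidScenarioError("noise SDs must be >= 0")
        if not 0 < self.efficiency <= 1:
            raise InvalidScenarioError("efficiency must be in (0, 1]")

    @property
    def treatments(self) -> list[str]:
        trts = {self.control}
        for g in self.fold_true.values():
            trts.update(g)
        return sorted(trts)


def simulate_ct(
    scenario: QpcrScenario, rng: Optional[np.random.Generator] = None
) -> list[CtRecord]:
    """Generate Ct triplicates for every sample x gene well.

    A true fold change F shifts the target Ct by ``-log_{1+E}(F)`` cycles
    relative to the control baseline.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.rng_seed)
    log_base = np.log(1.0 + scenario.efficiency)
    records = []
    for trt in scenario.treatments:
        for b in range(1, scenario.n_bio + 1):
            sample = f"{trt}_{b}"
            for gene in scenario.reference_genes:
                center = scenario.ref_ct + rng.normal(0, scenario.ref_stability_sd)
                for t in range(1, scenario.n_tech + 1):
                    ct = center + rng.normal(0, scenario.tech_sd)
                    records.append(CtRecord(sample=sample, treatment=trt, gene=gene,
                                            ct=float(ct), tech_replicate=t))
            for gene, folds in scenario.fold_true.items():
                fold = 1.0 if trt == scenario.control else folds.get(trt, 1.0)
                center = (scenario.baseline_ct - np.log(fold) / log_base
                          + rng.normal(0, scenario.bio_sd))
                for t in range(1, scenario.n_tech + 1):
                    ct = center + rng.normal(0, scenario.tech_sd)
                    records.append(CtRecord(sample=sample, treatment=trt, gene=gene,
                                            ct=float(ct), tech_replicate=t))
    return records


# ---------------------------------------------------------------------------
# "paper-like" templates: the study conditions in scenario form

_GERM_TEMPLATES = {
    # treatment -> (p_germ, mgt_true, dispersion); window from MONITORING_DAYS
    "soybean": {
        "CTRL": (0.65, 2.2, 0.80),
        "HP2": (0.85, 1.45, 0.60),
        "HP4": (0.95, 1.25, 0.45),
        "HP8": (0.90, 1.35, 0.60),
        "HS": (0.0, 1.0, 0.50),
    },
    "wheat": {
        "CTRL": (0.80, 2.6, 1.00),
        "HP2": (0.90, 2.2, 0.80),
        "HP4": (0.92, 2.0, 0.70),
        "HP6": (0.90, 2.1, 0.80),
        "HS": (0.0, 1.0, 0.50),
    },
    "tomato": {
        "CTRL": (0.75, 3.6, 1.20),
        "HP2": (0.88, 3.0, 1.00),
        "HP8": (0.92, 2.8, 0.90),
        "HP24": (0.85, 3.0, 1.00),
        "HS": (0.0, 1.0, 0.50),
    },
}

#: true [ROOH] (uM) and net RFU per treatment: HS highest, HP lowest
_ASSAY_ROOH = {"CTRL": 2.0, "HP2": 1.0, "HP4": 0.8, "HP8": 1.0, "HPDB": 1.2, "HS": 3.5}
_ASSAY_RFU = {"CTRL": 900.0, "HP2": 450.0, "HP4": 350.0, "HP8": 450.0,
              "HPDB": 550.0, "HS": 1800.0}

#: fold changes vs CTRL at imbibition (HP4) and after dry-back (HP4DB);
#: scavenging genes strongly up, Rboh production genes mildly up,
#: MnSOD not significant at HP4 and APX2 not after dry-back
_QPCR_FOLDS = {
    "MnSOD": {"HP4": 1.15, "HP4DB": 2.0},
    "SOD1": {"HP4": 2.5, "HP4DB": 2.2},
    "CAT1": {"HP4": 6.0, "HP4DB": 5.0},
    "CAT5": {"HP4": 5.0, "HP4DB": 4.0},
    "APX2": {"HP4": 3.0, "HP4DB": 1.1},
    "RbohE2": {"HP4": 1.6, "HP4DB": 1.5},
    "RbohC2": {"HP4": 2.0, "HP4DB": 1.8},
}


def paper_like_germination(species: str = "soybean", rng_seed: int = 0
                           ) -> list[GerminationScenario]:
    """One scenario per treatment for the given species."""
    if species not in _GERM_TEMPLATES:
        raise InvalidScenarioError(f"unknown species {species!r}")
    D = MONITORING_DAYS[species]
    return [
        GerminationScenario(
            treatment=trt, p_germ=p, mgt_true=m, dispersion=s,
            monitoring_days=D, species=species, rng_seed=rng_seed,
        )
        for trt, (p, m, s) in _GERM_TEMPLATES[species].items()
    ]


def paper_like_assays(rng_seed: int = 0) -> AssayScenario:
    return AssayScenario(rooh_true=dict(_ASSAY_ROOH), rfu_true=dict(_ASSAY_RFU),
                         rng_seed=rng_seed)


def paper_like_qpcr(rng_seed: int = 0) -> QpcrScenario:
    return QpcrScenario(fold_true={g: dict(t) for g, t in _QPCR_FOLDS.items()},
                        rng_seed=rng_seed)


def write_paper_like_bundle(outdir, species: str = "soybean", rng_seed: int = 0
                            ) -> dict[str, str]:
    """Write the three input CSVs a pipeline run consumes; returns their paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    germ_rows = []
    for scen in paper_like_germination(species, rng_seed):
        for tc in simulate_germination(scen, rng):
            for t, c in zip(tc.times, tc.counts):
                germ_rows.append({
                    "species": tc.species, "treatment": tc.treatment,
                    "replicate": tc.replicate, "day": t,
                    "new_germinated": c, "total_seeds": tc.total_seeds,
                })
    counts_path = outdir / "germination_counts.csv"
    pd.DataFrame(germ_rows).to_csv(counts_path, index=False)

    assay_path = outdir / "assay_readings.csv"
    simulate_assays(paper_like_assays(rng_seed), rng).to_csv(assay_path, index=False)

    ct_rows = [
        {"sample": r.sample, "treatment": r.treatment, "gene": r.gene,
         "tech_replicate": r.tech_replicate, "ct": r.ct}
        for r in simulate_ct(paper_like_qpcr(rng_seed), rng)
    ]
    ct_path = outdir / "qpcr_ct.csv"
    pd.DataFrame(ct_rows).to_csv(ct_path, index=False)
    return {"counts": str(counts_path), "assays": str(assay_path), "ct": str(ct_path)}
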