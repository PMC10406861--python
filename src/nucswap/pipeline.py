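"""End-to-end orchestration: simulate → correct → classify → census → fit.

A run is fully specified by a :class:`RunConfig` (scenario, generator
settings, correction factors, QC/classification rules, kinetics settings,
master seed) and is deterministic given its seed.  Named condition
fixtures carry the published rate constants of the eight-plus measurement
conditions (salt, temperature, Nap1, H3K56ac mimic, CpG methylation)
purely as regression expectations for rate comparisons — they are never
used as fit inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ClassificationRules, QCThresholds, TimeCourse,
                       TraceClassifier, compute_census)
from .correction import LeakageCorrector, LeakageFactors, BaselineError
from .kinetics import (DEFAULT_C_REF, ExchangeRateModel, RateFit,
                       compare_rates, exchange_timescale)
from .simulate import (BenchmarkDataset, TimeCourseDesign,
                       TraceSimulationParams, generate_benchmark_dataset)

#: Published rate constants (M^-1 s^-1) and their fit standard errors for
#: the measured conditions; regression expectations only.
CONDITION_FITS: Dict[str, Tuple[float, float]] = {
    "unmod_low_salt": (356.0, 64.0),      # 10 mM NaCl, 4 C
    "unmod_high_salt": (686.0, 111.0),    # 50 mM NaCl + 150 mM KCl, 4 C
    "unmod_25C": (414.0, 64.0),           # 10 mM NaCl, 25 C
    "unmod_nap1": (683.0, 94.0),          # + 400 nM Nap1, 4 C
    "h3kac_low_salt": (1000.0, 200.0),    # H3K56ac mimic
    "h3kac_high_salt": (916.0, 139.0),
    "h3kac_25C": (1040.0, 180.0),
    "h3kac_nap1": (1380.0, 170.0),
    "cpgme_low_salt": (277.0, 42.0),      # CpG methylated
    "cpgme_high_salt": (397.0, 51.0),
    "cpgme_25C": (400.0, 53.0),
    "cpgme_nap1": (626.0, 72.0),
}

#: Pairwise significance verdicts stated for the measured conditions under
#: the difference-vs-sum-of-errors criterion.
CONDITION_VERDICTS: List[Tuple[str, str, bool]] = [
    ("unmod_high_salt", "unmod_low_salt", True),
    ("unmod_25C", "unmod_low_salt", False),
    ("unmod_nap1", "unmod_low_salt", True),
    ("h3kac_low_salt", "unmod_low_salt", True),
    ("h3kac_high_salt", "unmod_high_salt", False),
    ("h3kac_25C", "unmod_25C", True),
    ("h3kac_nap1", "unmod_nap1", True),
    ("cpgme_low_salt", "unmod_low_salt", False),
    ("cpgme_high_salt", "unmod_high_salt", True),
    ("cpgme_25C", "unmod_25C", False),
    ("cpgme_nap1", "unmod_nap1", False),
]


class StageError(RuntimeError):
    """A pipeline stage failed; message is stage-tagged."""


@dataclass
class RunConfig:
    scenario: str = "unmod_low_salt"  # fixture name or "custom"
    design: TimeCourseDesign = field(default_factory=TimeCourseDesign)
    params: TraceSimulationParams = field(default_factory=TraceSimulationParams)
    leakage: LeakageFactors = field(default_factory=LeakageFactors)
    qc: QCThresholds = field(default_factory=QCThresholds)
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    denominator: str = "all"
    amplitude_fixed: bool = True
    weighted: bool = False
    C_ref: float = DEFAULT_C_REF
    out_dir: Optional[Path] = None
    write_traces: bool = False
    population: str = "closed_form"

    def __post_init__(self) -> None:
        if self.scenario != "custom":
            if self.scenario not in CONDITION_FITS:
                raise ValueError(
                    f"unknown scenario {self.scenario!r}; use one of "
                    f"{sorted(CONDITION_FITS)} or 'custom'"
                )
            k_ref = CONDITION_FITS[self.scenario][0]
            if self.design.k_true != k_ref:
                self.design = dataclasses.replace(self.design, k_true=k_ref)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    scenario: str
    seed: int
    config_hash: str
    n_traces: int
    n_qc_pass: int
    class_counts: Dict[str, int]
    census: pd.DataFrame
    fit: RateFit
    timescale_s: float
    timescale_se_s: float
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "n_traces": self.n_traces,
            "n_qc_pass": self.n_qc_pass,
            "class_counts": dict(sorted(self.class_counts.items())),
            "census": self.census.to_dict(orient="records"),
            "fit": {
                "k_hat": self.fit.k_hat,
                "se_k": self.fit.se_k,
                "k_rounded_3sig": self.fit.k_rounded,
                "amplitude": self.fit.amplitude,
                "exponent_coeff": self.fit.exponent_coeff,
                "amplitude_fixed": self.fit.amplitude_fixed,
                "C_total": self.fit.C_total,
                "F": self.fit.F,
                "flags": list(self.fit.flags),
            },
            "timescale_at_Cref": {
                "t_s": self.timescale_s,
                "se_t_s": self.timescale_se_s,
            },
        }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages on a synthetic dataset and assemble the report."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    try:
        dataset: BenchmarkDataset = generate_benchmark_dataset(
            config.design, config.params, out_dir=out,
            population=config.population, write_traces=config.write_traces,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"simulate: {exc}") from exc

    # --- correct ----------------------------------------------------------
    corrected = []
    n_baseline_fail = 0
    for tr in dataset.traces:
        try:
            corr = LeakageCorrector(
                r5=config.leakage.r5, r5_5=config.leakage.r5_5
            ).fit(tr).transform(tr)
        except BaselineError:
            n_baseline_fail += 1
            continue
        corrected.append(corr)
    if not corrected:
        raise StageError("correct: no trace offered a usable baseline")

    # --- classify ---------------------------------------------------------
    clf = TraceClassifier(rules=config.rules, qc=config.qc).fit()
    table = clf.analyze(corrected)
    if out:
        table.to_csv(out / "classification.csv", index=False,
                     float_format="%.6f")

    # --- census -----------------------------------------------------------
    census = compute_census(table, denominator=config.denominator)
    if census.summary["n_qualifying"].sum() == 0 or len(census.summary) == 0:
        raise StageError("census: no qualifying molecules")
    if out:
        census.by_replicate.to_csv(out / "census_replicates.csv", index=False,
                                   float_format="%.6f")
        census.summary.to_csv(out / "census.csv", index=False,
                              float_format="%.6f")

    # --- fit --------------------------------------------------------------
    usable = census.summary.dropna(subset=["fraction"])
    est = ExchangeRateModel(
        F=config.design.F, C_total=config.design.C_total,
        amplitude_fixed=config.amplitude_fixed, weighted=config.weighted,
    )
    try:
        est.fit(usable["time_h"].to_numpy(float) * 3600.0,
                usable["fraction"].to_numpy(float),
                sd=usable["sd"].to_numpy(float),
                condition=config.scenario)
    except Exception as exc:
        raise StageError(f"fit: {exc}") from exc
    fit = est.fit_result_
    ts = exchange_timescale(fit, C_ref=config.C_ref)

    report = RunReport(
        scenario=config.scenario,
        seed=config.design.seed,
        config_hash=config.config_hash(),
        n_traces=len(dataset.traces),
        n_qc_pass=int(table["qc_pass"].sum()),
        class_counts=table.loc[table["qc_pass"], "class"]
        .value_counts().to_dict(),
        census=census.summary,
        fit=fit,
        timescale_s=ts.t_exchange,
        timescale_se_s=ts.se_t,
    )
    if out:
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")
    return report


def compare_conditions(reports: Sequence) -> pd.DataFrame:
    """All pairwise rate comparisons among fitted or fixture conditions.

    Accepts :class:`RunReport` objects, ``(name, k, se)`` triples, or
    fixture names from :data:`CONDITION_FITS`.
    """
    entries = []
    for r in reports:
        if isinstance(r, RunReport):
            entries.append((r.scenario, r.fit.k_hat, r.fit.se_k))
        elif isinstance(r, str):
            k, se = CONDITION_FITS[r]
            entries.append((r, k, se))
        else:
            name, k, se = r
            entries.append((str(name), float(k), float(se)))
    rows = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            (na, ka, sa), (nb, kb, sb) = entries[i], entries[j]
            cmp = compare_rates((ka, sa), (kb, sb))
            rows.append(
                {
                    "condition_a": na, "condition_b": nb,
                    "k_a": ka, "se_a": sa, "k_b": kb, "se_b": sb,
                    "difference": cmp.difference,
                    "sum_of_errors": cmp.sum_of_errors,
                    "significant": cmp.significant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["condition_a", "condition_b", "k_a", "se_a", "k_b", "se_b",
                 "difference", "sum_of_errors", "significant"],
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj
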