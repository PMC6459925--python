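"""End-to-end orchestration: simulate -> normalize -> select -> fit -> survive.

One structured config drives the whole run.  A single global seed is set;
per-stage seeds are derived by stable hashing of the stage name so stages
stay decoupled yet the whole run is reproducible bit-for-bit at the
declared float precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .discriminant import exhaustive_search
from .funnel import FunnelConfig, run_funnel
from .normalize import NormalizationParams, normalize_chain
from .simulate import SimulationConfig, simulate
from .survival import cox_fit, km_fit, logrank, multivariate_select
from .types import Group, TimePoint

log = logging.getLogger("mirecur")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "RunReport"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    normalization: NormalizationParams = field(
        default_factory=NormalizationParams
    )
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    max_panel_size: int = 3
    hr_threshold: float = 2.0
    endpoints: tuple[str, ...] = ("rfs", "os")
    log2: bool = True
    seed: int = 0
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed by stable hashing of the stage name."""
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every problem as a diagnostic string; never raises."""
    diags: list[str] = []
    for name, obj in (
        ("simulation", config.simulation),
        ("normalization", config.normalization),
        ("funnel", config.funnel),
    ):
        try:
            obj.validate()
        except Exception as exc:
            diags.append(f"{name}: {exc}")
    if config.max_panel_size < 1:
        diags.append("max_panel_size must be >= 1")
    if not set(config.endpoints) <= {"rfs", "os"}:
        diags.append(f"unknown endpoints: {set(config.endpoints) - {'rfs', 'os'}}")
    if config.hr_threshold < 0:
        diags.append("hr_threshold must be >= 0")
    return diags


@dataclass
class RunReport:
    """Consolidated report of one pipeline run."""

    funnel_counts: dict
    candidate_table: pd.DataFrame
    best_combination_table: pd.DataFrame
    index_definition: dict
    survival_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "funnel_counts": self.funnel_counts,
            "candidate_table": self.candidate_table.to_dict(orient="records"),
            "best_combination_table": self.best_combination_table.to_dict(
                orient="records"
            ),
            "index_definition": self.index_definition,
            "survival_summary": self.survival_summary,
            "provenance": self.provenance,
        }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in fixed order on a simulated cohort.

    Writes intermediate artifacts when ``config.out_dir`` is set, and
    assembles a report mirroring the funnel-count, per-candidate,
    best-panel and survival table shapes of a recurrence-index study.
    """
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))

    sim = dataclasses.replace(config.simulation,
                              seed=config.stage_seed("simulate"))
    panel, cohort, samples, raw, truth = simulate(sim)
    log.info("simulated %d patients / %d arrays / %d probes",
             len(cohort), len(samples), len(raw.probe_ids))

    norm = normalize_chain(raw, panel, config.normalization, log2=config.log2)
    log.info("normalized to stage %s: %d x %d", norm.stage.value,
             *norm.values.shape)

    report = run_funnel(norm, samples, cohort, config.funnel)
    counts = report.counts()
    log.info("funnel counts: %s", counts)

    candidates = sorted(report.final_up | report.final_down)
    pre_map = {s.patient_id: s.sample_id for s in samples
               if s.time_point == TimePoint.PRE}
    X = pd.DataFrame(
        {pid: norm.values.loc[candidates, sid] for pid, sid in pre_map.items()}
    ).T.loc[cohort["patient_id"]]
    y = cohort["group"].to_numpy()

    candidate_rows = []
    best_rows = []
    index_def: dict = {}
    surv: dict = {}
    if candidates:
        search = exhaustive_search(
            X, y, candidates, min(config.max_panel_size, len(candidates))
        )
        for _, row in search.entries[search.entries["size"] == 1].iterrows():
            candidate_rows.append(
                {
                    "mirna": row["members"][0],
                    "direction": "up" if row["members"][0] in report.final_up
                    else "down",
                    "accuracy_pct": 100 * row["accuracy"],
                    "sensitivity_pct": 100 * row["sensitivity"],
                    "specificity_pct": 100 * row["specificity"],
                    "auc": row["auc"],
                }
            )
        bps = search.best_per_size()
        for _, row in bps.iterrows():
            best_rows.append(
                {
                    "members": list(row["members"]),
                    "size": int(row["size"]),
                    "accuracy_pct": 100 * row["accuracy"],
                    "sensitivity_pct": 100 * row["sensitivity"],
                    "specificity_pct": 100 * row["specificity"],
                    "auc": row["auc"],
                }
            )
        best = search.best()
        index_def = {
            "members": best.members,
            "coefficients": best.coefficients,
            "intercept": best.intercept,
            "cutoff": best.cutoff,
            "metrics": best.metrics,
        }

        scores = best.score(X[best.members].to_numpy(float))
        high = scores >= best.cutoff
        for endpoint in config.endpoints:
            t = cohort[f"{endpoint}_days"].to_numpy(float)
            e = cohort[f"{endpoint}_event"].to_numpy(bool)
            lr = logrank(t[high], e[high], t[~high], e[~high]) if (
                high.any() and (~high).any()
            ) else None
            covs = pd.DataFrame(
                {
                    "index_high": high.astype(float),
                    "age": cohort["age"].to_numpy(float),
                    "lymph_metastasis": cohort["lymph_metastasis"]
                    .astype(float).to_numpy(),
                    "cea": np.log1p(cohort["cea"].to_numpy(float)),
                    "ca19_9": np.log1p(cohort["ca19_9"].to_numpy(float)),
                },
                index=cohort["patient_id"],
            )
            uni = cox_fit(covs, t, e, mode="univariate")
            chosen = multivariate_select(uni, config.hr_threshold)
            multi = (
                cox_fit(covs[chosen], t, e, mode="multivariate")
                if chosen else None
            )
            km_high = km_fit(t[high], e[high]) if high.any() else None
            km_low = km_fit(t[~high], e[~high]) if (~high).any() else None
            surv[endpoint] = {
                "logrank_p": lr.p if lr else None,
                "univariate": uni.table.round(6).to_dict(orient="index"),
                "multivariate_covariates": chosen,
                "multivariate": multi.table.round(6).to_dict(orient="index")
                if multi is not None else None,
                "km_high": km_high.to_frame().to_dict(orient="list")
                if km_high else None,
                "km_low": km_low.to_frame().to_dict(orient="list")
                if km_low else None,
            }

    run = RunReport(
        funnel_counts=counts,
        candidate_table=pd.DataFrame(candidate_rows),
        best_combination_table=pd.DataFrame(best_rows),
        index_definition=index_def,
        survival_summary=surv,
        provenance={
            "seed": config.seed,
            "n_patients": int(len(cohort)),
            "n_samples": int(len(samples)),
            "planted_up": truth.planted_up_mirnas,
            "planted_down": truth.planted_down_mirnas,
            "package": "mirecur 0.1.0",
        },
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_panel(panel, out / "panel.tsv")
        mio.write_cohort(cohort, out / "cohort.csv")
        mio.write_samples(samples, out / "samples.csv")
        mio.write_signal_matrix(raw, out / "signals_raw.tsv")
        mio.write_signal_matrix(norm, out / "signals_normalized.tsv")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(run.to_dict(), fh, indent=2, default=_json_default)
        if index_def:
            from .types import DiscriminantModel

            mio.write_model(
                DiscriminantModel(**index_def), out / "best_index.json"
            )
    return run


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
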