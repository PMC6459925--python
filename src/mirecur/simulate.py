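"""Synthetic serum-miRNA cohorts with planted recurrence markers.

The generator emulates the design of a 22-patient post-surgical biliary
tract cancer cohort sampled at three time points (pre-operative,
postoperative, recurrence/last observation): a 2565-probe miRNA panel with
47 internal-control miRNAs and a block of negative-control probes, planted
"upregulated" markers (high pre-op in relapsers, dropping after surgery,
re-rising at recurrence) and mirror-image "downregulated" markers,
per-array multiplicative scale factors plus additive optical background so
the normalization chain has real work to do, and exponential, censored
recurrence-free and overall survival times.

Signals are built on a log2 scale and exponentiated; background is added
after exponentiation, which reproduces the multiplicative-signal-plus-
additive-background structure that background subtraction and quantile
normalization assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import (
    Group,
    ProbeClass,
    ProbePanel,
    SampleRecord,
    SignalMatrix,
    Stage,
    TimePoint,
    ValidationError,
)

__all__ = ["SimulationConfig", "GroundTruth", "build_panel",
           "generate_cohort", "generate_signals", "simulate"]


@dataclass
class SimulationConfig:
    """Cohort and signal-model parameters.

    Defaults mirror the study design the pipeline targets: 22 patients of
    whom 13 relapse, 66 arrays, a 2565-miRNA panel with 47 internal
    controls, four planted up-markers and two down-markers.  Effect sizes
    are in log2 units; ``marker_effect_log2`` is the pre-operative group
    difference and ``dynamics_amplitude_log2`` the post-operative drop /
    recurrence re-rise.  ``trajectory_concordance`` is the fraction of
    relapsers showing the canonical fall-then-rise pattern; non-relapsers
    re-elevate with the complementary probability.
    """

    n_patients: int = 22
    n_recurrence: int = 13
    n_target_probes: int = 2565
    n_internal_controls: int = 47
    n_negative_controls: int = 100
    n_up_markers: int = 4
    n_down_markers: int = 2
    marker_effect_log2: float = 1.5
    dynamics_amplitude_log2: float = 1.0
    trajectory_concordance: float = 0.9
    array_scale_sd: float = 0.3
    background_mean: float = 40.0
    background_sd: float = 8.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.4
    detect_drop_fraction: float = 0.54
    absent_background_factor: float = 0.85
    rfs_rate: float = 1.0 / 365.0
    post_recurrence_rate: float = 1.0 / 300.0
    followup_days: float = 1454.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_recurrence > self.n_patients:
            raise ValidationError("n_recurrence must not exceed n_patients")
        n_markers = self.n_up_markers + self.n_down_markers
        if n_markers > self.n_target_probes - self.n_internal_controls:
            raise ValidationError("more planted markers than free target probes")
        for name in ("array_scale_sd", "background_sd", "noise_log2_sd",
                     "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.trajectory_concordance <= 1.0:
            raise ValidationError("trajectory_concordance must lie in [0, 1]")
        if self.followup_days <= 0 or self.rfs_rate <= 0:
            raise ValidationError("followup_days and rfs_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery testing."""

    planted_up_mirnas: list[str]
    planted_down_mirnas: list[str]
    true_discriminant: dict[str, float] = field(default_factory=dict)
    array_scale_factors: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def build_panel(config: SimulationConfig) -> ProbePanel:
    """Probe panel matching the configured design.

    Internal controls are the last ``n_internal_controls`` of the
    ``n_target_probes`` miRNA probes; negative controls carry no miRNA name.
    """
    config.validate()
    n_free = config.n_target_probes - config.n_internal_controls
    rows = []
    for i in range(n_free):
        rows.append((f"probe_{i:04d}", ProbeClass.TARGET.value, f"miR-sim-{i:04d}"))
    for i in range(config.n_internal_controls):
        rows.append(
            (f"ic_{i:03d}", ProbeClass.INTERNAL_CONTROL.value, f"miR-ctrl-{i:03d}")
        )
    for i in range(config.n_negative_controls):
        rows.append((f"neg_{i:03d}", ProbeClass.NEGATIVE_CONTROL.value, ""))
    return ProbePanel(
        table=pd.DataFrame(rows, columns=["probe_id", "probe_class", "mirna_name"])
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[SampleRecord]]:
    """Draw the clinical table and the three-sample-per-patient sheet.

    Relapsers get RFS ~ Exponential(rfs_rate) resampled into (0, followup)
    with an observed event; non-relapsers are censored at follow-up with
    uniform jitter.  OS is RFS plus an independent exponential
    post-recurrence survival for relapsers (censoring carried over), which
    preserves rfs <= os.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    is_rec = np.zeros(n, dtype=bool)
    is_rec[: config.n_recurrence] = True

    rfs = np.empty(n)
    # truncated exponential via inverse CDF on (0, followup)
    u = rng.uniform(size=n)
    cap = 1.0 - np.exp(-config.rfs_rate * config.followup_days)
    rfs_rec = -np.log(1.0 - u * cap) / config.rfs_rate
    rfs_cens = config.followup_days * (0.85 + 0.15 * rng.uniform(size=n))
    rfs = np.where(is_rec, np.maximum(rfs_rec, 1.0), rfs_cens)

    post = rng.exponential(1.0 / config.post_recurrence_rate, size=n)
    os_days = np.where(is_rec, rfs + post, rfs)
    os_event = is_rec & (rng.uniform(size=n) < 0.7)

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "group": np.where(
                is_rec, Group.RECURRENCE.value, Group.NONRECURRENCE.value
            ),
            "rfs_days": rfs,
            "rfs_event": is_rec,
            "os_days": os_days,
            "os_event": os_event,
            "age": np.round(rng.normal(65.4, 10.0, size=n)).clip(31, 90),
            "sex": rng.choice(["male", "female"], size=n, p=[17 / 22, 5 / 22]),
            "disease_type": rng.choice(
                ["bile_duct", "gallbladder", "ampulla"],
                size=n,
                p=[15 / 22, 5 / 22, 2 / 22],
            ),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n,
                                p=[0.4, 0.5, 0.1, 0.0]),
            "differentiation": rng.choice(
                ["well", "moderate", "poor"], size=n, p=[0.3, 0.55, 0.15]
            ),
            "lymph_metastasis": rng.uniform(size=n) < (10 / 22),
            "cea": np.exp(rng.normal(1.0, 0.8, size=n)),
            "ca19_9": np.exp(rng.normal(3.0, 1.0, size=n)),
        }
    )

    samples: list[SampleRecord] = []
    for pid in cohort["patient_id"]:
        for tp in TimePoint:
            samples.append(
                SampleRecord(
                    sample_id=f"{pid}_{tp.value}", patient_id=pid, time_point=tp
                )
            )
    return cohort, samples


def generate_signals(
    cohort: pd.DataFrame,
    samples: list[SampleRecord],
    panel: ProbePanel,
    config: SimulationConfig,
) -> tuple[SignalMatrix, GroundTruth]:
    """Raw probe intensities with planted marker structure.

    Per-probe baseline log2 levels are Normal(baseline_log2_mean,
    baseline_log2_sd); internal controls sit one unit higher so they are
    always well detected and, by construction, carry no group or time
    effect.  A fraction of free target probes is pushed toward background so
    the detection filter has something to remove.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = [s.sample_id for s in samples]
    n_arrays = len(sample_ids)

    target_ids = panel.target_ids
    ic_ids = panel.internal_control_ids
    neg_ids = panel.negative_control_ids
    mirna_ids = target_ids + ic_ids

    up = target_ids[: config.n_up_markers]
    down = target_ids[config.n_up_markers:
                      config.n_up_markers + config.n_down_markers]

    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                      size=len(mirna_ids))
    base_s = pd.Series(base, index=mirna_ids)
    base_s[ic_ids] = config.baseline_log2_mean + 1.0
    # planted markers are stably detected serum miRNAs by definition, so
    # their baselines sit clear of the detection floor even after the
    # group/time effects pull them down
    base_s[up + down] = config.baseline_log2_mean + 1.0 + rng.normal(
        0.0, 0.5, size=len(up) + len(down)
    )
    # a fraction of non-marker targets is absent from serum: essentially no
    # specific signal, and slightly dimmer than the negative-control average
    # so the presence call rejects them in most arrays
    n_low = int(config.detect_drop_fraction * len(target_ids))
    low_pool = [t for t in target_ids if t not in set(up) | set(down)]
    low_ids = list(rng.choice(low_pool, size=min(n_low, len(low_pool)),
                              replace=False))
    base_s[low_ids] = -3.0

    rec_ids = set(
        cohort.loc[cohort["group"] == Group.RECURRENCE.value, "patient_id"]
    )
    concordant = {
        pid: bool(rng.uniform() < config.trajectory_concordance)
        for pid in cohort["patient_id"]
    }

    log2 = np.tile(base_s.to_numpy()[:, None], (1, n_arrays))
    log2 += rng.normal(0.0, config.noise_log2_sd,
                       size=(len(mirna_ids), n_arrays))
    idx = {p: i for i, p in enumerate(mirna_ids)}

    for j, rec in enumerate(samples):
        relapser = rec.patient_id in rec_ids
        for marker, sign in [(m, +1.0) for m in up] + [(m, -1.0) for m in down]:
            i = idx[marker]
            delta = 0.0
            if relapser:
                if rec.time_point == TimePoint.PRE:
                    delta = config.marker_effect_log2
                elif rec.time_point == TimePoint.POST:
                    delta = config.marker_effect_log2 - (
                        config.dynamics_amplitude_log2
                        if concordant[rec.patient_id] else 0.0
                    )
                elif rec.time_point == TimePoint.FINAL:
                    delta = config.marker_effect_log2 if concordant[
                        rec.patient_id] else (
                        config.marker_effect_log2
                        - config.dynamics_amplitude_log2)
            else:
                # surgery still removes the tumour signal transiently
                if rec.time_point == TimePoint.POST:
                    delta = -config.dynamics_amplitude_log2
                elif rec.time_point == TimePoint.FINAL:
                    # a minority of non-relapsers re-elevate
                    delta = 0.0 if not concordant[rec.patient_id] else (
                        -config.dynamics_amplitude_log2)
            log2[i, j] += sign * delta

    scale = np.exp(rng.normal(0.0, config.array_scale_sd, size=n_arrays))
    linear = scale[None, :] * np.exp2(log2)
    background = rng.normal(config.background_mean, config.background_sd,
                            size=(len(mirna_ids), n_arrays)).clip(min=0.0)
    low_rows = np.array([p in set(low_ids) for p in mirna_ids])
    background[low_rows] *= config.absent_background_factor
    linear = linear + background

    neg = rng.normal(config.background_mean, config.background_sd,
                     size=(len(neg_ids), n_arrays)).clip(min=0.0)

    values = pd.DataFrame(
        np.vstack([linear, neg]),
        index=mirna_ids + neg_ids,
        columns=sample_ids,
    ).loc[panel.ids()]
    detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    matrix = SignalMatrix(values=values, detected=detected, stage=Stage.RAW)

    w = {panel.name_of(m): 1.0 for m in up}
    w.update({panel.name_of(m): -1.0 for m in down})
    norm = float(np.sqrt(sum(v * v for v in w.values()))) or 1.0
    truth = GroundTruth(
        planted_up_mirnas=[panel.name_of(m) for m in up],
        planted_down_mirnas=[panel.name_of(m) for m in down],
        true_discriminant={k: v / norm for k, v in w.items()},
        array_scale_factors=dict(zip(sample_ids, scale.tolist())),
    )
    return matrix, truth


def simulate(
    config: SimulationConfig,
) -> tuple[ProbePanel, pd.DataFrame, list[SampleRecord], SignalMatrix, GroundTruth]:
    """One-call convenience wrapper: panel, cohort, samples, signals, truth."""
    panel = build_panel(config)
    cohort, samples = generate_cohort(config)
    matrix, truth = generate_signals(cohort, samples, panel, config)
    return panel, cohort, samples, matrix, truth
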