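"""Four-stage candidate-miRNA selection funnel.

Starting from every miRNA on the array, the funnel keeps:

1. miRNAs detected (value > 0) in at least a configurable fraction of
   pre-operative samples;
2. miRNAs whose paired pre/post difference is significant (two-sided paired
   t test), split into a *pre-high* pool (higher before surgery) and a
   *pre-low* pool (higher after surgery);
3. miRNAs whose pre-operative median split separates recurrence-free
   survival (two-group log-rank test);
4. miRNAs whose three-time-point trajectory matches the canonical
   recurrence pattern — for pre-high candidates a post-operative fall
   followed by a re-rise at the recurrence draw, concentrated in relapsers;
   pre-low candidates must show the mirror pattern.

Each stage's surviving set is a subset of the previous stage's, so the
report's counts form a monotone funnel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import logrank
from .types import Group, SignalMatrix, SampleRecord, TimePoint, ValidationError

__all__ = [
    "Direction",
    "FunnelConfig",
    "FunnelReport",
    "PairedTestResult",
    "LogrankSplitResult",
    "filter_detected",
    "paired_prepost_test",
    "median_split_logrank",
    "classify_trajectory",
    "run_funnel",
]


class Direction(str, enum.Enum):
    PRE_HIGH = "pre_high"
    PRE_LOW = "pre_low"


@dataclass
class FunnelConfig:
    detection_fraction: float = 0.5
    alpha_paired: float = 0.05
    alpha_logrank: float = 0.05
    trajectory_margin: float = 0.0
    trajectory_majority: float = 0.5
    use_bh: bool = False  # Benjamini-Hochberg on the paired-test p-values

    def validate(self) -> None:
        if not 0.0 < self.detection_fraction <= 1.0:
            raise ValidationError("detection_fraction must lie in (0, 1]")
        for a in (self.alpha_paired, self.alpha_logrank):
            if not 0.0 < a < 1.0:
                raise ValidationError("alphas must lie in (0, 1)")
        if not 0.0 < self.trajectory_majority <= 1.0:
            raise ValidationError("trajectory_majority must lie in (0, 1]")


@dataclass
class PairedTestResult:
    t: float
    p: float
    direction: Direction
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and np.isfinite(self.p)


@dataclass
class LogrankSplitResult:
    p: float
    high_group_worse: bool
    degenerate: bool = False


@dataclass
class FunnelReport:
    n_input: int
    detected_set: set[str]
    paired_significant_pre_high: set[str]
    paired_significant_pre_low: set[str]
    rfs_significant_pre_high: set[str]
    rfs_significant_pre_low: set[str]
    final_up: set[str]
    final_down: set[str]
    paired_p: dict[str, float] = field(default_factory=dict)
    logrank_p: dict[str, float] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "detected": len(self.detected_set),
            "paired_significant": len(self.paired_significant_pre_high)
            + len(self.paired_significant_pre_low),
            "pre_high": len(self.paired_significant_pre_high),
            "pre_low": len(self.paired_significant_pre_low),
            "rfs_significant_pre_high": len(self.rfs_significant_pre_high),
            "rfs_significant_pre_low": len(self.rfs_significant_pre_low),
            "final_up": len(self.final_up),
            "final_down": len(self.final_down),
            "final": len(self.final_up) + len(self.final_down),
        }

    def check_inclusions(self) -> None:
        paired = self.paired_significant_pre_high | self.paired_significant_pre_low
        if not paired <= self.detected_set:
            raise ValidationError("paired-significant set escapes detected set")
        if not self.rfs_significant_pre_high <= self.paired_significant_pre_high:
            raise ValidationError("RFS pre-high set escapes paired pre-high set")
        if not self.rfs_significant_pre_low <= self.paired_significant_pre_low:
            raise ValidationError("RFS pre-low set escapes paired pre-low set")
        if not self.final_up <= self.rfs_significant_pre_high:
            raise ValidationError("final up set escapes RFS pre-high set")
        if not self.final_down <= self.rfs_significant_pre_low:
            raise ValidationError("final down set escapes RFS pre-low set")


# ---------------------------------------------------------------------------
# helpers


def _samples_at(samples: list[SampleRecord], tp: TimePoint) -> dict[str, str]:
    """patient_id -> sample_id at the given time point."""
    return {
        s.patient_id: s.sample_id for s in samples if s.time_point == tp
    }


def _values_by_patient(
    matrix: SignalMatrix, samples: list[SampleRecord], tp: TimePoint
) -> pd.DataFrame:
    """Probe x patient value frame for one time point."""
    mapping = _samples_at(samples, tp)
    cols = {pid: matrix.values[sid] for pid, sid in mapping.items()
            if sid in matrix.values.columns}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# stage 1: detection


def filter_detected(
    matrix: SignalMatrix,
    samples: list[SampleRecord],
    config: FunnelConfig | None = None,
) -> set[str]:
    """miRNAs detected (value > 0) in >= detection_fraction of pre samples."""
    config = config or FunnelConfig()
    config.validate()
    pre = _samples_at(samples, TimePoint.PRE)
    pre_cols = [sid for sid in pre.values() if sid in matrix.values.columns]
    if not pre_cols:
        raise ValidationError("no pre-operative samples in matrix")
    ok = matrix.detected[pre_cols] & (matrix.values[pre_cols] > 0)
    frac = ok.mean(axis=1)
    return set(frac.index[frac >= config.detection_fraction])


# ---------------------------------------------------------------------------
# stage 2: paired pre/post test


def _paired_t_frame(
    matrix: SignalMatrix, samples: list[SampleRecord], probes: list[str]
) -> pd.DataFrame:
    """Vectorized two-sided paired t over (pre - post) differences.

    Returns a frame indexed by probe with columns t, p, mean_diff,
    degenerate.  Degenerate rows (zero-variance, nonzero-mean differences)
    carry p = NaN; identical pre/post vectors carry p = 1.
    """
    pre = _values_by_patient(matrix, samples, TimePoint.PRE)
    post = _values_by_patient(matrix, samples, TimePoint.POST)
    patients = sorted(set(pre.columns) & set(post.columns))
    if len(patients) < 2:
        raise ValidationError("paired test needs >= 2 patients with pre and post")
    d = (pre[patients] - post[patients]).loc[probes]
    n = len(patients)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0.0
    degenerate = zero_sd & (mean != 0.0)
    p = pd.Series(p, index=d.index)
    p[zero_sd & (mean == 0.0)] = 1.0
    p[degenerate] = np.nan
    t[zero_sd] = np.nan
    return pd.DataFrame(
        {"t": t, "p": p, "mean_diff": mean, "degenerate": degenerate}
    )


def paired_prepost_test(
    matrix: SignalMatrix, samples: list[SampleRecord], mirna: str
) -> PairedTestResult:
    """Two-sided paired t test of (pre - post) for one miRNA.

    The direction is the sign of the mean difference: ``PRE_HIGH`` when the
    pre-operative level exceeds the postoperative one.
    """
    row = _paired_t_frame(matrix, samples, [mirna]).iloc[0]
    direction = Direction.PRE_HIGH if row["mean_diff"] > 0 else Direction.PRE_LOW
    return PairedTestResult(
        t=float(row["t"]),
        p=float(row["p"]),
        direction=direction,
        degenerate=bool(row["degenerate"]),
    )


# ---------------------------------------------------------------------------
# stage 3: median-split log-rank on RFS


def median_split_logrank(
    pre_values: pd.Series, cohort: pd.DataFrame, mirna: str = ""
) -> LogrankSplitResult:
    """Two-group log-rank on RFS after splitting at the median pre value.

    Patients with value >= median form the high group (ties go high).  If
    all values are identical no split exists and the miRNA is excluded with
    a degenerate flag.
    """
    aligned = cohort.set_index("patient_id").loc[pre_values.index]
    med = float(pre_values.median())
    high = pre_values >= med
    if high.all() or (~high).all():
        return LogrankSplitResult(p=np.nan, high_group_worse=False,
                                  degenerate=True)
    t = aligned["rfs_days"].to_numpy(float)
    e = aligned["rfs_event"].to_numpy(bool)
    res = logrank(t[high.to_numpy()], e[high.to_numpy()],
                  t[~high.to_numpy()], e[~high.to_numpy()])
    worse = _km_lower(t[high.to_numpy()], e[high.to_numpy()],
                      t[~high.to_numpy()], e[~high.to_numpy()])
    return LogrankSplitResult(p=res.p, high_group_worse=worse)


def _km_lower(t_a, e_a, t_b, e_b) -> bool:
    """True when group A's KM curve is lower at the last event time."""
    from .survival import km_fit

    events = np.concatenate([t_a[np.asarray(e_a, bool)],
                             t_b[np.asarray(e_b, bool)]])
    if events.size == 0:
        return False
    t_last = events.max()
    sa = km_fit(t_a, e_a).survival_at(t_last)
    sb = km_fit(t_b, e_b).survival_at(t_last)
    return bool(sa < sb)


# ---------------------------------------------------------------------------
# stage 4: trajectory classification


def classify_trajectory(
    matrix: SignalMatrix,
    samples: list[SampleRecord],
    cohort: pd.DataFrame,
    mirna: str,
    direction: Direction,
    config: FunnelConfig | None = None,
) -> bool:
    """Does the three-time-point trajectory match the recurrence pattern?

    For a pre-high candidate, keep when (a) the relapser medians fall from
    pre to post and rise from post to the final draw (each by more than
    ``trajectory_margin``), (b) at least ``trajectory_majority`` of
    relapsers individually fall then rise, and (c) that fraction exceeds
    the corresponding fraction among non-relapsers.  Pre-low candidates use
    the mirror (rise-then-fall) pattern.
    """
    config = config or FunnelConfig()
    config.validate()
    pre = _values_by_patient(matrix, samples, TimePoint.PRE).loc[mirna]
    post = _values_by_patient(matrix, samples, TimePoint.POST).loc[mirna]
    final = _values_by_patient(matrix, samples, TimePoint.FINAL).loc[mirna]
    groups = cohort.set_index("patient_id")["group"]
    rel = [p for p in pre.index if groups.get(p) == Group.RECURRENCE.value]
    non = [p for p in pre.index if groups.get(p) == Group.NONRECURRENCE.value]
    if not rel:
        import warnings

        warnings.warn("no relapsers in cohort; trajectory classification skipped",
                      stacklevel=2)
        return False

    sign = 1.0 if direction == Direction.PRE_HIGH else -1.0
    m = config.trajectory_margin

    def canonical(pids) -> np.ndarray:
        fall = sign * (post[pids] - pre[pids]) < -m
        rise = sign * (final[pids] - post[pids]) > m
        return (fall & rise).to_numpy()

    med_fall = sign * (post[rel].median() - pre[rel].median()) < -m
    med_rise = sign * (final[rel].median() - post[rel].median()) > m
    if not (med_fall and med_rise):
        return False
    frac_rel = canonical(rel).mean()
    if frac_rel < config.trajectory_majority:
        return False
    frac_non = canonical(non).mean() if non else 0.0
    return bool(frac_rel > frac_non)


# ---------------------------------------------------------------------------
# the whole funnel


def run_funnel(
    matrix: SignalMatrix,
    samples: list[SampleRecord],
    cohort: pd.DataFrame,
    config: FunnelConfig | None = None,
) -> FunnelReport:
    """Execute all four stages and assemble the report.

    ``matrix`` is a normalized (typically log2) miRNA matrix whose rows are
    probe/miRNA identifiers; negative controls must already be gone.
    """
    config = config or FunnelConfig()
    config.validate()

    detected = filter_detected(matrix, samples, config)
    order = [p for p in matrix.probe_ids if p in detected]

    tf = _paired_t_frame(matrix, samples, order)
    pvals = tf["p"].copy()
    if config.use_bh:
        ok = pvals.notna()
        pvals[ok] = _bh_adjust(pvals[ok].to_numpy())
    sig = pvals < config.alpha_paired
    pre_high = set(tf.index[sig & (tf["mean_diff"] > 0)])
    pre_low = set(tf.index[sig & (tf["mean_diff"] < 0)])

    pre_frame = _values_by_patient(matrix, samples, TimePoint.PRE)
    rfs_high: set[str] = set()
    rfs_low: set[str] = set()
    logrank_p: dict[str, float] = {}
    for mirna in order:
        if mirna not in pre_high and mirna not in pre_low:
            continue
        res = median_split_logrank(pre_frame.loc[mirna], cohort, mirna)
        if res.degenerate:
            continue
        logrank_p[mirna] = res.p
        if res.p < config.alpha_logrank:
            (rfs_high if mirna in pre_high else rfs_low).add(mirna)

    final_up = {
        m for m in rfs_high
        if classify_trajectory(matrix, samples, cohort, m,
                               Direction.PRE_HIGH, config)
    }
    final_down = {
        m for m in rfs_low
        if classify_trajectory(matrix, samples, cohort, m,
                               Direction.PRE_LOW, config)
    }

    report = FunnelReport(
        n_input=len(matrix.probe_ids),
        detected_set=detected,
        paired_significant_pre_high=pre_high,
        paired_significant_pre_low=pre_low,
        rfs_significant_pre_high=rfs_high,
        rfs_significant_pre_low=rfs_low,
        final_up=final_up,
        final_down=final_down,
        paired_p={m: float(tf.loc[m, "p"]) for m in order},
        logrank_p=logrank_p,
    )
    report.check_inclusions()
    return report


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
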