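"""Array normalization chain for serum miRNA intensity matrices.

The chain runs strictly forward through four stages:

1. **Background correction / presence calls** — per array, the detection
   floor is the mean of the negative-control probes after trimming the top
   and bottom 5% (by intensity); a miRNA is *present* only when its signal
   is strictly greater than that floor, in which case the floor is
   subtracted.  Absent probes are set to 0 and flagged undetected.
2. **Quantile normalization** — all arrays are forced to share one value
   distribution (each rank replaced by the across-array mean at that rank;
   ties within an array receive the mean of the quantile values they span).
3. **Internal-control scaling** — each array is divided by the ratio of its
   internal-control mean to a preset target, so every array's
   internal-control mean lands exactly on the preset value.
4. **log2 transform** — log2(value + offset), the scale on which the
   discriminant index is fitted by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ProbeClass,
    ProbePanel,
    SignalMatrix,
    Stage,
    ValidationError,
)

__all__ = [
    "NormalizationParams",
    "negctrl_floor",
    "background_correct",
    "quantile_normalize",
    "internal_control_scale",
    "log2_transform",
    "normalize_chain",
]


@dataclass
class NormalizationParams:
    """Tunables of the chain.

    ``preset_value`` is the target internal-control mean; when ``None`` the
    batch is self-normalizing: the grand mean of per-array internal-control
    means is used.  ``negctrl_trim_fraction`` is per tail.
    """

    negctrl_trim_fraction: float = 0.05
    preset_value: float | None = None
    log2_offset: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.negctrl_trim_fraction < 0.5:
            raise ValidationError("negctrl_trim_fraction must lie in [0, 0.5)")
        if self.preset_value is not None and self.preset_value <= 0:
            raise ValidationError("preset_value must be positive")


def negctrl_floor(
    array_column: pd.Series,
    panel: ProbePanel,
    params: NormalizationParams | None = None,
) -> float:
    """Trimmed mean of the negative controls on one array.

    ``ceil(trim_fraction * n)`` probes are removed from each tail of the
    intensity ranking (ties broken by probe id order); if that would leave
    nothing, the plain mean is returned.
    """
    params = params or NormalizationParams()
    params.validate()
    neg_ids = panel.negative_control_ids
    if not neg_ids:
        raise ValidationError(
            "background correction requested but panel has no negative controls"
        )
    neg = array_column.loc[neg_ids]
    n = len(neg)
    k = math.ceil(params.negctrl_trim_fraction * n)
    if 2 * k >= n:
        return float(neg.mean())
    order = np.lexsort((np.arange(n), neg.to_numpy()))
    kept = neg.to_numpy()[order][k: n - k]
    return float(kept.mean())


def background_correct(
    matrix: SignalMatrix,
    panel: ProbePanel,
    params: NormalizationParams | None = None,
) -> SignalMatrix:
    """Presence calls and background subtraction; drops negative controls.

    Per array: a miRNA probe strictly above the trimmed negative-control
    mean is detected and replaced by (value − floor); everything else is set
    to 0 and flagged undetected.  A probe at exactly the floor is absent.
    """
    params = params or NormalizationParams()
    matrix.require_stage(Stage.RAW)
    mirna_ids = [p for p in matrix.probe_ids if p in set(panel.mirna_ids)]
    vals = matrix.values.loc[mirna_ids]
    floors = np.array(
        [negctrl_floor(matrix.values[c], panel, params) for c in vals.columns]
    )
    detected = vals.gt(floors, axis=1) & matrix.detected.loc[mirna_ids]
    corrected = (vals.sub(floors, axis=1)).where(detected, 0.0)
    return matrix.advance(corrected, detected, Stage.BACKGROUND_CORRECTED)


def quantile_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Force all arrays onto the common mean-of-sorted-values distribution.

    Ties within an array receive the mean of the quantile values their rank
    range spans; the detection mask is untouched.  A single-array matrix is
    passed through with a warning (undetected zeros included, so every
    array contributes an equal-length vector).
    """
    matrix.require_stage(Stage.BACKGROUND_CORRECTED)
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 arrays",
                      stacklevel=2)
        return matrix.advance(values.copy(), matrix.detected.copy(),
                              Stage.QUANTILE_NORMALIZED)
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = _assign_quantiles(arr[:, j], ref)
    frame = pd.DataFrame(out, index=values.index, columns=values.columns)
    return matrix.advance(frame, matrix.detected.copy(),
                          Stage.QUANTILE_NORMALIZED)


def _assign_quantiles(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    ranked = col[order]
    out_sorted = ref.copy()
    # average the reference values across each tied run
    i = 0
    n = len(ranked)
    while i < n:
        j = i + 1
        while j < n and ranked[j] == ranked[i]:
            j += 1
        if j - i > 1:
            out_sorted[i:j] = ref[i:j].mean()
        i = j
    out = np.empty_like(col)
    out[order] = out_sorted
    return out


def internal_control_scale(
    matrix: SignalMatrix,
    panel: ProbePanel,
    params: NormalizationParams | None = None,
) -> SignalMatrix:
    """Divide each array by (its internal-control mean / preset value).

    After scaling, every array's internal-control mean equals the preset
    value to within 1e-9 relative.  With ``preset_value=None`` the preset is
    the grand mean of per-array internal-control means, which leaves the
    batch's overall level unchanged.
    """
    params = params or NormalizationParams()
    params.validate()
    matrix.require_stage(Stage.QUANTILE_NORMALIZED)
    ic_ids = [p for p in panel.internal_control_ids if p in matrix.values.index]
    if len(ic_ids) < len(panel.internal_control_ids):
        missing = set(panel.internal_control_ids) - set(ic_ids)
        raise ValidationError(
            f"internal-control probes missing from matrix: {sorted(missing)[:5]}"
        )
    ic_means = matrix.values.loc[ic_ids].mean(axis=0)
    bad = ic_means[ic_means <= 0]
    if not bad.empty:
        raise ValidationError(
            f"non-positive internal-control mean on array(s): "
            f"{list(bad.index[:5])}"
        )
    preset = params.preset_value
    if preset is None:
        preset = float(ic_means.mean())
    scaled = matrix.values.div(ic_means / preset, axis=1)
    return matrix.advance(scaled, matrix.detected.copy(), Stage.CONTROL_SCALED)


def log2_transform(
    matrix: SignalMatrix, params: NormalizationParams | None = None
) -> SignalMatrix:
    """Monotone log2(value + offset); detection mask unchanged."""
    params = params or NormalizationParams()
    matrix.require_stage(Stage.CONTROL_SCALED)
    out = np.log2(matrix.values + params.log2_offset)
    return matrix.advance(out, matrix.detected.copy(), Stage.LOG2)


def normalize_chain(
    matrix: SignalMatrix,
    panel: ProbePanel,
    params: NormalizationParams | None = None,
    log2: bool = True,
) -> SignalMatrix:
    """Run the full chain: background -> quantile -> control scale [-> log2]."""
    params = params or NormalizationParams()
    out = background_correct(matrix, panel, params)
    out = quantile_normalize(out)
    out = internal_control_scale(out, panel, params)
    if log2:
        out = log2_transform(out, params)
    return out
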