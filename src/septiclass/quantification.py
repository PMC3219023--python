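"""Relative quantification of real-time amplification curves.

Converts raw fluorescence-vs-cycle traces into efficiency-corrected
relative fold changes per marker per sample:

1. take-off (Cq-like) cycle estimation as the point of peak cycling
   acceleration — the maximum of the discrete second difference of the
   trace, refined by quadratic interpolation;
2. the Pfaffl-style efficiency-corrected ratio
   E_target^dCt(target) / E_reference^dCt(reference), with
   dCt = (reference take-off − sample take-off) so that higher expression
   gives a fold change > 1;
3. geometric-mean combination of multiple normalization markers;
4. plate QC against negative (no-template) and positive control wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic import AmplificationCurve, PanelSpec, WellRole

__all__ = [
    "NOT_DETECTED",
    "QuantResult",
    "PlateQC",
    "PlateQCError",
    "SampleUnquantifiableError",
    "takeoff_cycle",
    "pfaffl_fold_change",
    "combine_normalizers",
    "plate_qc",
    "quantify_sample",
]

#: Sentinel for a well whose trace never departs baseline.
NOT_DETECTED = None

# Peak second difference must exceed this multiple of the baseline noise
# level (median absolute second difference over the first baseline cycles)
# for a take-off to be called.
_DETECTION_MULTIPLE = 5.0
_BASELINE_CYCLES = 10


class PlateQCError(RuntimeError):
    """Raised when quantification is attempted on a plate that failed QC."""


class SampleUnquantifiableError(RuntimeError):
    """Raised when a sample cannot be normalized (reference marker undetected)."""


@dataclass(frozen=True)
class QuantResult:
    """Efficiency-corrected relative quantification for one marker/sample."""

    marker_id: str
    sample_id: str
    takeoff_cycle: float
    delta_ct: float
    efficiency: float
    fold_change: float
    log2_fold_change: float


@dataclass(frozen=True)
class PlateQC:
    """Outcome of control-well checks for one plate."""

    n_negative_expected: int = 5
    n_positive_expected: int = 5
    n_negative_found: int = 0
    n_positive_found: int = 0
    negative_pass: bool = False
    positive_pass: bool = False
    reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return self.negative_pass and self.positive_pass


def _validate_efficiency(e: float, name: str = "efficiency") -> float:
    if not (1.0 < e <= 2.0):
        raise ValueError(f"{name} must lie in (1, 2] (got {e!r})")
    return float(e)


def takeoff_cycle(curve: AmplificationCurve, smoothing_window: int = 1) -> float | None:
    """Estimate the take-off cycle as the peak of cycling acceleration.

    Computes the discrete second difference of the (optionally
    moving-average smoothed) fluorescence series, locates its maximum, and
    refines the position by quadratic interpolation through the peak and
    its two neighbours.  Returns :data:`NOT_DETECTED` when the peak does
    not rise clearly above the baseline noise level, as is the case for
    no-template control wells.
    """
    cycles = curve.cycles
    fluo = curve.fluorescence
    if cycles.size < 10:
        raise ValueError("take-off estimation requires at least 10 cycles")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        # same-length smoothing with edge replication to avoid boundary bias
        padded = np.pad(fluo, (smoothing_window // 2, smoothing_window - 1 - smoothing_window // 2), mode="edge")
        fluo = np.convolve(padded, kernel, mode="valid")

    d2 = fluo[2:] - 2.0 * fluo[1:-1] + fluo[:-2]  # positioned at cycles[1:-1]
    peak = int(np.argmax(d2))
    peak_value = d2[peak]

    n_base = min(_BASELINE_CYCLES, d2.size)
    baseline_level = float(np.median(np.abs(d2[:n_base])))
    threshold = _DETECTION_MULTIPLE * baseline_level
    if peak_value <= threshold or peak_value <= 0.0:
        return NOT_DETECTED

    position = cycles[peak + 1]
    if 0 < peak < d2.size - 1:
        left, mid, right = d2[peak - 1], d2[peak], d2[peak + 1]
        denom = left - 2.0 * mid + right
        if denom != 0.0:
            offset = 0.5 * (left - right) / denom
            offset = float(np.clip(offset, -0.5, 0.5))
            step = cycles[peak + 2] - cycles[peak + 1]
            position = position + offset * step
    return float(position)


def pfaffl_fold_change(
    dct_target: float,
    dct_norm: float,
    e_target: float = 2.0,
    e_norm: float = 2.0,
) -> float:
    """Efficiency-corrected relative fold change.

    ratio = E_target^dCt(target) / E_norm^dCt(norm), with dCt oriented as
    (reference take-off − sample take-off).  With both efficiencies at 2
    this reduces exactly to the familiar 2^(−ddCt) expression.
    """
    e_target = _validate_efficiency(e_target, "e_target")
    e_norm = _validate_efficiency(e_norm, "e_norm")
    return float(e_target**dct_target / e_norm**dct_norm)


def combine_normalizers(normalizer_fold_changes: list[float]) -> float:
    """Geometric mean of per-reference-marker ratios.

    The geometric mean is the accepted convention for combining multiple
    reference genes; it is invariant to the order of the inputs.
    """
    values = np.asarray(list(normalizer_fold_changes), dtype=float)
    if values.size == 0:
        raise ValueError("at least one normalizer value is required")
    if np.any(values <= 0):
        raise ValueError("normalizer fold changes must be positive")
    return float(np.exp(np.mean(np.log(values))))


def plate_qc(
    curves: list[AmplificationCurve],
    n_negative_expected: int = 5,
    n_positive_expected: int = 5,
    smoothing_window: int = 1,
) -> PlateQC:
    """Check control wells: negatives must stay flat, positives must amplify.

    Count mismatches and failing wells are reported as reasons on the
    returned object rather than raised, so a failing plate can be logged
    and skipped.
    """
    negatives = [c for c in curves if c.role is WellRole.NEGATIVE_CONTROL]
    positives = [c for c in curves if c.role is WellRole.POSITIVE_CONTROL]
    reasons: list[str] = []

    negative_pass = True
    if len(negatives) != n_negative_expected:
        negative_pass = False
        reasons.append(
            f"expected {n_negative_expected} negative controls, found {len(negatives)}"
        )
    for c in negatives:
        if takeoff_cycle(c, smoothing_window) is not NOT_DETECTED:
            negative_pass = False
            reasons.append(f"negative control {c.well_id} amplified (contamination)")

    positive_pass = True
    if len(positives) != n_positive_expected:
        positive_pass = False
        reasons.append(
            f"expected {n_positive_expected} positive controls, found {len(positives)}"
        )
    for c in positives:
        if takeoff_cycle(c, smoothing_window) is NOT_DETECTED:
            positive_pass = False
            reasons.append(f"positive control {c.well_id} failed to amplify")

    return PlateQC(
        n_negative_expected=n_negative_expected,
        n_positive_expected=n_positive_expected,
        n_negative_found=len(negatives),
        n_positive_found=len(positives),
        negative_pass=negative_pass,
        positive_pass=positive_pass,
        reasons=tuple(reasons),
    )


def quantify_sample(
    curves: list[AmplificationCurve],
    reference_takeoffs: dict[str, float],
    panel: PanelSpec,
    sample_id: str,
    efficiencies: dict[str, float] | float = 2.0,
    qc: PlateQC | None = None,
    smoothing_window: int = 1,
) -> list[QuantResult]:
    """Quantify every diagnostic marker of one sample against a reference.

    ``curves`` holds this sample's target and normalizer wells;
    ``reference_takeoffs`` gives the calibrator's take-off cycle per marker
    (diagnostic and normalization markers alike).  Per-marker dCt is
    (reference − sample); each marker's efficiency-corrected ratio is
    divided by the geometric mean of the three reference-marker ratios.

    Raises :class:`PlateQCError` if ``qc`` is given and failed, and
    :class:`SampleUnquantifiableError` if any normalization marker is
    undetected in the sample.
    """
    if qc is not None and not qc.passed:
        raise PlateQCError(
            "plate failed QC: " + "; ".join(qc.reasons or ("unknown reason",))
        )

    def eff(marker: str) -> float:
        if isinstance(efficiencies, dict):
            return _validate_efficiency(efficiencies.get(marker, 2.0))
        return _validate_efficiency(float(efficiencies))

    by_marker = {c.marker_id: c for c in curves if c.role in (WellRole.TARGET, WellRole.NORMALIZER)}

    norm_ratios: list[float] = []
    for norm in panel.normalizer_ids:
        if norm not in by_marker:
            raise SampleUnquantifiableError(f"normalizer {norm} has no well for sample {sample_id}")
        if norm not in reference_takeoffs:
            raise SampleUnquantifiableError(f"normalizer {norm} has no reference take-off")
        ct = takeoff_cycle(by_marker[norm], smoothing_window)
        if ct is NOT_DETECTED:
            raise SampleUnquantifiableError(
                f"normalizer {norm} not detected in sample {sample_id}; sample unquantifiable"
            )
        dct = reference_takeoffs[norm] - ct
        norm_ratios.append(eff(norm) ** dct)
    norm_factor = combine_normalizers(norm_ratios)

    results: list[QuantResult] = []
    for marker in panel.marker_ids:
        curve = by_marker.get(marker)
        if curve is None:
            continue
        ct = takeoff_cycle(curve, smoothing_window)
        if ct is NOT_DETECTED:
            continue
        e = eff(marker)
        dct = reference_takeoffs[marker] - ct
        fold = (e**dct) / norm_factor
        results.append(
            QuantResult(
                marker_id=marker,
                sample_id=sample_id,
                takeoff_cycle=ct,
                delta_ct=dct,
                efficiency=e,
                fold_change=fold,
                log2_fold_change=math.log2(fold),
            )
        )
    return results
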