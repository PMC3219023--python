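"""Synthetic three-cohort study generator.

Emulates the statistical structure of a sepsis biomarker study: a healthy
control (HC) cohort, a post-surgical (PS) cohort with sterile systemic
inflammation, and a blood-culture-positive sepsis cohort, profiled on a
panel of 42 anonymous diagnostic markers plus 3 normalization markers.
Expression is generated on the log2 relative-fold-change scale with
cohort-dependent mean shifts, and raw amplification curves are generated
as four-parameter logistics so that take-off estimation has an exact
closed-form oracle.

The defaults encode the study conditions downstream stages are validated
against: 20 HC + 38 PS + 27 sepsis samples, signal spread over 20 of the
42 markers (so small sub-panels remain informative), per-marker shifts of
0.75 log2 units for sepsis-vs-PS and 1.5 for inflamed-vs-healthy, and
unit log2 noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "WellRole",
    "CohortDesign",
    "PanelSpec",
    "EffectModel",
    "CurveModel",
    "WellSpec",
    "AmplificationCurve",
    "LOGISTIC_TAKEOFF_OFFSET",
    "generate_cohort_design",
    "simulate_expression",
    "simulate_amplification_curves",
]


class Cohort(str, Enum):
    """Clinical cohort labels. MI (mixed inflammation) = PS ∪ SEPSIS."""

    HC = "HC"
    PS = "PS"
    SEPSIS = "SEPSIS"


class WellRole(str, Enum):
    TARGET = "TARGET"
    NORMALIZER = "NORMALIZER"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"
    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"


# Distance (in units of 1/k cycles) between the logistic midpoint c0 and the
# maximum of the second derivative of b + F_max / (1 + exp(-k (c - c0))):
# the maximum sits at c0 - ln(2 + sqrt(3)) / k.
LOGISTIC_TAKEOFF_OFFSET = math.log(2.0 + math.sqrt(3.0))


@dataclass(frozen=True)
class CohortDesign:
    """Per-sample identifiers and cohort labels."""

    sample_ids: tuple[str, ...]
    cohorts: tuple[Cohort, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.cohorts):
            raise ValueError("sample_ids and cohorts must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_id values must be unique")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def labels(self) -> np.ndarray:
        return np.array([c.value for c in self.cohorts])

    def mi_mask(self) -> np.ndarray:
        """Boolean mask of the mixed-inflammation group (PS ∪ SEPSIS)."""
        return np.array([c in (Cohort.PS, Cohort.SEPSIS) for c in self.cohorts])

    def cohort_mask(self, cohort: Cohort | str) -> np.ndarray:
        cohort = Cohort(cohort)
        return np.array([c is cohort for c in self.cohorts])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "cohort": [c.value for c in self.cohorts]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortDesign":
        return cls(
            sample_ids=tuple(str(s) for s in frame["sample_id"]),
            cohorts=tuple(Cohort(c) for c in frame["cohort"]),
        )


@dataclass(frozen=True)
class PanelSpec:
    """Diagnostic marker panel plus normalization (reference) markers."""

    marker_ids: tuple[str, ...]
    normalizer_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.marker_ids) < 1:
            raise ValueError("panel requires at least one diagnostic marker")
        if set(self.marker_ids) & set(self.normalizer_ids):
            raise ValueError("normalizer_ids must be disjoint from marker_ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def default(cls, n_markers: int = 42, n_normalizers: int = 3) -> "PanelSpec":
        """Anonymous 42-marker panel (M01..M42) with 3 reference markers."""
        width = max(2, len(str(n_markers)))
        return cls(
            marker_ids=tuple(f"M{i:0{width}d}" for i in range(1, n_markers + 1)),
            normalizer_ids=tuple(f"NORM{i}" for i in range(1, n_normalizers + 1)),
        )


@dataclass(frozen=True)
class EffectModel:
    """Per-marker, per-cohort mean log2 fold change and per-marker noise SD.

    ``mu`` maps marker id -> {cohort value -> mean}; ``sigma`` maps marker
    id -> SD.  With all means equal across cohorts the generated data carry
    no class signal.
    """

    mu: dict[str, dict[str, float]]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        for marker, sd in self.sigma.items():
            if not sd > 0:
                raise ValueError(f"sigma must be > 0 for every marker (got {sd!r} for {marker})")

    @classmethod
    def default(
        cls,
        panel: PanelSpec,
        n_informative: int = 20,
        sepsis_vs_ps: float = 0.75,
        mi_vs_hc: float = 1.5,
        sigma: float = 1.0,
    ) -> "EffectModel":
        """Place signal on the first ``n_informative`` markers.

        HC mean 0 everywhere; on informative markers PS mean is ``mi_vs_hc``
        and SEPSIS mean is ``mi_vs_hc + sepsis_vs_ps``.  Defaults spread the
        signal over 20 of 42 markers so that small random sub-panels retain
        most of the discriminative power.
        """
        informative = set(panel.marker_ids[:n_informative])
        mu: dict[str, dict[str, float]] = {}
        for m in panel.marker_ids:
            if m in informative:
                mu[m] = {
                    Cohort.HC.value: 0.0,
                    Cohort.PS.value: mi_vs_hc,
                    Cohort.SEPSIS.value: mi_vs_hc + sepsis_vs_ps,
                }
            else:
                mu[m] = {c.value: 0.0 for c in Cohort}
        return cls(mu=mu, sigma={m: float(sigma) for m in panel.marker_ids})

    @classmethod
    def null(cls, panel: PanelSpec, sigma: float = 1.0) -> "EffectModel":
        """No cohort effect on any marker."""
        return cls.default(panel, n_informative=0, sigma=sigma)


@dataclass(frozen=True)
class CurveModel:
    """Four-parameter logistic model for a real-time amplification trace.

    Noiseless trace: f(c) = baseline + f_max / (1 + exp(-slope (c - c0))).
    The midpoint c0 is positioned per well so that the analytic maximum of
    the second derivative sits at the requested take-off cycle.  Efficiency
    is the per-cycle amplification factor used by downstream quantification
    (2.0 = perfect doubling).
    """

    f_max: float = 100.0
    slope: float = 0.6
    baseline: float = 2.0
    noise_sd: float = 0.0
    n_cycles: int = 40
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.n_cycles < 10:
            raise ValueError("n_cycles must be >= 10")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")


@dataclass(frozen=True)
class WellSpec:
    """One plate well: which marker, which sample, and its true take-off."""

    well_id: str
    marker_id: str
    role: WellRole
    takeoff: float | None = None
    sample_id: str | None = None


@dataclass(frozen=True)
class AmplificationCurve:
    """Fluorescence-vs-cycle series for one well, with plate-role annotation."""

    well_id: str
    marker_id: str
    role: WellRole
    cycles: np.ndarray
    fluorescence: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if cycles.shape != fluo.shape:
            raise ValueError("cycles and fluorescence must have equal length")
        if cycles.size >= 2 and not np.all(np.diff(cycles) > 0):
            raise ValueError("cycles must be strictly increasing")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)


def generate_cohort_design(n_hc: int, n_ps: int, n_sepsis: int) -> CohortDesign:
    """Build a cohort design with deterministic HC, PS, SEPSIS ordering.

    The study emulated by the defaults enrolled 20 HC, 38 PS and 27 sepsis
    participants (85 in total).
    """
    for name, n in (("n_hc", n_hc), ("n_ps", n_ps), ("n_sepsis", n_sepsis)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0 (got {n})")
    sample_ids: list[str] = []
    cohorts: list[Cohort] = []
    for cohort, n in ((Cohort.HC, n_hc), (Cohort.PS, n_ps), (Cohort.SEPSIS, n_sepsis)):
        for i in range(1, n + 1):
            sample_ids.append(f"{cohort.value}{i:03d}")
            cohorts.append(cohort)
    return CohortDesign(sample_ids=tuple(sample_ids), cohorts=tuple(cohorts))


def simulate_expression(
    design: CohortDesign,
    panel: PanelSpec,
    effects: EffectModel,
    seed: int,
) -> pd.DataFrame:
    """Draw a samples × markers matrix of log2 relative fold changes.

    Entries are independent Normal(mu(marker, cohort), sigma(marker)).  The
    same seed reproduces the matrix bit-for-bit.
    """
    for m in panel.marker_ids:
        if m not in effects.mu or m not in effects.sigma:
            raise ValueError(f"effect model missing entry for marker {m!r}")
        for c in Cohort:
            if c.value not in effects.mu[m]:
                raise ValueError(f"effect model missing entry for ({m!r}, {c.value})")
    rng = np.random.default_rng(seed)
    mu = np.array(
        [[effects.mu[m][c.value] for m in panel.marker_ids] for c in design.cohorts]
    )
    sigma = np.array([effects.sigma[m] for m in panel.marker_ids])
    values = rng.normal(loc=mu, scale=sigma[None, :], size=(len(design), panel.n_markers))
    return pd.DataFrame(values, index=list(design.sample_ids), columns=list(panel.marker_ids))


def simulate_amplification_curves(
    wells: list[WellSpec],
    model: CurveModel,
    seed: int,
) -> list[AmplificationCurve]:
    """Generate logistic amplification traces for a set of plate wells.

    Each well's noiseless trace is baseline + f_max / (1 + exp(-k (c - c0)))
    with c0 = takeoff + ln(2 + sqrt(3)) / k so that the analytic maximum of
    the second derivative falls at the requested take-off cycle.
    Negative-control wells amplify nothing (f_max = 0); Gaussian noise with
    SD ``model.noise_sd`` is added to every trace.
    """
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, model.n_cycles + 1, dtype=float)
    curves: list[AmplificationCurve] = []
    for well in wells:
        if well.role is WellRole.NEGATIVE_CONTROL:
            trace = np.full_like(cycles, model.baseline)
        else:
            if well.takeoff is None:
                raise ValueError(f"well {well.well_id!r} requires a true take-off cycle")
            c0 = well.takeoff + LOGISTIC_TAKEOFF_OFFSET / model.slope
            trace = model.baseline + model.f_max / (
                1.0 + np.exp(-model.slope * (cycles - c0))
            )
        if model.noise_sd > 0:
            trace = trace + rng.normal(0.0, model.noise_sd, size=cycles.shape)
        curves.append(
            AmplificationCurve(
                well_id=well.well_id,
                marker_id=well.marker_id,
                role=well.role,
                cycles=cycles.copy(),
                fluorescence=trace,
                sample_id=well.sample_id,
            )
        )
    return curves
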