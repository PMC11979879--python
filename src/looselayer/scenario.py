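"""Ground-truth scenario and flow-schedule definitions for the generators.

A :class:`SyntheticScenario` bundles every parameter the synthetic-data module
needs: two-compartment Langmuir adsorption kinetics for the sensor surface,
acoustic sensitivities, drift/noise scales, the true diffusion interaction
parameter for DLS series, impurity optics, and viscosity/opalescence models.
A :class:`FlowSchedule` is the ordered list of pump segments (baseline /
sample / rinse) a QCM-D run executes.

The two-compartment surface model: an irreversible base layer with coverage
Gamma1 (capacity ``gmax1``, rate ``ka1``, no desorption) and a loosely
interacting layer Gamma2 that forms on top of the occupied base layer
(capacity ``gmax2``, adsorption ``ka2`` gated by Gamma1/gmax1, desorption
``kd2``).  The loose layer washes off during rinse; the base layer does not.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

PHASE_LABELS = ("baseline", "sample", "rinse")


@dataclass(frozen=True)
class FlowSegment:
    """One pump segment of a QCM-D run."""

    label: str
    buffer: str
    concentration_mg_ml: float
    duration_s: float
    flow_rate_ul_min: float = 10.0

    def validate(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValidationError(f"unknown segment label {self.label!r}")
        if not self.duration_s > 0:
            raise ValidationError("segment duration must be positive")
        if self.label == "sample" and not self.concentration_mg_ml > 0:
            raise ValidationError("sample segment requires concentration > 0")
        if self.label in ("rinse", "baseline") and self.concentration_mg_ml != 0:
            raise ValidationError(f"{self.label} segment must have zero concentration")


@dataclass(frozen=True)
class FlowSchedule:
    """Ordered exposure/wash segments; the first must be a baseline."""

    segments: tuple[FlowSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("schedule has no segments")
        for seg in self.segments:
            seg.validate()
        if self.segments[0].label != "baseline":
            raise ValidationError("first segment must be a baseline")

    @property
    def duration_s(self) -> float:
        return float(sum(seg.duration_s for seg in self.segments))

    def boundaries(self) -> list[float]:
        """Cumulative segment start times, excluding t=0, including the end."""
        out, t = [], 0.0
        for seg in self.segments:
            t += seg.duration_s
            out.append(t)
        return out

    def segment_at(self, t: float) -> FlowSegment:
        acc = 0.0
        for seg in self.segments:
            acc += seg.duration_s
            if t < acc:
                return seg
        return self.segments[-1]

    def to_records(self) -> list[dict]:
        return [dataclasses.asdict(seg) for seg in self.segments]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "FlowSchedule":
        return cls(tuple(FlowSegment(**dict(r)) for r in records))


def three_phase_schedule(
    concentration_mg_ml: float = 10.0,
    buffer: str = "histidine",
    baseline_s: float = 900.0,
    sample_s: float = 1200.0,
    rinse_s: float = 2400.0,
    flow_rate_ul_min: float = 10.0,
) -> FlowSchedule:
    """The canonical baseline -> sample -> rinse adsorption run."""
    return FlowSchedule(
        (
            FlowSegment("baseline", buffer, 0.0, baseline_s, flow_rate_ul_min),
            FlowSegment("sample", buffer, concentration_mg_ml, sample_s, flow_rate_ul_min),
            FlowSegment("rinse", buffer, 0.0, rinse_s, flow_rate_ul_min),
        )
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """All ground-truth parameters of a synthetic experiment.

    Defaults describe a moderately well-behaved mAb (trastuzumab-like layer
    and kD) measured on a 5 MHz crystal.
    """

    # surface kinetics (mL mg^-1 s^-1, ng cm^-2, s^-1)
    ka1: float = 0.002
    gmax1: float = 450.0
    ka2: float = 0.005
    kd2: float = 0.01
    gmax2: float = 507.6
    # acoustics: dissipation per areal mass (1e-6 per ng cm^-2); Sauerbrey
    # sensitivity (ng cm^-2 Hz^-1, 17.7 for a 5 MHz crystal)
    alpha1: float = 0.001
    alpha2: float = 0.008
    c_sauerbrey: float = 17.7
    # trace imperfections
    drift_rate_hz_h: float = 0.0
    noise_sd_f: float = 0.15
    noise_sd_d: float = 0.05
    buffer_offsets: Mapping[str, float] = field(default_factory=dict)
    loose_capacity_by_buffer: Mapping[str, float] | None = None
    # DLS ground truth
    d0_ref: float = 4.0e-7
    ref_temp_c: float = 20.0
    kd_true: float = 51.7
    rh_nm: float = 5.0
    dls_noise_frac: float = 0.01
    # impurity (bead) model
    impurity_intensity_fraction: float = 0.0
    d_impurity: float | None = None
    impurity_noise_inflation: float = 5.0
    # solution behavior
    eta0_cp: float = 1.0
    b_visc: float = 0.045
    od_per_mg_ml: float = 0.002
    od_noise_sd: float = 0.005
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = {
            "ka1": self.ka1, "gmax1": self.gmax1, "ka2": self.ka2,
            "kd2": self.kd2, "gmax2": self.gmax2, "noise_sd_f": self.noise_sd_f,
            "noise_sd_d": self.noise_sd_d, "dls_noise_frac": self.dls_noise_frac,
        }
        for name, value in nonneg.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {value}")
        if not self.alpha2 > self.alpha1:
            raise ValidationError("alpha2 must exceed alpha1 (loose layer is softer)")
        if not 0.0 <= self.impurity_intensity_fraction < 1.0:
            raise ValidationError("impurity_intensity_fraction must lie in [0, 1)")
        if self.c_sauerbrey <= 0:
            raise ValidationError("c_sauerbrey must be positive")
        if self.eta0_cp <= 0:
            raise ValidationError("eta0_cp must be positive")

    def replace(self, **changes) -> "SyntheticScenario":
        return dataclasses.replace(self, **changes)

    def effective_gmax2(self, buffer: str) -> float:
        if self.loose_capacity_by_buffer and buffer in self.loose_capacity_by_buffer:
            return float(self.loose_capacity_by_buffer[buffer])
        return self.gmax2

    def loose_equilibrium(self, concentration_mg_ml: float, buffer: str = "") -> float:
        """Analytic steady-state loose coverage Gamma2 (ng cm^-2) at constant c."""
        rate = self.ka2 * concentration_mg_ml
        if rate + self.kd2 == 0:
            return 0.0
        return self.effective_gmax2(buffer) * rate / (rate + self.kd2)

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["buffer_offsets"] = dict(self.buffer_offsets)
        if self.loose_capacity_by_buffer is not None:
            d["loose_capacity_by_buffer"] = dict(self.loose_capacity_by_buffer)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticScenario":
        return cls(**dict(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
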