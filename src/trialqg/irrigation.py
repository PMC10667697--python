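"""Irrigation-depth design utilities for deficit-irrigation trials.

Net irrigation depth is the soil-water deficit summed over root-zone
layers, d_n = Σ_i (θ_FC,i − θ_i) Δz_i, where θ_FC and θ are volumetric
water contents (cm³ cm⁻³) at field capacity and at measurement, and Δz
is the layer thickness (m).  Gross depth divides by the application
efficiency (default 0.9, i.e. 10% conveyance loss); deficit treatments
apply a fraction of the gross depth (0.5 for the drought regime, 1.0
for the well-watered control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError


@dataclass(frozen=True)
class SoilLayer:
    """One root-zone soil layer.

    theta_fc and theta are volumetric water contents (cm³ cm⁻³);
    dz is the layer thickness in metres.
    """

    theta_fc: float
    theta: float
    dz: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_fc <= 1.0):
            raise DomainError(f"field capacity {self.theta_fc} outside [0, 1]")
        if self.theta < 0.0:
            raise DomainError(f"water content {self.theta} negative")
        if self.theta > self.theta_fc:
            raise DomainError(
                f"water content {self.theta} exceeds field capacity {self.theta_fc}"
            )
        if self.dz <= 0.0:
            raise DomainError("layer thickness must be positive")


@dataclass(frozen=True)
class IrrigationSpec:
    """Net and gross depths for one treatment application."""

    d_n: float
    d_g: float
    efficiency: float = 0.9
    treatment_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.d_g < self.d_n:
            raise DomainError("gross depth cannot be below net depth")
        if not (0.0 < self.efficiency <= 1.0):
            raise DomainError("efficiency must be in (0, 1]")
        if not (0.0 < self.treatment_fraction <= 1.0):
            raise DomainError("treatment fraction must be in (0, 1]")

    @property
    def applied_depth(self) -> float:
        return self.treatment_fraction * self.d_g


def net_irrigation_depth(layers: Iterable[SoilLayer] | SoilLayer) -> float:
    """Soil-water deficit depth (m) summed over layers.

    Additive over layers and homogeneous of degree one in layer
    thickness; zero when every layer sits at field capacity.  A trial
    with a single measured layer is simply a one-element list.
    """
    if isinstance(layers, SoilLayer):
        layers = [layers]
    return float(sum((lay.theta_fc - lay.theta) * lay.dz for lay in layers))


def gross_irrigation_depth(
    d_n: float, efficiency: float = 0.9, treatment_fraction: float = 1.0
) -> float:
    """Applied water depth (m): treatment_fraction × d_n / efficiency.

    ``treatment_fraction`` 1.0 reproduces the well-watered control;
    0.5 the deficit (drought) treatment.
    """
    if d_n < 0.0:
        raise DomainError("net depth must be non-negative")
    if not (0.0 < efficiency <= 1.0):
        raise DomainError("efficiency must be in (0, 1]")
    if not (0.0 < treatment_fraction <= 1.0):
        raise DomainError("treatment fraction must be in (0, 1]")
    return treatment_fraction * d_n / efficiency


def irrigation_plan(
    layers: Iterable[SoilLayer] | SoilLayer,
    efficiency: float = 0.9,
    treatment_fractions: Iterable[float] = (1.0, 0.5),
) -> list[IrrigationSpec]:
    """Net and gross depths for each treatment fraction of a deficit design."""
    d_n = net_irrigation_depth(layers)
    full = gross_irrigation_depth(d_n, efficiency)
    return [
        IrrigationSpec(d_n=d_n, d_g=full, efficiency=efficiency, treatment_fraction=f)
        for f in treatment_fractions
    ]
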