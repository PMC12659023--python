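"""Transport-coefficient rescaling and ratio statistics.

Electroosmotic flows measured with different water models are put on a
common footing by multiplying with the viscosity ratio μ_x/μ_TIP3P;
ionic currents are rescaled by the inverse conductivity ratio
σ_ref/σ_x.  Ratios whose numerator or denominator is statistically
indistinguishable from zero (|mean| < 2·error) are flagged unreliable:
their propagated error is extremely large.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .flux import FlowEstimate

__all__ = [
    "TransportConstants",
    "RescaledEstimate",
    "rescale_eof",
    "rescale_current",
    "normalized_ratio",
    "is_negligible",
]

#: Water-model shear viscosities, mPa·s.
DEFAULT_VISCOSITIES = {"TIP3P": 0.32, "OPC": 0.80, "water": 0.90}


@dataclass
class TransportConstants:
    """Viscosities per water model and conductivities per force field.

    ``conductivities`` maps a force-field label to (σ in S/m,
    concentration in mol/L); the concentration is checked for
    consistency when rescaling currents.
    """

    viscosities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VISCOSITIES)
    )
    conductivities: dict[str, tuple[float, float]] = field(default_factory=dict)
    viscosity_reference: str = "TIP3P"
    conductivity_reference: str = "CHARMM36"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.viscosities.values()):
            raise ValueError("viscosities must be positive")
        if any(s <= 0 for s, _ in self.conductivities.values()):
            raise ValueError("conductivities must be positive")

    @classmethod
    def from_toml(cls, path: str) -> "TransportConstants":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cond = {
            k: (float(v["sigma"]), float(v["concentration"]))
            for k, v in data.get("conductivities", {}).items()
        }
        return cls(
            viscosities={
                k: float(v) for k, v in data.get("viscosities", {}).items()
            }
            or dict(DEFAULT_VISCOSITIES),
            conductivities=cond,
            viscosity_reference=data.get("viscosity_reference", "TIP3P"),
            conductivity_reference=data.get("conductivity_reference", "CHARMM36"),
        )

    def viscosity_factor(self, model: str) -> float:
        """μ_x / μ_reference for a water model label."""
        for label in (model, self.viscosity_reference):
            if label not in self.viscosities:
                raise KeyError(
                    f"unknown water model {label!r}; known: "
                    f"{sorted(self.viscosities)}"
                )
        return self.viscosities[model] / self.viscosities[self.viscosity_reference]

    def conductivity_factor(self, force_field: str) -> float:
        """σ_reference / σ_x for a force-field label, checking concentrations."""
        for label in (force_field, self.conductivity_reference):
            if label not in self.conductivities:
                raise KeyError(
                    f"unknown force field {label!r}; known: "
                    f"{sorted(self.conductivities)}"
                )
        sigma_x, conc_x = self.conductivities[force_field]
        sigma_ref, conc_ref = self.conductivities[self.conductivity_reference]
        if conc_x != conc_ref:
            raise ValueError(
                f"conductivity concentrations differ: {force_field} at "
                f"{conc_x} mol/L vs {self.conductivity_reference} at {conc_ref} mol/L"
            )
        return sigma_ref / sigma_x


@dataclass
class RescaledEstimate:
    value: float
    error: float
    reliable: bool = True
    units: str = ""


def is_negligible(e: FlowEstimate) -> bool:
    """True when the estimate is statistically indistinguishable from zero,
    i.e. |mean| < 2·error (strict; |mean| exactly 2·error is not negligible)."""
    if e.error < 0:
        raise ValueError("error must be >= 0")
    return abs(e.mean) < 2.0 * e.error


def rescale_eof(
    eof: FlowEstimate, model: str, constants: TransportConstants
) -> RescaledEstimate:
    """Viscosity-rescaled EOF: value and error multiplied by μ_x/μ_ref."""
    factor = constants.viscosity_factor(model)
    return RescaledEstimate(
        value=factor * eof.mean,
        error=factor * eof.error,
        reliable=not is_negligible(eof),
        units=eof.units,
    )


def rescale_current(
    current: FlowEstimate, force_field: str, constants: TransportConstants
) -> RescaledEstimate:
    """Conductivity-rescaled current: value and error multiplied by σ_ref/σ_x."""
    factor = constants.conductivity_factor(force_field)
    return RescaledEstimate(
        value=factor * current.mean,
        error=factor * current.error,
        reliable=not is_negligible(current),
        units=current.units,
    )


def normalized_ratio(a: FlowEstimate, b: FlowEstimate) -> RescaledEstimate:
    """a/b with first-order error propagation
    √((δa/b)² + (a·δb/b²)²); flagged unreliable when either input is
    negligible or b is exactly zero."""
    if a.units != b.units:
        raise ValueError("estimates must share units")
    if b.mean == 0:
        return RescaledEstimate(
            value=float("nan"), error=float("nan"), reliable=False, units=""
        )
    value = a.mean / b.mean
    error = ((a.error / b.mean) ** 2 + (a.mean * b.error / b.mean**2) ** 2) ** 0.5
    return RescaledEstimate(
        value=value,
        error=error,
        reliable=not (is_negligible(a) or is_negligible(b)),
        units="",
    )
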