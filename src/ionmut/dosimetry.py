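"""Dose / particle-fluence conversions for heavy-ion irradiation.

A particle traversing matter deposits ``LET`` keV per micrometre of track.
For a target slab of unit cross-section area ``A`` (μm²) and specific
gravity ``rho`` (g/cm³), the absorbed dose delivered by ``N`` particles is

    dose [Gy] = N * LET * k / (A * rho)

where ``k`` converts keV per μm³ of unit-density water into gray:
``k = (J per keV) / (kg per μm³ of water) = 1.602e-16 / 1e-15 = 0.1602``.

All public functions work per "nucleus area", the reference cross-section
of a cell nucleus (100 μm² by convention here), so fluences are expressed
as particles per nucleus rather than per cm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "KEV_TO_JOULE",
    "WATER_MICRON3_KG",
    "DosimetryConfig",
    "DosimetryError",
    "IrradiationCondition",
    "fluence_from_dose",
    "dose_from_fluence",
    "condition_table",
]

#: Energy of 1 keV in joule.
KEV_TO_JOULE = 1.602e-16

#: Mass in kg of 1 μm³ of water at specific gravity 1.
WATER_MICRON3_KG = 1e-15


class DosimetryError(ValueError):
    """Raised for out-of-domain dosimetry parameters."""


@dataclass(frozen=True)
class DosimetryConfig:
    """Physical constants and reporting conventions.

    Parameters
    ----------
    kev_to_joule:
        Energy conversion constant, J/keV.
    rounding:
        Reporting convention for fluence: ``"nearest"`` rounds to the
        nearest integer particle, ``"none"`` reports the raw value.
    """

    kev_to_joule: float = KEV_TO_JOULE
    rounding: str = "nearest"

    def __post_init__(self) -> None:
        if self.kev_to_joule <= 0:
            raise DosimetryError("kev_to_joule must be positive")
        if self.rounding not in ("nearest", "none"):
            raise DosimetryError(f"unknown rounding convention {self.rounding!r}")

    @property
    def gray_per_kev_um3(self) -> float:
        """Gy delivered by 1 keV deposited in 1 μm³ of unit-density water."""
        return self.kev_to_joule / WATER_MICRON3_KG

    def report_fluence(self, fluence: float) -> float:
        return round(fluence) if self.rounding == "nearest" else fluence


_DEFAULT_CONFIG = DosimetryConfig()


def _check_params(let: float, density: float, nucleus_area: float) -> None:
    if let <= 0:
        raise DosimetryError(f"LET must be positive, got {let}")
    if density <= 0:
        raise DosimetryError(f"density must be positive, got {density}")
    if nucleus_area <= 0:
        raise DosimetryError(f"nucleus_area must be positive, got {nucleus_area}")


def fluence_from_dose(
    dose: float,
    let: float,
    density: float = 1.0,
    nucleus_area: float = 100.0,
    config: DosimetryConfig | None = None,
) -> float:
    """Particles per ``nucleus_area`` delivering ``dose`` at the given LET.

    Parameters
    ----------
    dose:
        Absorbed dose, Gy.
    let:
        Linear energy transfer, keV/μm.
    density:
        Specific gravity of the target, g/cm³.
    nucleus_area:
        Reference cross-section, μm².

    Returns
    -------
    float
        Unrounded particle count per ``nucleus_area``.
    """
    config = config or _DEFAULT_CONFIG
    _check_params(let, density, nucleus_area)
    if dose < 0:
        raise DosimetryError(f"dose must be non-negative, got {dose}")
    return nucleus_area * dose * density / (let * config.gray_per_kev_um3)


def dose_from_fluence(
    fluence: float,
    let: float,
    density: float = 1.0,
    nucleus_area: float = 100.0,
    config: DosimetryConfig | None = None,
) -> float:
    """Absorbed dose (Gy) delivered by ``fluence`` particles per ``nucleus_area``.

    Exact inverse of :func:`fluence_from_dose`.
    """
    config = config or _DEFAULT_CONFIG
    _check_params(let, density, nucleus_area)
    if fluence < 0:
        raise DosimetryError(f"fluence must be non-negative, got {fluence}")
    return fluence * let * config.gray_per_kev_um3 / (nucleus_area * density)


@dataclass
class IrradiationCondition:
    """One irradiation treatment: ion, LET, dose and the derived fluence."""

    let: float
    dose: float
    ion_label: str = "12C6+"
    density: float = 1.0
    nucleus_area: float = 100.0
    fluence_per_area: float = field(init=False)

    def __post_init__(self) -> None:
        self.fluence_per_area = fluence_from_dose(
            self.dose, self.let, self.density, self.nucleus_area
        )


def condition_table(
    conditions: Iterable[Sequence[float]],
    density: float = 1.0,
    nucleus_area: float = 100.0,
    config: DosimetryConfig | None = None,
) -> pd.DataFrame:
    """Tabulate (LET, dose) pairs with their derived particle fluences.

    Rows keep the input order.  Invalid pairs raise :class:`DosimetryError`
    annotated with the offending condition index.
    """
    config = config or _DEFAULT_CONFIG
    rows = []
    for i, pair in enumerate(conditions):
        let, dose = pair
        try:
            fluence = fluence_from_dose(dose, let, density, nucleus_area, config)
        except DosimetryError as exc:
            raise DosimetryError(f"condition {i} (let={let}, dose={dose}): {exc}") from exc
        rows.append(
            {
                "let_kev_um": let,
                "dose_gy": dose,
                "nucleus_area_um2": nucleus_area,
                "fluence_per_area": fluence,
                "fluence_reported": config.report_fluence(fluence),
            }
        )
    columns = [
        "let_kev_um",
        "dose_gy",
        "nucleus_area_um2",
        "fluence_per_area",
        "fluence_reported",
    ]
    return pd.DataFrame(rows, columns=columns)
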