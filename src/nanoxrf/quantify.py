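"""Thin-film standard calibration: counts -> areal mass -> ppm.

Count rates are converted to elemental areal masses by comparing the
sample's K-alpha count ratio over the internal Si standard (the Si3N4
support membrane) with the same ratio measured on a certified thin
multilayer reference standard of known Fe areal mass:

    am_X = am_Fe,std * (f_Fe/f_X) * (t_Si/t_Si,std)
                     * (S_X/S_Si) / (S_Fe,std/S_Si,std)

with the per-element fundamental-parameter factor f_X = sigma_X * xi_X / A_X
(fluorescence production cross-section at the excitation energy,
detector efficiency at the line energy, atomic mass).  The uncertainty
epsilon_X follows the same formula with the standard's certified
uncertainty in place of its areal mass — the budget is dominated by the
standard's certificate.

Areal masses convert to concentrations (mass fractions in ppm) through
the section thickness and an assumed density:

    c = am / (t * rho),   default t = 500 nm, rho = 1 g/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ElementConstants",
    "CalibrationStandard",
    "QuantResult",
    "areal_mass",
    "counts_from_areal_mass",
    "to_ppm",
    "from_ppm",
    "granule_background_quant",
    "default_constants",
    "default_standard",
]

DEFAULT_THICKNESS_CM = 500e-7  # 500 nm section
DEFAULT_DENSITY = 1.0  # g/cm^3 assigned to chemically fixed brain slices


@dataclass
class ElementConstants:
    """Per-element physical constants entering f_X = sigma * xi / A.

    ``table`` maps an element symbol to ``(sigma, xi, A)``:
    sigma — K fluorescence production cross-section at the excitation
    energy (cm^2/g); xi — detector efficiency at the K-alpha energy
    (0 < xi <= 1); A — atomic mass (g/mol).  Constants are inputs, not
    computed from first principles.
    """

    table: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for el, (sigma, xi, a) in self.table.items():
            if sigma <= 0 or not (0 < xi <= 1) or a <= 0:
                raise ValueError(f"invalid constants for {el}: {(sigma, xi, a)}")

    def f(self, element: str) -> float:
        try:
            sigma, xi, a = self.table[element]
        except KeyError:
            raise KeyError(f"element {element!r} not in constants table") from None
        return sigma * xi / a

    @classmethod
    def from_json(cls, path: str | Path) -> "ElementConstants":
        raw = json.loads(Path(path).read_text())
        return cls(
            table={
                el: (rec["sigma_cm2_g"], rec["xi"], rec["A_g_mol"])
                for el, rec in raw["elements"].items()
            }
        )


@dataclass
class CalibrationStandard:
    """Calibration record for a thin multilayer reference standard.

    Fields mirror what a beamline calibration run provides: the
    standard's certified Fe areal mass and uncertainty, the Fe and Si
    count rates measured on the standard, and the Si3N4 membrane
    thicknesses of the sample mount and of the standard mount (the Si
    signal of the membrane is the internal normalisation channel).
    """

    am_fe: float  # certified Fe areal mass, ng/cm^2
    eps_fe: float  # its certified uncertainty, ng/cm^2
    s_fe: float  # Fe K-alpha count rate measured on the standard
    s_si: float  # Si K-alpha count rate measured on the standard
    t_si_cm: float  # sample-mount membrane thickness, cm
    t_si_std_cm: float  # standard-mount membrane thickness, cm
    constants: ElementConstants = field(default_factory=lambda: default_constants())

    def __post_init__(self) -> None:
        for name in ("am_fe", "eps_fe", "s_fe", "s_si", "t_si_cm", "t_si_std_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path, constants: ElementConstants | None = None) -> "CalibrationStandard":
        raw = json.loads(Path(path).read_text())["standard"]
        return cls(
            am_fe=raw["am_fe_ng_cm2"],
            eps_fe=raw["eps_fe_ng_cm2"],
            s_fe=raw["s_fe_counts"],
            s_si=raw["s_si_counts"],
            t_si_cm=raw["t_si_cm"],
            t_si_std_cm=raw["t_si_std_cm"],
            constants=constants or default_constants(),
        )


@dataclass
class QuantResult:
    element: str
    am: float  # ng/cm^2
    eps: float  # ng/cm^2 (absolute); eps_percent gives the relative form
    c_ppm: float | None = None
    compartment: str = ""
    neuron_id: str = ""

    @property
    def eps_percent(self) -> float:
        return 100.0 * self.eps / self.am if self.am > 0 else float("nan")


def areal_mass(
    s_x: float, s_si: float, std: CalibrationStandard, element: str
) -> tuple[float, float]:
    """Areal mass (ng/cm^2) and its uncertainty from count rates.

    ``s_x`` and ``s_si`` are the element and internal-Si counts summed
    over the same region (any common live-time factor cancels in the
    ratio).
    """
    if s_si <= 0:
        raise ValueError("internal Si standard absent (S_Si <= 0)")
    if s_x < 0:
        raise ValueError("element counts must be non-negative")
    f_ratio = std.constants.f("Fe") / std.constants.f(element)
    scale = (
        f_ratio
        * (std.t_si_cm / std.t_si_std_cm)
        * (s_x / s_si)
        / (std.s_fe / std.s_si)
    )
    return std.am_fe * scale, std.eps_fe * scale


def counts_from_areal_mass(
    am_x: float, s_si: float, std: CalibrationStandard, element: str
) -> float:
    """Inverse of :func:`areal_mass`: expected element counts for a target
    areal mass at a given internal-Si count level.  Used by the phantom
    generator so that synthetic maps round-trip the calibration."""
    if s_si <= 0:
        raise ValueError("internal Si standard absent (S_Si <= 0)")
    if am_x < 0:
        raise ValueError("areal mass must be non-negative")
    f_ratio = std.constants.f("Fe") / std.constants.f(element)
    denom = f_ratio * (std.t_si_cm / std.t_si_std_cm) / (std.s_fe / std.s_si)
    return (am_x / std.am_fe) / denom * s_si


def to_ppm(
    am: float | np.ndarray,
    t_cm: float = DEFAULT_THICKNESS_CM,
    rho: float = DEFAULT_DENSITY,
) -> float | np.ndarray:
    """Concentration in ppm (mass fraction x 1e6) from areal mass in ng/cm^2.

    c = am / (t * rho):  ng/cm^2 / (cm * g/cm^3) = 1e-9 g/g per unit,
    i.e. 1e-3 ppm per (ng/cm^2)/(t_cm * rho).
    """
    if t_cm <= 0:
        raise ValueError("section thickness must be positive")
    if rho <= 0:
        raise ValueError("density must be positive")
    return np.multiply(am, 1e-3) / (t_cm * rho)


def from_ppm(
    c_ppm: float, t_cm: float = DEFAULT_THICKNESS_CM, rho: float = DEFAULT_DENSITY
) -> float:
    """Areal mass (ng/cm^2) corresponding to a concentration in ppm."""
    if t_cm <= 0 or rho <= 0:
        raise ValueError("thickness and density must be positive")
    return c_ppm * t_cm * rho * 1e3


def granule_background_quant(
    maps: dict[str, "object"],
    background: np.ndarray,
    std: CalibrationStandard,
    elements: tuple[str, ...] = ("Fe", "S"),
) -> dict[str, tuple[float, float]]:
    """Background areal masses in the cytoplasm with granules masked out.

    ``maps`` must contain an ``"Si"`` map (internal standard) besides
    the requested elements; ``background`` is the boolean
    cytoplasm-minus-granules region.
    """
    background = np.asarray(background, dtype=bool)
    if not background.any():
        raise ValueError("empty background region")
    if "Si" not in maps:
        raise ValueError("internal Si standard absent (no Si map)")
    s_si, _ = maps["Si"].region_sum(background)
    out = {}
    for el in elements:
        s_x, _ = maps[el].region_sum(background)
        out[el] = areal_mass(s_x, s_si, std, el)
    return out


def default_constants() -> ElementConstants:
    """Constants table shipped with the package (documented nominal values)."""
    with resources.files("nanoxrf.data").joinpath("element_constants.json").open() as fh:
        raw = json.load(fh)
    return ElementConstants(
        table={
            el: (rec["sigma_cm2_g"], rec["xi"], rec["A_g_mol"])
            for el, rec in raw["elements"].items()
        }
    )


def default_standard() -> CalibrationStandard:
    """Synthetic calibration-standard record shipped with the package."""
    with resources.files("nanoxrf.data").joinpath("standard_synthetic.json").open() as fh:
        raw = json.load(fh)["standard"]
    return CalibrationStandard(
        am_fe=raw["am_fe_ng_cm2"],
        eps_fe=raw["eps_fe_ng_cm2"],
        s_fe=raw["s_fe_counts"],
        s_si=raw["s_si_counts"],
        t_si_cm=raw["t_si_cm"],
        t_si_std_cm=raw["t_si_std_cm"],
    )
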