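"""Synthetic neuron phantoms with the statistical structure of nano-XRF data.

The phantom emulates what the analysis assumes about a scanned neuron:
a compartmented geometry (neuropil around a cell body with cytoplasm,
nucleus, nucleolus, a P-rich perinuclear rim and optional organelles),
per-compartment expected element count rates on the scale of published
compartment areal masses (mapped to counts through the calibration
module's inverse, so phantom -> pipeline round-trips exercise the full
counts -> areal-mass chain), independent per-pixel Poisson shot noise,
a spatially uniform Si channel from the support membrane (internal
control), and sub-micron Fe/S granules with S-rich core / Fe-rich rim
morphology.

Geometry is procedural (ellipses; later classes overwrite earlier ones
in declared order), not traced from images: tests need parametric
ground truth.  One global integer seed governs organelle placement,
granule placement and noise through deterministically derived
substreams, so identical (spec, seed) reproduces identical maps
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanoxrf.maps import ElementMap
from nanoxrf.registration import RegionMask
from nanoxrf.reference import load_reference_table
from nanoxrf.quantify import CalibrationStandard, counts_from_areal_mass, default_standard
from nanoxrf.spectra import DetectorModel, SpectrumStack, _design_matrix

__all__ = [
    "Ellipse",
    "FullField",
    "GranuleSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "render_spectra",
    "neuron_phantom_spec",
    "composition_from_reference",
]


@dataclass
class FullField:
    """Shape covering the whole grid (the background/neuropil layer)."""

    cls: str


@dataclass
class Ellipse:
    """Filled ellipse; pixel membership by center-of-pixel inclusion."""

    cls: str
    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (row, col), pixels
    angle: float = 0.0  # radians, counter-clockwise

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = ca * dc + sa * dr
        v = -sa * dc + ca * dr
        return (u / self.semi_axes[1]) ** 2 + (v / self.semi_axes[0]) ** 2 <= 1.0


@dataclass
class GranuleSpec:
    """Population of Fe/S granules to drop into a placement compartment.

    Each granule is an S-enriched core disk; when ``rim_width_nm`` is
    positive the Fe enhancement sits in an annulus around the core
    (S-rich core / Fe-rich rim morphology), otherwise Fe is added
    uniformly over the disk (homogeneous granule).  Rates are *added*
    counts/pixel on top of the host compartment's rates.
    """

    n: int
    radius_range_nm: tuple[float, float]
    s_core_rate: float
    fe_rate: float
    rim_width_nm: float = 0.0
    placement_class: str = "cytoplasm"
    max_rejections: int = 2000


@dataclass
class PhantomSpec:
    """Full description of one synthetic neuron acquisition."""

    grid_shape: tuple[int, int]
    pixel_size_nm: float
    geometry: list  # FullField / Ellipse, drawn in order (later wins)
    composition: dict[str, dict[str, float]]  # class -> element -> counts/px
    granules: GranuleSpec | None = None
    dwell_scale: float = 1.0
    seed: int = 0

    def elements(self) -> list[str]:
        els: set[str] = set()
        for rates in self.composition.values():
            els.update(rates)
        return sorted(els)

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1 or self.pixel_size_nm <= 0 or self.dwell_scale < 0:
            raise ValueError("invalid grid or scales")
        for cls, rates in self.composition.items():
            for el, rate in rates.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {cls}/{el}")
        for shape in self.geometry:
            if isinstance(shape, Ellipse):
                r0, c0 = shape.center
                ar, ac = shape.semi_axes
                m = max(ar, ac)
                if r0 - m < -0.5 or r0 + m > rows - 0.5 or c0 - m < -0.5 or c0 + m > cols - 0.5:
                    raise ValueError(f"shape for class {shape.cls!r} exceeds the grid")
            if shape.cls not in self.composition:
                raise ValueError(f"class {shape.cls!r} has no composition entry")
        if self.granules is not None:
            g = self.granules
            if g.n < 0 or g.s_core_rate < 0 or g.fe_rate < 0:
                raise ValueError("granule rates and count must be non-negative")
            if g.radius_range_nm[0] < self.pixel_size_nm:
                raise ValueError("granule radius must be at least one pixel")
            if g.n > 0 and not {"Fe", "S"} <= set(self.elements()):
                raise ValueError("granules need Fe and S composition channels")


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated phantom."""

    region_mask: RegionMask  # partition of the grid incl. a "granule" class
    true_rates: dict[str, dict[str, float]]  # class -> element -> counts/px
    granule_table: pd.DataFrame  # one row per rendered granule
    granule_labels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def mask(self, cls: str) -> np.ndarray:
        return self.region_mask.boolean(cls)


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def generate_phantom(spec: PhantomSpec) -> tuple[dict[str, ElementMap], PhantomTruth]:
    """Render a phantom: per-element Poisson count maps plus ground truth."""
    spec.validate()
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    # class labels in declared order; later shapes overwrite earlier ones
    class_order: list[str] = []
    for shape in spec.geometry:
        if shape.cls not in class_order:
            class_order.append(shape.cls)
    label_of = {cls: i + 1 for i, cls in enumerate(class_order)}
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    for shape in spec.geometry:
        if isinstance(shape, FullField):
            labels[:] = label_of[shape.cls]
        else:
            labels[shape.contains(rr, cc)] = label_of[shape.cls]

    elements = spec.elements()
    rates = {el: np.zeros(spec.grid_shape) for el in elements}
    for cls, comp in spec.composition.items():
        if cls not in label_of:
            continue
        region = labels == label_of[cls]
        for el, rate in comp.items():
            rates[el][region] = rate * spec.dwell_scale

    granule_rows: list[dict] = []
    granule_labels = np.zeros(spec.grid_shape, dtype=np.int32)
    if spec.granules is not None and spec.granules.n > 0:
        _place_granules(spec, labels, label_of, rates, granule_labels, granule_rows, rr, cc)

    if granule_labels.any():
        label_of["granule"] = len(class_order) + 1
        labels = labels.copy()
        labels[granule_labels > 0] = label_of["granule"]

    rng = _substream(spec.seed, 1)
    maps = {}
    for el in elements:  # sorted order keeps the draw sequence reproducible
        counts = rng.poisson(rates[el]).astype(np.float64)
        maps[el] = ElementMap(
            element=el,
            counts=counts,
            pixel_size_nm=spec.pixel_size_nm,
            uncertainty=None,  # raw counts: Poisson sqrt(S) applies downstream
        )

    truth = PhantomTruth(
        region_mask=RegionMask(
            labels=labels,
            class_table={v: k for k, v in label_of.items()},
            pixel_size_nm=spec.pixel_size_nm,
        ),
        true_rates={
            cls: {el: r * spec.dwell_scale for el, r in comp.items()}
            for cls, comp in spec.composition.items()
        },
        granule_table=pd.DataFrame(
            granule_rows,
            columns=[
                "granule", "center_row", "center_col", "radius_nm",
                "n_core_px", "n_rim_px", "expected_S", "expected_Fe",
            ],
        ),
        granule_labels=granule_labels,
    )
    return maps, truth


def _place_granules(spec, labels, label_of, rates, granule_labels, granule_rows, rr, cc):
    g = spec.granules
    host = labels == label_of[g.placement_class]
    if not host.any():
        raise ValueError(f"placement class {g.placement_class!r} has no pixels")
    host_idx = np.flatnonzero(host.ravel())
    rng = _substream(spec.seed, 0)
    px = spec.pixel_size_nm
    rejections = 0
    placed = 0
    while placed < g.n:
        if rejections > g.max_rejections:
            raise RuntimeError(
                f"granule placement failed: {placed}/{g.n} placed after "
                f"{rejections} rejections in class {g.placement_class!r}"
            )
        radius_nm = rng.uniform(*g.radius_range_nm)
        flat = rng.choice(host_idx)
        r0, c0 = np.unravel_index(flat, spec.grid_shape)
        r_out_px = (radius_nm + g.rim_width_nm) / px
        dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
        footprint = dist <= r_out_px
        # the full footprint must sit inside the host compartment and not
        # touch a previously placed granule
        if not host[footprint].all() or (granule_labels[footprint] > 0).any():
            rejections += 1
            continue
        core = dist <= radius_nm / px
        rim = footprint & ~core if g.rim_width_nm > 0 else footprint
        s_add = g.s_core_rate * spec.dwell_scale
        fe_add = g.fe_rate * spec.dwell_scale
        rates["S"][core] += s_add
        if g.rim_width_nm > 0:
            rates["Fe"][rim] += fe_add
        else:
            rates["Fe"][footprint] += fe_add
        placed += 1
        granule_labels[footprint] = placed
        granule_rows.append(
            {
                "granule": placed,
                "center_row": int(r0),
                "center_col": int(c0),
                "radius_nm": float(radius_nm),
                "n_core_px": int(core.sum()),
                "n_rim_px": int((footprint & ~core).sum()),
                "expected_S": float(rates["S"][footprint].sum()),
                "expected_Fe": float(rates["Fe"][footprint].sum()),
            }
        )


def render_spectra(
    element_maps: dict[str, ElementMap],
    detector: DetectorModel,
    seed: int,
    offset_kev: float = 0.0,
    gain_kev: float = 0.012,
    n_channels: int = 1024,
    background_per_pixel: float = 0.0,
    live_time_s: float = 0.05,
) -> SpectrumStack:
    """Expand count maps into a noisy per-pixel spectrum stack.

    Each pixel's expected histogram is the sum of unit-area K-line
    profiles (K-alpha plus tied K-beta) scaled to that pixel's counts,
    plus an optional smooth low-energy background emulating membrane
    and resin scatter; Poisson noise is applied per energy channel.
    """
    elements = sorted(element_maps)
    for el in elements:
        if el not in detector.lines:
            raise ValueError(f"element {el!r} has no tabulated K-line energies")
    first = element_maps[elements[0]]
    shape = first.shape
    energies = offset_kev + gain_kev * np.arange(n_channels)
    profiles = _design_matrix(energies, elements, detector, gain_kev)  # (chan, el)

    counts = np.stack(
        [np.nan_to_num(element_maps[el].counts, nan=0.0) for el in elements], axis=-1
    )  # (rows, cols, el)
    expected = counts @ profiles.T  # (rows, cols, chan)
    if background_per_pixel > 0:
        bshape = np.exp(-energies / 4.0)
        bshape /= bshape.sum()
        expected = expected + background_per_pixel * bshape

    rng = _substream(seed, 2)
    noisy = rng.poisson(expected).astype(np.uint32)
    return SpectrumStack(
        counts=noisy,
        offset_kev=offset_kev,
        gain_kev=gain_kev,
        pixel_size_nm=first.pixel_size_nm,
        live_time_s=live_time_s,
    )


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

# Nominal per-pixel Si counts contributed by the 500-nm Si3N4 membrane at
# fine-scan dwell; the membrane dominates the spectrum and is spatially
# uniform, so it doubles as the internal control channel.
SI_MEMBRANE_RATE = 20000.0

# Zn areal masses (ng/cm^2) are not part of the shipped reference table;
# nominal tissue-scale values with the nucleolar enrichment applied.
ZN_AM = {"neuropil": 2.5, "cytoplasm": 2.8, "nucleus": 3.0}

# Nucleolar enrichment factors over the nuclear reference used by the
# default preset (relative count-rate contrasts Delta + 1).
NUCLEOLAR_ENRICHMENT = {"P": 1.66, "S": 1.224, "Ca": 1.53, "Fe": 1.65, "Zn": 1.47}


def composition_from_reference(
    condition: str = "CTRL",
    neuron: int = 1,
    si_per_pixel: float = SI_MEMBRANE_RATE,
    standard: CalibrationStandard | None = None,
    nucleolar_enrichment: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Class -> element -> expected counts/pixel from reference areal masses.

    Areal masses of the published compartment table are pushed through
    the inverse of the calibration relation at the given internal-Si
    level, so analysing the phantom recovers the same areal masses.
    The nucleolus is set as the nucleus scaled by the stated enrichment
    factors (parametric ground truth for contrast-recovery tests); the
    neuropil is a P-poor, S-rich matrix relative to the cell body.
    """
    std = standard or default_standard()
    table = load_reference_table()
    sel = table[(table.condition == condition) & (table.neuron == neuron)]
    if sel.empty:
        raise ValueError(f"no reference rows for {condition} neuron {neuron}")
    enrich = nucleolar_enrichment or NUCLEOLAR_ENRICHMENT

    am: dict[str, dict[str, float]] = {}
    for compartment in ("nucleus", "cytoplasm"):
        rows = sel[sel.compartment == compartment]
        am[compartment] = dict(zip(rows.element, rows.am_ng_cm2))
        am[compartment]["Zn"] = ZN_AM[compartment]
    am["neuropil"] = {
        "P": 0.7 * am["nucleus"]["P"],
        "S": 1.35 * am["nucleus"]["S"],  # S-rich matrix: the cell is S-depleted
        "Ca": am["nucleus"]["Ca"],
        "Fe": 0.9 * am["nucleus"]["Fe"],
        "Zn": ZN_AM["neuropil"],
    }
    am["nucleolus"] = {el: am["nucleus"][el] * enrich.get(el, 1.0) for el in am["nucleus"]}
    am["perinuclear_rim"] = dict(am["nucleus"], P=1.8 * am["nucleus"]["P"])
    am["mitochondria"] = dict(am["cytoplasm"], Ca=1.5 * am["cytoplasm"]["Ca"])
    am["RER"] = dict(
        am["cytoplasm"],
        P=1.5 * am["cytoplasm"]["P"],
        Ca=2.0 * am["cytoplasm"]["Ca"],
    )
    am["lipofuscin"] = dict(
        am["cytoplasm"],
        Ca=2.0 * am["cytoplasm"]["Ca"],
        Fe=3.0 * am["cytoplasm"]["Fe"],
    )

    composition = {}
    for cls, comp in am.items():
        composition[cls] = {
            el: counts_from_areal_mass(m, si_per_pixel, std, el) for el, m in comp.items()
        }
        composition[cls]["Si"] = si_per_pixel
    return composition


def neuron_phantom_spec(
    condition: str = "ctrl",
    grid_shape: tuple[int, int] = (192, 192),
    pixel_size_nm: float = 50.0,
    seed: int = 0,
    organelles: bool = True,
    n_granules: int | None = None,
    si_per_pixel: float = SI_MEMBRANE_RATE,
    dwell_scale: float = 1.0,
    standard: CalibrationStandard | None = None,
) -> PhantomSpec:
    """Ready-made single-neuron phantom.

    ``condition="ctrl"`` renders smaller, homogeneous, S-dominated
    granules; ``condition="asyn"`` renders more and larger granules
    with strong Fe-rich rims, emulating the iron shift seen after
    alpha-synuclein overexpression.
    """
    condition = condition.lower()
    if condition not in ("ctrl", "asyn"):
        raise ValueError("condition must be 'ctrl' or 'asyn'")
    composition = composition_from_reference(
        condition="CTRL" if condition == "ctrl" else "ASYN",
        neuron=1,
        si_per_pixel=si_per_pixel,
        standard=standard,
    )
    rows, cols = grid_shape
    r0, c0 = rows / 2.0, cols / 2.0
    s = min(rows, cols) / 192.0  # geometry scales with the grid
    geometry: list = [
        FullField("neuropil"),
        Ellipse("cytoplasm", (r0, c0), (80 * s, 72 * s)),
        Ellipse("perinuclear_rim", (r0, c0 - 6 * s), (46 * s, 42 * s)),
        Ellipse("nucleus", (r0, c0 - 6 * s), (42 * s, 38 * s)),
        Ellipse("nucleolus", (r0 - 6 * s, c0 - 12 * s), (11 * s, 10 * s)),
    ]
    if organelles:
        rng = _substream(seed, 3)
        for cls, n, ax in (("mitochondria", 10, 3.0), ("RER", 6, 4.0), ("lipofuscin", 3, 3.0)):
            for _ in range(n):
                # drop small ellipses into the cytoplasmic shell
                for _attempt in range(200):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0.55, 0.85)
                    cr = r0 + rad * 80 * s * np.sin(ang) * 0.95
                    ccol = c0 + rad * 72 * s * np.cos(ang) * 0.95
                    e = Ellipse(cls, (cr, ccol), (ax * s * rng.uniform(0.7, 1.3), ax * s * rng.uniform(0.7, 1.3)), rng.uniform(0, np.pi))
                    drr = (cr - r0) / (80 * s - max(e.semi_axes))
                    dcc = (ccol - c0) / (72 * s - max(e.semi_axes))
                    if drr**2 + dcc**2 < 1.0:
                        geometry.append(e)
                        break

    cyto = composition["cytoplasm"]
    if condition == "ctrl":
        granules = GranuleSpec(
            n=8 if n_granules is None else n_granules,
            radius_range_nm=(60.0, 160.0),
            s_core_rate=4.0 * cyto["S"],
            fe_rate=1.5 * cyto["Fe"],
            rim_width_nm=0.0,
        )
    else:
        granules = GranuleSpec(
            n=12 if n_granules is None else n_granules,
            radius_range_nm=(80.0, 300.0),
            s_core_rate=4.0 * cyto["S"],
            fe_rate=6.0 * cyto["Fe"],
            rim_width_nm=100.0,
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        pixel_size_nm=pixel_size_nm,
        geometry=geometry,
        composition=composition,
        granules=granules,
        dwell_scale=dwell_scale,
        seed=seed,
    )
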