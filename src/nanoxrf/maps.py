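"""Per-element fitted-count rasters and their on-disk form.

An :class:`ElementMap` is the working currency of the pipeline: a 2-D
raster of fitted fluorescence counts for one element on a stated pixel
grid, optionally carrying a per-pixel uncertainty raster.  Maps are
written as single-channel 32-bit TIFF with a JSON sidecar recording the
element, pixel pitch and units.

Coordinate convention (used package-wide): pixel centers at integer
coordinates, origin at the top-left, x = column, y = row, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ElementMap"]


@dataclass
class ElementMap:
    """Fitted-count raster for a single element.

    Parameters
    ----------
    element:
        Element symbol, e.g. ``"Fe"``.
    counts:
        2-D array of fitted counts per pixel (non-negative; NaN marks
        pixels whose per-pixel fit failed).
    pixel_size_nm:
        Pixel pitch in nanometres (square pixels).
    uncertainty:
        Optional 2-D array of per-pixel count uncertainties.  When the
        map holds raw integrated counts this is ``sqrt(counts)``
        (Poisson); when it comes from a spectral fit it is the fit
        sigma.
    units:
        Physical meaning of ``counts``; ``"counts"`` by default.
    """

    element: str
    counts: np.ndarray
    pixel_size_nm: float
    uncertainty: np.ndarray | None = None
    units: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("ElementMap.counts must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty)
            if self.uncertainty.shape != self.counts.shape:
                raise ValueError("uncertainty shape must match counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in square micrometres."""
        return (self.pixel_size_nm / 1000.0) ** 2

    def region_sum(self, mask: np.ndarray) -> tuple[float, float]:
        """Summed counts ``S`` and Poisson uncertainty over a boolean mask.

        The region uncertainty is ``sqrt(sum(uncertainty**2))`` when a
        per-pixel uncertainty raster is present, else ``sqrt(S)``
        (shot-noise limit of raw counts).
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.counts.shape:
            raise ValueError("mask grid does not match map grid")
        vals = self.counts[mask]
        s = float(np.nansum(vals))
        if self.uncertainty is not None:
            sigma = float(np.sqrt(np.nansum(self.uncertainty[mask] ** 2)))
        else:
            sigma = float(np.sqrt(max(s, 0.0)))
        return s, sigma

    # ------------------------------------------------------------------ I/O
    def write_tiff(self, path: str | Path) -> Path:
        """Write the map as 32-bit TIFF plus a ``.json`` sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.counts.astype(np.float32))
        sidecar = {
            "element": self.element,
            "pixel_size_nm": self.pixel_size_nm,
            "units": self.units,
        }
        if self.uncertainty is not None:
            unc_path = path.with_name(path.stem + "_unc" + path.suffix)
            tifffile.imwrite(unc_path, self.uncertainty.astype(np.float32))
            sidecar["uncertainty_file"] = unc_path.name
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ElementMap":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        counts = tifffile.imread(path)
        unc = None
        if "uncertainty_file" in sidecar:
            unc = tifffile.imread(path.with_name(sidecar["uncertainty_file"]))
        return cls(
            element=sidecar["element"],
            counts=np.asarray(counts),
            pixel_size_nm=float(sidecar["pixel_size_nm"]),
            uncertainty=unc,
            units=sidecar.get("units", "counts"),
        )


def write_map_bundle(maps: dict[str, ElementMap], directory: str | Path) -> dict[str, Path]:
    """Write one TIFF per element under ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for element, emap in maps.items():
        out[element] = emap.write_tiff(directory / f"map_{element}.tif")
    return out


def read_map_bundle(directory: str | Path) -> dict[str, ElementMap]:
    """Read every ``map_*.tif`` element map in ``directory``."""
    directory = Path(directory)
    maps = {}
    for path in sorted(directory.glob("map_*.tif")):
        emap = ElementMap.read_tiff(path)
        maps[emap.element] = emap
    return maps
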