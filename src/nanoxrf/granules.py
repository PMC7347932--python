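"""Detection and characterisation of Fe/S-rich cytoplasmic granules.

Granules are sub-micron cytoplasmic regions whose Fe or S counts
exceed the mean cytoplasmic background by k standard deviations
(k = 2 by default).  The two exceedance masks are combined by union,
restricted to the cytoplasm, and 8-connected components of at least
2 pixels become labelled granules — isolated single-pixel exceedances
(a few percent of pixels under pure Poisson noise) are rejected by the
size floor.

Background statistics are computed over *all* cytoplasm pixels in a
single pass, granules included; an optional one-iteration refinement
(recompute mean/SD excluding the first-pass granules, re-threshold)
is available behind a flag and off by default.

Each granule is measured for area (pixel count x pixel area), summed
Fe/S counts and calibrated areal masses, the Fe/S mass ratio,
mean-over-background ratios against the granule-free cytoplasm, and a
within-granule heterogeneity index (sigma/mean per element).  Granule
populations are summarised per condition with a size split at
0.07 um^2 separating small from large granules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from nanoxrf.maps import ElementMap
from nanoxrf.quantify import CalibrationStandard, areal_mass

__all__ = [
    "GranuleRecord",
    "GranuleSummary",
    "detect_granules",
    "measure_granules",
    "summarize",
    "records_table",
    "colocalize",
]

SIZE_SPLIT_UM2 = 0.07  # small/large granule boundary
MIN_PIXELS = 2  # multi-pixel requirement


@dataclass
class GranuleRecord:
    """One detected granule and its per-element characterisation."""

    label: int
    area_um2: float
    n_pixels: int
    centroid: tuple[float, float]  # (row, col) pixels
    counts: dict[str, float]  # element -> summed counts
    am: dict[str, float]  # element -> areal mass ng/cm^2 (empty w/o standard)
    fe_s_ratio: float | None  # areal-mass ratio; None when S is zero
    over_background: dict[str, float]  # element -> mean / background-mean
    rsd: dict[str, float]  # element -> within-granule sigma/mean
    enriched_in: str = ""  # "Fe" | "S" | "Fe+S"
    condition: str = ""
    neuron_id: str = ""

    @property
    def size_class(self) -> str:
        return "small" if self.area_um2 < SIZE_SPLIT_UM2 else "large"


@dataclass
class GranuleSummary:
    condition: str
    n: int
    mean_area_um2: float | None = None
    sd_area_um2: float | None = None
    mean_fe_over_bgd: float | None = None
    mean_s_over_bgd: float | None = None
    mean_fe_s_ratio: float | None = None
    rsd_fe: float | None = None  # across-granule relative SD of Fe means
    rsd_s: float | None = None
    n_small: int = 0
    n_large: int = 0


def detect_granules(
    fe_map: ElementMap,
    s_map: ElementMap,
    cytoplasm: np.ndarray,
    k: float = 2.0,
    min_pixels: int = MIN_PIXELS,
    refine_background: bool = False,
) -> tuple[np.ndarray, dict[str, float]]:
    """Label Fe- or S-enriched granules inside the cytoplasm.

    Per element the threshold is ``mean + k * SD`` over cytoplasm
    pixels; a pixel is enriched if it exceeds either element's
    threshold.  Returns the granule label raster (0 = none) and the
    thresholds used.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    if cytoplasm.shape != fe_map.shape or fe_map.shape != s_map.shape:
        raise ValueError("maps and cytoplasm mask must share one grid")
    if not cytoplasm.any():
        raise ValueError("empty cytoplasm mask")

    def thresholds(region: np.ndarray) -> dict[str, float]:
        out = {}
        for emap in (fe_map, s_map):
            vals = emap.counts[region]
            out[emap.element] = float(np.nanmean(vals) + k * np.nanstd(vals))
        return out

    thr = thresholds(cytoplasm)
    enriched = (
        (fe_map.counts > thr[fe_map.element]) | (s_map.counts > thr[s_map.element])
    ) & cytoplasm
    labels = _label_min_size(enriched, min_pixels)

    if refine_background and labels.max() > 0:
        bgd = cytoplasm & (labels == 0)
        if bgd.any():
            thr = thresholds(bgd)
            enriched = (
                (fe_map.counts > thr[fe_map.element])
                | (s_map.counts > thr[s_map.element])
            ) & cytoplasm
            labels = _label_min_size(enriched, min_pixels)
    return labels, thr


def _label_min_size(enriched: np.ndarray, min_pixels: int) -> np.ndarray:
    labels = skmeasure.label(enriched, connectivity=2)
    if labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_pixels)
    keep = keep[keep > 0]
    remap = np.zeros(sizes.size, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def measure_granules(
    labels: np.ndarray,
    maps: dict[str, ElementMap],
    pixel_size_nm: float,
    cytoplasm: np.ndarray,
    standard: CalibrationStandard | None = None,
    condition: str = "",
    neuron_id: str = "",
) -> list[GranuleRecord]:
    """Characterise every labelled granule.

    ``maps`` must contain ``"Fe"`` and ``"S"``; an ``"Si"`` map plus a
    calibration standard enable areal masses and the Fe/S *mass* ratio
    (without them the Fe/S ratio falls back to the raw count ratio).
    Background means use the cytoplasm with all granules removed.
    """
    labels = np.asarray(labels)
    cytoplasm = np.asarray(cytoplasm, dtype=bool)
    background = cytoplasm & (labels == 0)
    bgd_mean = {
        el: float(np.nanmean(maps[el].counts[background])) if background.any() else np.nan
        for el in ("Fe", "S")
    }
    pixel_area = (pixel_size_nm / 1000.0) ** 2

    records: list[GranuleRecord] = []
    for prop in skmeasure.regionprops(labels):
        region = labels == prop.label
        counts, am, rsd, over = {}, {}, {}, {}
        for el in ("Fe", "S"):
            vals = maps[el].counts[region].astype(float)
            counts[el] = float(np.nansum(vals))
            mean = float(np.nanmean(vals))
            rsd[el] = float(np.nanstd(vals) / mean) if mean > 0 else float("nan")
            over[el] = mean / bgd_mean[el] if bgd_mean[el] and bgd_mean[el] > 0 else float("nan")
        if standard is not None and "Si" in maps:
            s_si, _ = maps["Si"].region_sum(region)
            for el in ("Fe", "S"):
                am[el] = areal_mass(counts[el], s_si, standard, el)[0]
            fe_s = am["Fe"] / am["S"] if am["S"] > 0 else None
        else:
            fe_s = counts["Fe"] / counts["S"] if counts["S"] > 0 else None
        records.append(
            GranuleRecord(
                label=int(prop.label),
                area_um2=float(prop.num_pixels * pixel_area),
                n_pixels=int(prop.num_pixels),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                counts=counts,
                am=am,
                fe_s_ratio=fe_s,
                over_background=over,
                rsd=rsd,
                enriched_in=_enrichment_class(over),
                condition=condition,
                neuron_id=neuron_id,
            )
        )
    return records


def _enrichment_class(over: dict[str, float]) -> str:
    fe, s = over.get("Fe", float("nan")), over.get("S", float("nan"))
    tags = [el for el, v in (("Fe", fe), ("S", s)) if np.isfinite(v) and v > 1.0]
    return "+".join(tags) if tags else ""


def summarize(
    records: list[GranuleRecord], condition: str = ""
) -> GranuleSummary:
    """Population summary of one condition's granules (n = 0 safe)."""
    recs = [r for r in records if not condition or r.condition == condition]
    n = len(recs)
    if n == 0:
        return GranuleSummary(condition=condition, n=0)
    areas = np.array([r.area_um2 for r in recs])
    fe_over = np.array([r.over_background["Fe"] for r in recs])
    s_over = np.array([r.over_background["S"] for r in recs])
    ratios = np.array([r.fe_s_ratio for r in recs if r.fe_s_ratio is not None])
    fe_means = fe_over[np.isfinite(fe_over)]
    s_means = s_over[np.isfinite(s_over)]

    def rel_sd(x: np.ndarray) -> float | None:
        if len(x) < 2 or x.mean() == 0:
            return None
        return float(x.std(ddof=1) / x.mean())

    return GranuleSummary(
        condition=condition,
        n=n,
        mean_area_um2=float(areas.mean()),
        sd_area_um2=float(areas.std(ddof=1)) if n > 1 else 0.0,
        mean_fe_over_bgd=float(fe_means.mean()) if len(fe_means) else None,
        mean_s_over_bgd=float(s_means.mean()) if len(s_means) else None,
        mean_fe_s_ratio=float(ratios.mean()) if len(ratios) else None,
        rsd_fe=rel_sd(fe_means),
        rsd_s=rel_sd(s_means),
        n_small=int((areas < SIZE_SPLIT_UM2).sum()),
        n_large=int((areas >= SIZE_SPLIT_UM2).sum()),
    )


def records_table(records: list[GranuleRecord]) -> pd.DataFrame:
    """One row per granule, CSV-ready."""
    rows = []
    for r in records:
        rows.append(
            {
                "label": r.label,
                "condition": r.condition,
                "neuron_id": r.neuron_id,
                "area_um2": r.area_um2,
                "n_pixels": r.n_pixels,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "Fe_counts": r.counts.get("Fe"),
                "S_counts": r.counts.get("S"),
                "Fe_am": r.am.get("Fe"),
                "S_am": r.am.get("S"),
                "FeS_ratio": r.fe_s_ratio,
                "Fe_over_bgd": r.over_background.get("Fe"),
                "S_over_bgd": r.over_background.get("S"),
                "Fe_rsd": r.rsd.get("Fe"),
                "S_rsd": r.rsd.get("S"),
                "size_class": r.size_class,
                "enriched_in": r.enriched_in,
            }
        )
    return pd.DataFrame(rows)


def colocalize(labels: np.ndarray, tem_mask: np.ndarray) -> pd.DataFrame:
    """Overlap fraction of each granule with a transformed TEM mask.

    Returns one row per granule with the fraction of its pixels inside
    the TEM class (e.g. lipofuscin) and a matched flag (> 50% overlap);
    granules not matching any recognised structure are the norm, not an
    error.
    """
    labels = np.asarray(labels)
    tem_mask = np.asarray(tem_mask, dtype=bool)
    rows = []
    for prop in skmeasure.regionprops(labels):
        region = labels == prop.label
        frac = float(tem_mask[region].mean())
        rows.append({"label": int(prop.label), "overlap_fraction": frac, "matched": frac > 0.5})
    return pd.DataFrame(rows)
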