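"""End-to-end orchestration: maps/masks in -> contrasts, masses, granules out.

A run is described by a single :class:`RunConfig` (loadable from YAML).
Inputs are either pre-fitted per-element TIFF maps or an HDF5 spectrum
stack (then compartment counts come from mask-summed spectrum fits and
granule maps from per-pixel fits).  Outputs land under one directory:
tidy CSV tables, label TIFFs, a log, and a reproducibility manifest
written atomically at the end of the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import nanoxrf
from nanoxrf import contrast as contrast_mod
from nanoxrf import granules as granules_mod
from nanoxrf import phantom as phantom_mod
from nanoxrf import quantify as quantify_mod
from nanoxrf import spectra as spectra_mod
from nanoxrf.maps import read_map_bundle, write_map_bundle
from nanoxrf.registration import (
    FiducialSet,
    RegionMask,
    apply_transform,
    check_alignment,
    estimate_similarity,
)

__all__ = ["RunConfig", "RunManifest", "run_full", "simulate"]

log = logging.getLogger("nanoxrf")

SCAN_PRESETS_NM = {"coarse": 400.0, "fine": 50.0, "very-fine": 25.0}

CONTRAST_COMPARTMENTS = (
    "cytoplasm",
    "nucleolus",
    "perinuclear_rim",
    "neuropil",
    "mitochondria",
    "RER",
    "lipofuscin",
)


@dataclass
class RunConfig:
    output_dir: str
    maps_dir: str | None = None  # pre-fitted per-element TIFF maps
    stack_path: str | None = None  # HDF5 spectrum stack (alternative input)
    masks_path: str | None = None  # label TIFF (+ .json class table)
    fiducials_path: str | None = None  # CSV src_x,src_y,dst_x,dst_y
    standard_path: str | None = None  # calibration standard JSON
    elements: tuple[str, ...] = ("Si", "P", "S", "Ca", "Fe", "Zn")
    scan_mode: str = "fine"  # coarse | fine | very-fine
    pixel_size_nm: float | None = None  # explicit override of the preset
    k_sigma: float = 2.0
    min_granule_pixels: int = 2
    thickness_cm: float = quantify_mod.DEFAULT_THICKNESS_CM
    density_g_cm3: float = quantify_mod.DEFAULT_DENSITY
    max_rms_px: float = 1.0
    seed: int = 0
    neuron_id: str = "n1"
    condition: str = "ctrl"

    def __post_init__(self) -> None:
        if self.pixel_size_nm is None:
            if self.scan_mode not in SCAN_PRESETS_NM:
                raise ValueError(
                    f"scan_mode must be one of {sorted(SCAN_PRESETS_NM)} "
                    "or pixel_size_nm given explicitly"
                )
            self.pixel_size_nm = SCAN_PRESETS_NM[self.scan_mode]
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.thickness_cm <= 0:
            raise ValueError("section thickness must be positive")
        for name in ("maps_dir", "stack_path", "masks_path", "fiducials_path", "standard_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "elements" in raw:
            raw["elements"] = tuple(raw["elements"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        """Atomic write: temp file in the same directory, then rename."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2))
        os.replace(tmp, path)


def _setup_logging(output_dir: Path) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(output_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_full(config: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk).

    Stage order: input ingest (maps or stack fit) -> mask alignment ->
    compartment counting -> contrast -> quantification (skipped with a
    warning when no standard is configured) -> granule analysis.
    Stage failures raise with the stage name; the manifest flags what
    completed.
    """
    out = Path(config.output_dir)
    _setup_logging(out)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=nanoxrf.__version__, seed=config.seed
    )
    try:
        maps, stack = _stage_ingest(config, manifest)
        mask = _stage_align(config, manifest, maps)
        counts = _stage_compartments(config, manifest, maps, stack, mask)
        _stage_contrast(config, manifest, counts, out)
        standard = _stage_quantify(config, manifest, counts, out)
        _stage_granules(config, manifest, maps, mask, standard, out)
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        manifest.warnings.append(f"aborted: {exc}")
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    log.info("run complete: %s", out)
    return manifest


def _stage_ingest(config, manifest):
    if config.maps_dir:
        maps = read_map_bundle(config.maps_dir)
        stack = None
        source = "maps"
    elif config.stack_path:
        stack = spectra_mod.SpectrumStack.read_h5(config.stack_path)
        detector = spectra_mod.DetectorModel()
        log.info("fitting per-pixel maps for %s", config.elements)
        maps = spectra_mod.per_pixel_maps(stack, list(config.elements), detector)
        source = "stack"
    else:
        raise ValueError("ingest: neither maps_dir nor stack_path configured")
    missing = [el for el in config.elements if el not in maps]
    if missing:
        manifest.warnings.append(f"ingest: elements without maps: {missing}")
    manifest.stages["ingest"] = {"source": source, "n_elements": len(maps)}
    return maps, stack


def _stage_align(config, manifest, maps):
    if not config.masks_path:
        raise ValueError("align: masks_path is required")
    mask = RegionMask.read(config.masks_path)
    grid = next(iter(maps.values())).shape
    if config.fiducials_path:
        fid = FiducialSet.read_csv(config.fiducials_path)
        tf = estimate_similarity(fid)
        report = check_alignment(tf, config.max_rms_px)
        if not report.passed:
            raise ValueError(
                f"align: fiducial rms {report.rms_residual:.2f} px exceeds "
                f"{config.max_rms_px} px"
            )
        mask = apply_transform(mask, tf, grid, config.pixel_size_nm)
        manifest.stages["align"] = {
            "rms_px": report.rms_residual,
            "scale": tf.scale,
            "rotation_rad": tf.rotation,
        }
    else:
        if mask.shape != grid:
            raise ValueError("align: mask grid differs from map grid and no fiducials given")
        manifest.stages["align"] = {"rms_px": 0.0, "identity": True}
    return mask


def _stage_compartments(config, manifest, maps, stack, mask):
    """CompartmentCounts per element x compartment (incl. nuclear reference)."""
    regions = {"nuclear_reference": contrast_mod.nuclear_reference_mask(mask)}
    for cls in CONTRAST_COMPARTMENTS:
        try:
            region = mask.boolean(cls)
        except KeyError:
            continue
        if region.any():
            regions[cls] = region

    counts: dict[tuple[str, str], contrast_mod.CompartmentCounts] = {}
    if stack is not None:
        detector = spectra_mod.DetectorModel()
        for name, region in regions.items():
            fit = spectra_mod.fit_spectrum(
                spectra_mod.sum_spectrum(stack, region), list(config.elements), detector
            )
            for el in config.elements:
                counts[(el, name)] = contrast_mod.CompartmentCounts(
                    element=el, S=max(fit.counts[el], 0.0),
                    sigma_S=max(fit.sigmas[el], 1e-9), N=int(region.sum()),
                    compartment=name, neuron_id=config.neuron_id,
                )
    else:
        for name, region in regions.items():
            for el in config.elements:
                if el not in maps:
                    continue
                counts[(el, name)] = contrast_mod.compartment_counts(
                    maps[el], region, name, config.neuron_id
                )
    manifest.stages["compartments"] = {
        "n_regions": len(regions), "n_measurements": len(counts)
    }
    return counts


def _stage_contrast(config, manifest, counts, out):
    results = []
    for (el, name), cc in counts.items():
        if name == "nuclear_reference":
            continue
        ref = counts.get((el, "nuclear_reference"))
        if ref is None or ref.S == 0:
            continue
        results.append(contrast_mod.delta(cc, ref))
    df = contrast_mod.contrast_table(results)
    df.to_csv(out / "contrasts.csv", index=False)
    manifest.stages["contrast"] = {"n_rows": len(df)}


def _stage_quantify(config, manifest, counts, out):
    if not config.standard_path:
        manifest.warnings.append(
            "quantify: no calibration standard configured; areal masses and "
            "ppm omitted (contrasts need no standard)"
        )
        log.warning("quantification skipped: no calibration standard")
        manifest.stages["quantify"] = {"skipped": True}
        return None
    standard = quantify_mod.CalibrationStandard.from_json(config.standard_path)
    rows = []
    compartments = sorted({name for (_, name) in counts})
    for name in compartments:
        si = counts.get(("Si", name))
        if si is None or si.S <= 0:
            manifest.warnings.append(f"quantify: no Si counts for {name}")
            continue
        for el in config.elements:
            if el == "Si" or (el, name) not in counts:
                continue
            am, eps = quantify_mod.areal_mass(counts[(el, name)].S, si.S, standard, el)
            rows.append(
                {
                    "element": el,
                    "compartment": name,
                    "neuron_id": config.neuron_id,
                    "am_ng_cm2": am,
                    "eps_ng_cm2": eps,
                    "eps_pct": 100.0 * eps / am if am > 0 else np.nan,
                    "c_ppm": quantify_mod.to_ppm(am, config.thickness_cm, config.density_g_cm3),
                }
            )
    pd.DataFrame(rows).to_csv(out / "areal_masses.csv", index=False)
    manifest.stages["quantify"] = {"n_rows": len(rows)}
    return standard


def _stage_granules(config, manifest, maps, mask, standard, out):
    if "Fe" not in maps or "S" not in maps:
        manifest.warnings.append("granules: Fe and S maps required; stage skipped")
        manifest.stages["granules"] = {"skipped": True}
        return
    try:
        cytoplasm = mask.boolean("cytoplasm")
    except KeyError:
        manifest.warnings.append("granules: no cytoplasm class in masks; stage skipped")
        manifest.stages["granules"] = {"skipped": True}
        return
    try:  # phantom truth masks carve granules out of the cytoplasm class
        cytoplasm = cytoplasm | mask.boolean("granule")
    except KeyError:
        pass
    labels, thresholds = granules_mod.detect_granules(
        maps["Fe"], maps["S"], cytoplasm,
        k=config.k_sigma, min_pixels=config.min_granule_pixels,
    )
    records = granules_mod.measure_granules(
        labels, maps, config.pixel_size_nm, cytoplasm,
        standard=standard, condition=config.condition, neuron_id=config.neuron_id,
    )
    granules_mod.records_table(records).to_csv(out / "granules.csv", index=False)
    summary = granules_mod.summarize(records, config.condition)
    pd.DataFrame([asdict(summary)]).to_csv(out / "granule_summary.csv", index=False)
    RegionMask(
        labels=labels.astype(np.uint16),
        class_table={int(l): f"granule_{l}" for l in np.unique(labels) if l > 0},
        pixel_size_nm=config.pixel_size_nm,
    ).write(out / "granule_labels.tif")
    manifest.stages["granules"] = {
        "n_granules": len(records), "thresholds": thresholds
    }


def simulate(
    output_dir: str | Path,
    condition: str = "ctrl",
    seed: int = 0,
    grid_shape: tuple[int, int] = (192, 192),
    pixel_size_nm: float = 50.0,
    with_spectra: bool = False,
    n_channels: int = 512,
) -> dict[str, Path]:
    """Write a phantom bundle in the formats :func:`run_full` reads.

    Produces per-element TIFF maps, the truth label mask, the granule
    truth table, a copy of the synthetic calibration standard, and
    optionally an HDF5 spectrum stack.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = phantom_mod.neuron_phantom_spec(
        condition=condition, grid_shape=grid_shape,
        pixel_size_nm=pixel_size_nm, seed=seed,
    )
    maps, truth = phantom_mod.generate_phantom(spec)
    paths = write_map_bundle(maps, out / "maps")
    truth.region_mask.write(out / "truth_masks.tif")
    truth.granule_table.to_csv(out / "truth_granules.csv", index=False)
    from importlib import resources

    std_text = resources.files("nanoxrf.data").joinpath("standard_synthetic.json").read_text()
    (out / "standard.json").write_text(std_text)
    result = {"maps": out / "maps", "masks": out / "truth_masks.tif",
              "standard": out / "standard.json"}
    if with_spectra:
        stack = phantom_mod.render_spectra(
            maps, spectra_mod.DetectorModel(), seed=seed, n_channels=n_channels
        )
        stack.write_h5(out / "stack.h5")
        result["stack"] = out / "stack.h5"
    return result
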