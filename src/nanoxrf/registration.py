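"""TEM-mask import and registration onto the XRF pixel grid.

Compartment and organelle masks are drawn by hand on TEM mosaics of a
section adjacent to the one scanned by XRF.  Because the two rasters
differ only by the mounting geometry and magnification, a similarity
transform (translation + rotation + isotropic scale, no reflection:
consecutive sections are same-handed) estimated from manually picked
fiducial point pairs suffices to carry the masks onto the XRF grid.
Labels are categorical, so resampling is nearest-neighbour.

Alignment quality is judged by the fiducial RMS residual; the pipeline
refuses registrations worse than 1 XRF pixel by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import transform as sktransform

__all__ = [
    "RegionMask",
    "FiducialSet",
    "SimilarityTransform",
    "AlignmentReport",
    "estimate_similarity",
    "apply_transform",
    "check_alignment",
]


@dataclass
class RegionMask:
    """Labeled raster naming compartment/organelle classes on a pixel grid.

    ``labels`` holds small non-negative integers; 0 is background.
    ``class_table`` maps each non-zero label to a class name such as
    ``"nucleus"``, ``"nucleolus"``, ``"perinuclear_rim"``,
    ``"cytoplasm"``, ``"neuropil"``, ``"mitochondria"``, ``"RER"``,
    ``"lipofuscin"`` or ``"granule"``.
    """

    labels: np.ndarray
    class_table: dict[int, str]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("RegionMask.labels must be 2-D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        self.class_table = {int(k): v for k, v in self.class_table.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.class_table)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from class_table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_of(self, class_name: str) -> int:
        for lbl, name in self.class_table.items():
            if name == class_name:
                return lbl
        raise KeyError(f"no class named {class_name!r}")

    def boolean(self, class_name: str) -> np.ndarray:
        """Boolean mask of one named class."""
        return self.labels == self.label_of(class_name)

    def class_names(self) -> list[str]:
        return [self.class_table[l] for l in sorted(self.class_table)]

    # ------------------------------------------------------------------ I/O
    def write(self, path: str | Path) -> Path:
        """Write as 8/16-bit label TIFF plus a JSON class-name table."""
        path = Path(path)
        dtype = np.uint8 if self.labels.max(initial=0) < 256 else np.uint16
        tifffile.imwrite(path, self.labels.astype(dtype))
        sidecar = {
            "pixel_size_nm": self.pixel_size_nm,
            "class_table": {str(k): v for k, v in self.class_table.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RegionMask":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            labels=np.asarray(tifffile.imread(path)),
            class_table={int(k): v for k, v in sidecar["class_table"].items()},
            pixel_size_nm=float(sidecar["pixel_size_nm"]),
        )


@dataclass
class FiducialSet:
    """Paired landmark coordinates in TEM (source) and XRF (destination).

    Coordinates are 0-based pixel positions, ``x`` = column, ``y`` = row.
    Angular features at cell boundaries, blood vessels or resin cracks
    serve as landmarks; at least two non-coincident pairs are required.
    """

    src: np.ndarray  # (n, 2) x, y
    dst: np.ndarray  # (n, 2) x, y

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src and dst must both be (n, 2)")
        if len(self.src) < 2:
            raise ValueError("need at least 2 fiducial pairs")
        if len(np.unique(self.src, axis=0)) != len(self.src):
            raise ValueError("duplicate source points")

    def __len__(self) -> int:
        return len(self.src)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(
            src=df[["src_x", "src_y"]].to_numpy(float),
            dst=df[["dst_x", "dst_y"]].to_numpy(float),
        )

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "src_x": self.src[:, 0],
                "src_y": self.src[:, 1],
                "dst_x": self.dst[:, 0],
                "dst_y": self.dst[:, 1],
            }
        ).to_csv(path, index=False)


@dataclass
class SimilarityTransform:
    """Estimated TEM -> XRF mapping: rotation, isotropic scale, translation."""

    scale: float
    rotation: float  # radians, counter-clockwise about the origin
    translation: tuple[float, float]  # (tx, ty) pixels
    rms_residual: float = 0.0
    residuals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    def _sk(self) -> sktransform.SimilarityTransform:
        return sktransform.SimilarityTransform(
            scale=self.scale, rotation=self.rotation, translation=self.translation
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) source (x, y) points into the destination frame."""
        return self._sk()(np.atleast_2d(np.asarray(points, dtype=float)))

    def inverse(self) -> "SimilarityTransform":
        inv = sktransform.SimilarityTransform(matrix=np.linalg.inv(self._sk().params))
        return SimilarityTransform(
            scale=float(inv.scale),
            rotation=float(inv.rotation),
            translation=(float(inv.translation[0]), float(inv.translation[1])),
            rms_residual=self.rms_residual,
        )


@dataclass
class AlignmentReport:
    passed: bool
    rms_residual: float
    max_rms: float
    per_fiducial: np.ndarray | None = None


def estimate_similarity(fiducials: FiducialSet) -> SimilarityTransform:
    """Least-squares similarity transform from fiducial pairs.

    Minimises the summed squared destination-frame residuals (Umeyama
    closed form, proper rotation only — reflections are excluded).

    Raises
    ------
    ValueError
        If all source points are coincident (degenerate fiducials).
    """
    src, dst = fiducials.src, fiducials.dst
    if np.allclose(src, src[0]):
        raise ValueError("degenerate fiducials: all source points coincident")
    try:
        tf = sktransform.SimilarityTransform.from_estimate(src, dst)
        ok = bool(tf)
    except AttributeError:  # scikit-image < 0.26
        tf = sktransform.SimilarityTransform()
        ok = tf.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tf.params)):
        raise ValueError("similarity estimation failed on the given fiducials")
    residuals = np.linalg.norm(tf(src) - dst, axis=1)
    return SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(tf.rotation),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        residuals=residuals,
    )


def apply_transform(
    mask: RegionMask,
    tf: SimilarityTransform,
    target_grid: tuple[int, int],
    target_pixel_size_nm: float | None = None,
) -> RegionMask:
    """Resample a label raster onto the destination (XRF) grid.

    Nearest-neighbour interpolation keeps labels categorical; pixels
    whose pre-image falls outside the source raster become background
    (0).
    """
    if not np.all(np.isfinite([tf.scale, tf.rotation, *tf.translation])):
        raise ValueError("transform parameters must be finite")
    # warp() maps output coords through inverse_map into the source image
    warped = sktransform.warp(
        mask.labels.astype(float),
        inverse_map=tf.inverse()._sk(),
        output_shape=target_grid,
        order=0,
        mode="constant",
        cval=0,
        preserve_range=True,
    )
    labels = np.rint(warped).astype(mask.labels.dtype)
    return RegionMask(
        labels=labels,
        class_table=dict(mask.class_table),
        pixel_size_nm=target_pixel_size_nm or mask.pixel_size_nm,
    )


def check_alignment(tf: SimilarityTransform, max_rms: float = 1.0) -> AlignmentReport:
    """Pass/fail the registration at a fiducial RMS threshold (pixels).

    The default of 1 pixel is the registration uncertainty the analysis
    budget assumes when masks are carried between adjacent sections.
    """
    return AlignmentReport(
        passed=tf.rms_residual <= max_rms,
        rms_residual=tf.rms_residual,
        max_rms=max_rms,
        per_fiducial=tf.residuals,
    )
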