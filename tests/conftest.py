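"""Shared fixtures: small parametric phantoms and detector models."""

from __future__ import annotations

import numpy as np
import pytest

from nanoxrf.phantom import Ellipse, FullField, GranuleSpec, PhantomSpec
from nanoxrf.spectra import DetectorModel


@pytest.fixture
def detector() -> DetectorModel:
    return DetectorModel()


def flat_spec(
    rates: dict[str, float],
    shape: tuple[int, int] = (100, 100),
    seed: int = 0,
    granules: GranuleSpec | None = None,
    cls: str = "cytoplasm",
) -> PhantomSpec:
    """Single-class phantom covering the whole grid."""
    return PhantomSpec(
        grid_shape=shape,
        pixel_size_nm=50.0,
        geometry=[FullField(cls)],
        composition={cls: dict(rates)},
        granules=granules,
        seed=seed,
    )


def nucleus_nucleolus_spec(
    nucleus_rates: dict[str, float],
    enrichment: dict[str, float],
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> PhantomSpec:
    """Nucleus filling the grid with an enriched nucleolar ellipse inside."""
    r0, c0 = shape[0] / 2.0, shape[1] / 2.0
    nucleolus = {el: r * enrichment.get(el, 1.0) for el, r in nucleus_rates.items()}
    return PhantomSpec(
        grid_shape=shape,
        pixel_size_nm=50.0,
        geometry=[FullField("nucleus"), Ellipse("nucleolus", (r0, c0), (20.0, 20.0))],
        composition={"nucleus": dict(nucleus_rates), "nucleolus": nucleolus},
        seed=seed,
    )


def assert_counts_match(observed: float, expected: float, sigma: float, k: float = 5.0):
    assert abs(observed - expected) <= k * sigma, (
        f"observed {observed:.3f} vs expected {expected:.3f} "
        f"(|diff| > {k} sigma = {k * sigma:.3f})"
    )
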