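"""Relative count-rate contrasts between compartments.

The elemental signal of a compartment *i* is compared with the nuclear
reference *n* through the relative count rate

    Delta_{i,n} = (S_i/N_i - S_n/N_n) / (S_n/N_n) = (S_i/S_n)(N_n/N_i) - 1

where S is the summed fitted counts of the element over the compartment
mask, sigma_S its uncertainty, and N the number of pixels.  The
propagated uncertainty is

    sigma_Delta = (Delta + 1) * sqrt((sigma_Si/S_i)^2 + (sigma_Sn/S_n)^2).

Per-neuron contrasts are aggregated across neurons only when their
relative uncertainty sigma_Delta/|Delta| is below 30% and at least
three measurements survive; the mean and the across-neuron SD are then
reported.  The nuclear reference is the nucleus mask with the nucleolus
and the P-rich perinuclear rim removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanoxrf.maps import ElementMap
from nanoxrf.registration import RegionMask

__all__ = [
    "CompartmentCounts",
    "ContrastResult",
    "AggregateContrast",
    "delta",
    "aggregate",
    "compartment_counts",
    "nuclear_reference_mask",
    "contrast_table",
]

MAX_RELATIVE_UNCERTAINTY = 0.30  # exclusion threshold sigma_Delta/|Delta|
MIN_REPLICATES = 3  # triplicate floor for reporting an average


@dataclass
class CompartmentCounts:
    """Summed counts of one element over one compartment of one neuron."""

    element: str
    S: float
    sigma_S: float
    N: int
    compartment: str
    neuron_id: str = ""

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be non-negative")
        if self.sigma_S <= 0:
            raise ValueError("sigma_S must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def rate(self) -> float:
        """Counts per pixel."""
        return self.S / self.N


@dataclass
class ContrastResult:
    element: str
    compartment: str
    reference: str
    delta: float
    sigma_delta: float | None  # None when undefined (S_i = 0)
    n_pixels: int = 0
    neuron_id: str = ""
    zero_signal: bool = False

    def __post_init__(self) -> None:
        if self.sigma_delta is not None and self.sigma_delta < 0:
            raise ValueError("sigma_delta must be non-negative")

    @property
    def relative_uncertainty(self) -> float | None:
        if self.sigma_delta is None or self.delta == 0:
            return None
        return self.sigma_delta / abs(self.delta)


@dataclass
class AggregateContrast:
    element: str
    compartment: str
    reference: str
    reportable: bool
    mean: float | None = None
    sd: float | None = None
    n_included: int = 0
    n_excluded: int = 0
    exclusion_reasons: list[str] = field(default_factory=list)


def delta(i: CompartmentCounts, n: CompartmentCounts) -> ContrastResult:
    """Contrast of compartment ``i`` against the nuclear reference ``n``.

    Raises
    ------
    ValueError
        If the reference has zero counts (the ratio is undefined).

    Notes
    -----
    ``S_i = 0`` returns ``delta = -1`` flagged ``zero_signal`` with
    ``sigma_delta`` missing: the relative-uncertainty formula divides
    by ``S_i`` and is undefined there.
    """
    if i.element != n.element:
        raise ValueError("compartment and reference measure different elements")
    if n.S == 0:
        raise ValueError("reference compartment has zero counts")
    d = (i.S / n.S) * (n.N / i.N) - 1.0
    if i.S == 0:
        return ContrastResult(
            element=i.element,
            compartment=i.compartment,
            reference=n.compartment,
            delta=-1.0,
            sigma_delta=None,
            n_pixels=i.N,
            neuron_id=i.neuron_id,
            zero_signal=True,
        )
    sigma = (d + 1.0) * np.sqrt((i.sigma_S / i.S) ** 2 + (n.sigma_S / n.S) ** 2)
    return ContrastResult(
        element=i.element,
        compartment=i.compartment,
        reference=n.compartment,
        delta=float(d),
        sigma_delta=float(sigma),
        n_pixels=i.N,
        neuron_id=i.neuron_id,
    )


def aggregate(
    results: list[ContrastResult],
    max_relative_uncertainty: float = MAX_RELATIVE_UNCERTAINTY,
    min_replicates: int = MIN_REPLICATES,
) -> AggregateContrast:
    """Across-neuron mean +/- SD of contrasts, under the filtering rules.

    A measurement enters the average only if its relative uncertainty
    ``sigma_Delta/|Delta|`` is strictly below ``max_relative_uncertainty``
    (missing ``sigma_Delta`` excludes it).  If fewer than
    ``min_replicates`` survive, the aggregate is marked not reportable.
    """
    if not results:
        return AggregateContrast(
            element="", compartment="", reference="", reportable=False,
            exclusion_reasons=["no measurements"],
        )
    keys = {(r.element, r.compartment, r.reference) for r in results}
    if len(keys) > 1:
        raise ValueError(f"mixed element/compartment pairs in aggregate: {sorted(keys)}")
    element, compartment, reference = next(iter(keys))

    included, reasons = [], []
    for r in results:
        if r.sigma_delta is None:
            reasons.append(f"{r.neuron_id or '?'}: sigma_delta undefined")
        elif r.delta == 0 or r.sigma_delta / abs(r.delta) >= max_relative_uncertainty:
            reasons.append(
                f"{r.neuron_id or '?'}: relative uncertainty >= "
                f"{max_relative_uncertainty:.0%}"
            )
        else:
            included.append(r.delta)

    if len(included) < min_replicates:
        return AggregateContrast(
            element=element, compartment=compartment, reference=reference,
            reportable=False, n_included=len(included),
            n_excluded=len(results) - len(included), exclusion_reasons=reasons,
        )
    arr = np.asarray(included)
    return AggregateContrast(
        element=element, compartment=compartment, reference=reference,
        reportable=True, mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
        n_included=len(arr), n_excluded=len(results) - len(arr),
        exclusion_reasons=reasons,
    )


def nuclear_reference_mask(mask: RegionMask) -> np.ndarray:
    """Boolean nuclear reference: nucleus minus nucleolus and perinuclear rim.

    The reference compartment is the main body of the nucleus excluding
    the nucleolus and the P-rich perinuclear region, which carry their
    own distinct compositions.
    """
    ref = mask.boolean("nucleus")
    for cls in ("nucleolus", "perinuclear_rim"):
        try:
            ref = ref & ~mask.boolean(cls)
        except KeyError:
            continue
    if not ref.any():
        raise ValueError("nuclear reference mask is empty")
    return ref


def compartment_counts(
    emap: ElementMap,
    region: np.ndarray,
    compartment: str,
    neuron_id: str = "",
) -> CompartmentCounts:
    """Sum an element map over a boolean region into a CompartmentCounts.

    The uncertainty source is declared by the map: a fit-derived
    per-pixel sigma raster when present, otherwise the Poisson
    ``sqrt(S)`` of raw integrated counts.
    """
    s, sigma = emap.region_sum(region)
    if sigma <= 0:  # zero-count region: floor at the one-count Poisson sigma
        sigma = float(np.sqrt(max(s, 1.0)))
    return CompartmentCounts(
        element=emap.element,
        S=s,
        sigma_S=sigma,
        N=int(np.asarray(region, bool).sum()),
        compartment=compartment,
        neuron_id=neuron_id,
    )


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Tidy per-measurement contrast table (one row per neuron/element/pair)."""
    rows = []
    for r in results:
        rel = r.relative_uncertainty
        included = rel is not None and rel < MAX_RELATIVE_UNCERTAINTY
        rows.append(
            {
                "element": r.element,
                "compartment": r.compartment,
                "reference": r.reference,
                "delta": r.delta,
                "sigma_delta": r.sigma_delta,
                "n_pixels": r.n_pixels,
                "neuron_id": r.neuron_id,
                "included_flag": included,
                "exclusion_reason": (
                    "" if included else
                    "sigma_delta undefined" if r.sigma_delta is None else
                    "relative uncertainty >= 30%"
                ),
            }
        )
    return pd.DataFrame(rows)
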