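"""Published per-compartment reference measurements.

A compact table of elemental areal masses (ng/cm^2), concentrations
(ppm) and relative uncertainties (%) reported for Fe, Ca, S and P in
the nucleus, nucleolus, cytoplasm and the pooled Fe/S-rich granules of
nigral neuron bodies, for a control and an alpha-synuclein
overexpressing condition (two neurons each).  Ships with the package
so that the concentration conversion and the stated inter-compartment
ranges can be checked without beamline data; granule rows carry no ppm
(none was reported for the pooled-granule column).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "element_range"]


def load_reference_table() -> pd.DataFrame:
    """Reference table as a tidy DataFrame.

    Columns: condition (CTRL | ASYN), neuron (1 | 2), compartment,
    element, am_ng_cm2, c_ppm (NaN for granule rows), eps_pct.
    """
    with resources.files("nanoxrf.data").joinpath("reference_compartments.csv").open() as fh:
        return pd.read_csv(fh)


def element_range(
    df: pd.DataFrame,
    element: str,
    compartments: tuple[str, ...] = ("nucleus", "nucleolus", "cytoplasm"),
) -> tuple[float, float]:
    """Min–max areal mass of one element across the given compartments."""
    sel = df[(df.element == element) & (df.compartment.isin(compartments))]
    if sel.empty:
        raise ValueError(f"no rows for element {element!r}")
    return float(sel.am_ng_cm2.min()), float(sel.am_ng_cm2.max())
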