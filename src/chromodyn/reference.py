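"""Reference constants for the MeCP2 MBD mutant panel.

Per-construct reported kinetic parameters (recovery half-time in seconds
and mobile fraction normalized to one), median DAPI-GFP Pearson
coefficients, and the packaged clinical severity score (CSS) table for the
hemizygous male cases.  These are inputs to the analysis (e.g. to
parameterize simulations of a given construct), not outputs of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "FrapReference",
    "FRAP_REFERENCE",
    "PCC_MEDIAN",
    "load_css_table",
]


@dataclass(frozen=True)
class FrapReference:
    t_half_s: float
    t_half_sd: float
    mobile_fraction: float
    mobile_fraction_sd: float
    r_squared: float


FRAP_REFERENCE: dict[str, FrapReference] = {
    "WT": FrapReference(64.16, 23.11, 0.59, 0.07, 0.992),
    "P152A": FrapReference(52.61, 2.27, 0.61, 0.15, 0.99),
    "P152H": FrapReference(42.35, 23.79, 0.56, 0.16, 0.976),
    "P152R": FrapReference(12.44, 3.86, 0.69, 0.13, 0.8),
    "T158M": FrapReference(12.74, 16.76, 0.79, 0.12, 0.948),
    "R111G": FrapReference(15.85, 8.1, 0.92, 0.09, 0.674),
    "PP390-91del": FrapReference(50.86, 22.69, 0.69, 0.23, 0.982),
}

# Median per-construct DAPI-GFP Pearson coefficients.
PCC_MEDIAN: dict[str, float] = {
    "R111G": 0.26,
    "R106W": 0.40,
    "R133L": 0.46,
    "T158M": 0.57,
    "P152R": 0.68,
    "F157I": 0.69,
    "P152H": 0.71,
    "P152A": 0.72,
    "N126I": 0.72,
    "R133C": 0.82,
    "R167W": 0.81,
}


def load_css_table() -> pd.DataFrame:
    """Packaged per-participant clinical severity scores
    (columns: mutation, case_id, css, note)."""
    with resources.files("chromodyn").joinpath("data/css_clinical.csv").open() as fh:
        return pd.read_csv(fh)
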