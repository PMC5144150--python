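"""DAPI-GFP co-localization: per-nucleus Pearson coefficient, band
classification, and binding/clustering pattern calls.

The classification bands follow the fixed convention used for scoring
construct localization: r_p >= 0.6 positive co-localization, 0.5 < r_p <
0.6 weak positive, r_p <= 0.5 no or negligible co-localization.  Combined
with the morphometric comparison against wild type, each construct falls
into one of four binding/clustering patterns: normal, impaired clustering
(protein localizes but chromocenters are more numerous and smaller),
abolished clustering, or abolished binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import NucleusMask

__all__ = [
    "ColocalizationResult",
    "pearson_coloc",
    "classify_localization",
    "classify_binding_pattern",
    "BAND_NEGLIGIBLE_MAX",
    "BAND_POSITIVE_MIN",
]

BAND_NEGLIGIBLE_MAX = 0.5   # r_p <= 0.5 -> no/negligible co-localization
BAND_POSITIVE_MIN = 0.6     # r_p >= 0.6 -> positive co-localization

CATEGORIES = ("positive", "weak_positive", "negligible")
PATTERNS = ("normal", "impaired_clustering", "abolished_clustering",
            "abolished_binding")


@dataclass
class ColocalizationResult:
    nucleus_label: int
    r_p: float | None
    category: str | None
    pattern: str | None = None


def pearson_coloc(channel_a: np.ndarray, channel_b: np.ndarray,
                  mask: NucleusMask | np.ndarray | None = None) -> float:
    """Sample Pearson correlation of two channels over masked pixels.

    ``mask`` may be a :class:`NucleusMask`, a boolean array, or ``None``
    (all pixels).  Returns NaN with a warning if either channel has zero
    variance within the mask.
    """
    a = np.asarray(channel_a, dtype=np.float64)
    b = np.asarray(channel_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    if mask is not None:
        m = mask.mask if isinstance(mask, NucleusMask) else np.asarray(mask, bool)
        a = a[m]
        b = b[m]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 3:
        raise ValueError("need at least 3 pixels for a correlation")
    ac = a - a.mean()
    bc = b - b.mean()
    va = ac @ ac
    vb = bc @ bc
    if va == 0 or vb == 0:
        warnings.warn("zero variance in a channel: Pearson undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((ac @ bc) / np.sqrt(va * vb))


def classify_localization(r_p: float | None) -> str | None:
    """Map a Pearson coefficient to its co-localization band."""
    if r_p is None or (isinstance(r_p, float) and np.isnan(r_p)):
        return None
    if not -1.0 <= r_p <= 1.0:
        raise ValueError("r_p must be in [-1, 1]")
    if r_p >= BAND_POSITIVE_MIN:
        return "positive"
    if r_p > BAND_NEGLIGIBLE_MAX:
        return "weak_positive"
    return "negligible"


def classify_binding_pattern(
    r_p: float,
    cn_significant_increase: bool = False,
    cs_significant_decrease: bool = False,
    identifiable_chromocenters: bool = True,
    cn_significant_decrease: bool = False,
    borderline_margin: float = 0.02,
) -> tuple[str, bool]:
    """Assign one of the four binding/clustering patterns.

    Returns ``(pattern, borderline)`` where ``borderline`` flags an r_p
    within ``borderline_margin`` of a band edge, so callers can surface
    calls like an r_p of 0.57 that sits close to the weak/positive cut.
    """
    if not -1.0 <= r_p <= 1.0:
        raise ValueError("r_p must be in [-1, 1]")
    if cn_significant_increase and cn_significant_decrease:
        raise ValueError("contradictory CN flags: increase and decrease both set")

    borderline = (
        abs(r_p - BAND_NEGLIGIBLE_MAX) <= borderline_margin
        or abs(r_p - BAND_POSITIVE_MIN) <= borderline_margin
    )
    if r_p <= BAND_NEGLIGIBLE_MAX or (
        not identifiable_chromocenters and r_p < BAND_POSITIVE_MIN
    ):
        return "abolished_binding", borderline
    if r_p < BAND_POSITIVE_MIN:
        return "abolished_clustering", borderline
    if cn_significant_increase and cs_significant_decrease:
        return "impaired_clustering", borderline
    return "normal", borderline
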