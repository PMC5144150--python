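"""FRAP normalization and recovery-curve fitting.

Traces are normalized in the two-step scheme standard for confocal FRAP:
background subtraction, then *double normalization* against the whole-cell
ROI to cancel acquisition photobleaching,

    I_dn(t) = (T_pre / T(t)) * (I(t) / I_pre),

followed by *full-scale normalization* anchoring the first post-bleach
frame at 0 and the pre-bleach plateau at 1,

    I_fs(t) = (I_dn(t) - I_dn(t_bleach)) / (1 - I_dn(t_bleach)).

Post-bleach recovery is fitted by nonlinear least squares to a single
(default) or double exponential association; the fitted amplitude is the
mobile fraction (normalized to one) and the half-time solves
f(t_half) = f(inf)/2 (ln 2 / k for the single exponential).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .morphometry import TestResult, mann_whitney_u
from .synthetic import FrapTrace

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedTrace",
    "FrapFit",
    "normalize_trace",
    "full_scale",
    "fit_recovery",
    "summarize_constructs",
]


@dataclass
class NormalizedTrace:
    """Full-scale normalized recovery series; ``tau_s`` counts from the
    first post-bleach frame (t = 0 at the bleach event)."""

    time_s: np.ndarray
    i_dn: np.ndarray
    i_fs: np.ndarray
    bleach_frame: int
    construct: str = ""

    @property
    def tau_s(self) -> np.ndarray:
        t = self.time_s[self.bleach_frame:]
        return t - t[0]

    @property
    def post(self) -> np.ndarray:
        return self.i_fs[self.bleach_frame:]


@dataclass
class FrapFit:
    model: str                    # "single_exp" | "double_exp"
    t_half_s: float
    mobile_fraction: float
    r_squared: float
    params: dict = field(default_factory=dict)
    construct: str = ""


def full_scale(series: np.ndarray, bleach_index: int) -> np.ndarray:
    """Anchor a series at 0 on its ``bleach_index`` frame and 1 on its
    pre-bleach mean.  Idempotent: applying it twice equals applying once."""
    series = np.asarray(series, dtype=float)
    i0 = series[bleach_index]
    pre = series[:bleach_index].mean()
    if pre == i0:
        raise ValueError("no bleach depth: pre-bleach mean equals bleach value")
    return (series - i0) / (pre - i0)


def normalize_trace(trace: FrapTrace, min_pre: int = 5) -> NormalizedTrace:
    """Background-subtract, double-normalize and full-scale-normalize a raw
    FRAP trace.

    Requires at least ``min_pre`` pre-bleach frames.  Negative intensities
    after background subtraction are clipped to zero with a warning.  A
    trace with no bleach depth (I_dn at the bleach frame >= 1) is rejected.
    """
    nb = trace.bleach_frame
    if nb < min_pre:
        raise ValueError(f"need >= {min_pre} pre-bleach frames, got {nb}")
    bg = float(np.mean(trace.roi_background))
    i = np.asarray(trace.roi_bleach, dtype=float) - bg
    t = np.asarray(trace.roi_cell, dtype=float) - bg
    if (i < 0).any() or (t < 0).any():
        warnings.warn("negative intensities after background subtraction; "
                      "clipping to 0", RuntimeWarning, stacklevel=2)
        i = np.clip(i, 0, None)
        t = np.clip(t, 0, None)
    i_pre = i[:nb].mean()
    t_pre = t[:nb].mean()
    if i_pre <= 0 or t_pre <= 0 or (t <= 0).any():
        raise ValueError("non-positive ROI intensities; cannot normalize")
    i_dn = (t_pre / t) * (i / i_pre)
    if i_dn[nb] >= 1.0:
        raise ValueError("no bleach depth at the bleach frame")
    i_fs = (i_dn - i_dn[nb]) / (1.0 - i_dn[nb])
    return NormalizedTrace(
        time_s=np.asarray(trace.time_s, dtype=float),
        i_dn=i_dn,
        i_fs=i_fs,
        bleach_frame=nb,
        construct=trace.construct,
    )


# Both models carry a small free baseline offset b: the full-scale anchor
# is a single (noisy) frame, so every other point shares its error as a
# common offset, which would otherwise be absorbed into the rate.
def _single(t, a, k, b=0.0):
    return b + a * (1.0 - np.exp(-k * t))


def _double(t, a1, k1, a2, k2, b=0.0):
    return b + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def _fit_single(tau, y):
    a0 = float(np.mean(y[-max(1, y.size // 10):]))
    a0 = min(max(a0, 1e-3), 1.5)
    half_level = a0 / 2.0
    above = np.nonzero(y >= half_level)[0]
    t_half0 = tau[above[0]] if above.size and tau[above[0]] > 0 else tau[-1] / 4
    k0_base = math.log(2.0) / max(t_half0, tau[1] if tau.size > 1 else 1.0)
    best = None
    for mult in (0.1, 1.0, 10.0):
        try:
            popt, _ = curve_fit(
                _single, tau, y, p0=[a0, k0_base * mult, 0.0],
                bounds=([0.0, 1e-8, -0.5], [2.0, np.inf, 0.5]), maxfev=10000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _single(tau, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise RuntimeError("single-exponential fit did not converge "
                           "(multi-start exhausted)")
    return best[0]


def _fit_double(tau, y, single_popt):
    a, k, b = single_popt
    best = None
    for split in (0.3, 0.5, 0.7):
        p0 = [a * split, k * 3.0, a * (1 - split), k / 3.0, b]
        try:
            popt, _ = curve_fit(
                _double, tau, y, p0=p0,
                bounds=([0, 1e-8, 0, 1e-8, -0.5],
                        [2, np.inf, 2, np.inf, 0.5]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _double(tau, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    return None if best is None else best[0]


def fit_recovery(normalized: NormalizedTrace, model: str = "single_exp",
                 min_post: int = 20) -> FrapFit:
    """Fit the post-bleach portion of a full-scale normalized trace.

    ``model`` is ``"single_exp"``, ``"double_exp"`` or ``"auto"`` (prefer
    the single exponential; adopt the double only if it improves adjusted
    R^2 by more than 0.01).  Warns on fitted amplitudes above 1.1
    (super-recovery, usually a normalization problem).
    """
    tau = normalized.tau_s
    y = normalized.post
    if y.size < min_post:
        raise ValueError(f"need >= {min_post} post-bleach points, got {y.size}")

    sp = _fit_single(tau, y)
    yhat_s = _single(tau, *sp)
    r2_s = _r2(y, yhat_s)

    chosen = "single_exp"
    popt = sp
    r2 = r2_s
    if model in ("double_exp", "auto"):
        dp = _fit_double(tau, y, sp)
        if dp is not None:
            r2_d = _r2(y, _double(tau, *dp))
            n = y.size
            adj_s = 1 - (1 - r2_s) * (n - 1) / (n - 3)
            adj_d = 1 - (1 - r2_d) * (n - 1) / (n - 5)
            if model == "double_exp" or adj_d - adj_s > 0.01:
                chosen, popt, r2 = "double_exp", dp, r2_d
        elif model == "double_exp":
            raise RuntimeError("double-exponential fit did not converge")

    if chosen == "single_exp":
        a, k, b = popt
        mobile = float(a)
        t_half = math.log(2.0) / k
        params = {"A": float(a), "k": float(k), "b": float(b)}
    else:
        a1, k1, a2, k2, b = popt
        mobile = float(a1 + a2)
        target = mobile / 2.0
        # half-time measured relative to the fitted baseline
        f = lambda t: _double(t, a1, k1, a2, k2) - b - target  # noqa: E731
        hi = 10.0 / min(k1, k2)
        t_half = float(brentq(f, 1e-12, hi))
        params = {"A1": float(a1), "k1": float(k1),
                  "A2": float(a2), "k2": float(k2), "b": float(b)}

    if mobile > 1.1:
        warnings.warn(f"fitted mobile fraction {mobile:.3f} > 1.1 "
                      "(super-recovery)", RuntimeWarning, stacklevel=2)
    return FrapFit(model=chosen, t_half_s=float(t_half),
                   mobile_fraction=mobile, r_squared=float(r2),
                   params=params, construct=normalized.construct)


def summarize_constructs(fits: dict[str, list[FrapFit]],
                         wt: str = "WT") -> pd.DataFrame:
    """Per-construct mean +/- sd of t_half and mobile fraction with
    two-tailed Mann-Whitney tests against the wild-type group.

    Groups of a single fit are excluded with a warning.  If the wild-type
    group is absent (or excluded) the vs-WT columns are left missing.
    """
    groups = {}
    for name, group in fits.items():
        if len(group) < 2:
            logger.warning("construct %s has <2 fits; excluded", name)
            continue
        groups[name] = group
    rows = []
    wt_group = groups.get(wt)
    for name, group in groups.items():
        th = np.array([f.t_half_s for f in group])
        mf = np.array([f.mobile_fraction for f in group])
        r2 = np.array([f.r_squared for f in group])
        row = {
            "construct": name,
            "n": len(group),
            "mean_t_half": th.mean(), "sd_t_half": th.std(ddof=1),
            "mean_mobile_fraction": mf.mean(), "sd_mobile_fraction": mf.std(ddof=1),
            "mean_r2": r2.mean(),
            "p_t_half_vs_wt": np.nan,
            "p_mobile_vs_wt": np.nan,
        }
        if wt_group is not None and name != wt:
            wt_th = [f.t_half_s for f in wt_group]
            wt_mf = [f.mobile_fraction for f in wt_group]
            row["p_t_half_vs_wt"] = mann_whitney_u(th, wt_th).p_two_sided
            row["p_mobile_vs_wt"] = mann_whitney_u(mf, wt_mf).p_two_sided
        rows.append(row)
    return pd.DataFrame(rows)
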