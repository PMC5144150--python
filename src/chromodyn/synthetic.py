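"""Synthetic microscopy scenes and FRAP traces with known ground truth.

The generators emulate the statistical structure of the real experiments —
DAPI-stained nuclei containing bright heterochromatin chromocenters, a GFP
channel whose relationship to the DAPI spots encodes the co-localization
state of the expressed construct, and fluorescence-recovery time series
following a single-exponential binding model — so that every downstream
stage (segmentation, co-localization, morphometry, kinetics, severity) can
be exercised against a sidecar of known truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SceneParams",
    "FrapSimParams",
    "ImageScene",
    "FrapTrace",
    "generate_nucleus_image",
    "generate_correlated_pair",
    "generate_frap_trace",
    "sample_morphometry",
]

COLOC_MODES = ("colocalized", "partial", "diffuse_mislocalized")

# Rendering levels on a [0, 1] intensity scale (arbitrary units).
_NUCLEOPLASM_DAPI = 0.30
_SPOT_AMPLITUDE_DAPI = 0.70
_NUCLEOPLASM_GFP = 0.15
_SPOT_AMPLITUDE_GFP = 0.75
_DIFFUSE_GFP = 0.50


@dataclass(frozen=True)
class SceneParams:
    """Parameters for a synthetic two-channel nucleus scene.

    Defaults describe a C2C12-like interphase nucleus: ~15 chromocenters of
    ~1 um diameter (radius 5 px at 0.1 um/px) inside an elliptical nucleus
    of semi-axes 60 x 45 px (12 x 9 um).
    """

    n_nuclei: int = 1
    chromocenters_mean: float = 15.0
    chromocenters_sd: float = 3.0
    radius_mean_px: float = 5.0
    radius_sd_px: float = 0.8
    coloc_mode: str = "colocalized"
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    nucleus_axes_px: tuple[float, float] = (70.0, 55.0)
    tile_px: int = 180
    # Minimum centre-to-centre distance between spots, in units of the sum
    # of the two spot sigmas; 3 keeps truncated footprints disjoint.
    separation_sigma: float = 3.0
    partial_fraction: float = 0.5
    nucleus_overlap: float = 0.0
    # A diffuse (unbound) GFP pool is never optically flat; it carries mild
    # spatial texture independent of the chromocenters, without which the
    # correlation with DAPI would be degenerate on noiseless scenes.
    diffuse_texture_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.chromocenters_mean < 0 or self.chromocenters_sd < 0:
            raise ValueError("chromocenter count distribution must be >= 0")
        if self.radius_mean_px <= 0:
            raise ValueError("chromocenter radius must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coloc_mode not in COLOC_MODES:
            raise ValueError(f"coloc_mode must be one of {COLOC_MODES}")
        if self.tile_px <= 0:
            raise ValueError("image dimensions must be positive")
        a, b = self.nucleus_axes_px
        if self.radius_mean_px * 1.5 >= min(a, b):
            raise ValueError("chromocenter radius larger than nucleus")


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters for a simulated FRAP experiment.

    The acquisition defaults (25 pre-bleach frames, 200 post-bleach frames
    at 108.784 ms per frame) mirror a confocal time-lapse protocol; the
    bleach pulse (~200 us, far shorter than a frame) is modelled as an
    instantaneous event between frames ``n_pre - 1`` and ``n_pre``.
    Recovery follows I(t) = (1-depth) + depth*mf*(1 - exp(-ln2 * t/t_half)).
    """

    mobile_fraction: float = 0.59
    t_half_s: float = 64.16
    bleach_depth: float = 0.8
    n_pre: int = 25
    n_post: int = 200
    dt_s: float = 0.108784
    acquisition_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    background_level: float = 0.0
    cell_level: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be > 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1] (a zero-depth "
                             "bleach is not a bleach event)")
        if self.n_pre < 1 or self.n_post < 1 or self.dt_s <= 0:
            raise ValueError("frame counts must be >= 1 and dt_s > 0")
        if self.acquisition_bleach_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")

    @property
    def rate_k(self) -> float:
        """Recovery rate constant k = ln(2) / t_half."""
        return math.log(2.0) / self.t_half_s


@dataclass
class ImageScene:
    """A rendered two-channel scene plus its ground-truth sidecar."""

    dapi: np.ndarray
    gfp: np.ndarray
    sidecar: dict

    @property
    def n_true_spots(self) -> int:
        return sum(len(n["spots"]) for n in self.sidecar["nuclei"])


@dataclass
class FrapTrace:
    """Raw FRAP ROI intensity series.

    ``bleach_frame`` is the index of the first post-bleach frame.
    """

    frame: np.ndarray
    time_s: np.ndarray
    roi_bleach: np.ndarray
    roi_cell: np.ndarray
    roi_background: np.ndarray
    bleach_frame: int
    construct: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame,
                "time_s": self.time_s,
                "roi_bleach": self.roi_bleach,
                "roi_cell": self.roi_cell,
                "roi_background": self.roi_background,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bleach_frame: int | None = None,
                 construct: str = "") -> "FrapTrace":
        import pandas as pd

        df = pd.read_csv(path)
        if bleach_frame is None:
            # Largest single-frame drop in the bleach ROI marks the event.
            bleach_frame = int(np.argmin(np.diff(df["roi_bleach"].to_numpy())) + 1)
        return cls(
            frame=df["frame"].to_numpy(),
            time_s=df["time_s"].to_numpy(),
            roi_bleach=df["roi_bleach"].to_numpy(),
            roi_cell=df["roi_cell"].to_numpy(),
            roi_background=df["roi_background"].to_numpy(),
            bleach_frame=bleach_frame,
            construct=construct,
        )


def _place_spots(rng, n_spots, axes, separation_sigma, radius_mean, radius_sd,
                 n_restarts: int = 50):
    """Rejection-sample spot centres inside an ellipse with a minimum
    pairwise separation; returns (centres, radii) in nucleus-local coords.

    Sequential placement can jam by bad luck well below the packing limit,
    so the whole layout is restarted (deterministically, from the same
    generator stream) up to ``n_restarts`` times before giving up.
    """
    last_err = None
    for _restart in range(n_restarts):
        try:
            return _place_spots_once(rng, n_spots, axes, separation_sigma,
                                     radius_mean, radius_sd)
        except ValueError as err:
            last_err = err
    raise last_err


def _place_spots_once(rng, n_spots, axes, separation_sigma, radius_mean,
                      radius_sd):
    a, b = axes
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_spots):
        r = max(1.0, rng.normal(radius_mean, radius_sd))
        sigma = r / 2.0
        placed = False
        for _attempt in range(500):
            # sample uniformly in the shrunken ellipse that keeps the
            # truncated (3 sigma) footprint inside the nucleus
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1.0:
                continue
            x = u * (a - 3.0 * sigma)
            y = v * (b - 3.0 * sigma)
            ok = True
            for (cx, cy), cr in zip(centres, radii):
                min_d = separation_sigma * (sigma + cr / 2.0)
                if (x - cx) ** 2 + (y - cy) ** 2 < min_d**2:
                    ok = False
                    break
            if ok:
                centres.append((x, y))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_spots} spots of radius ~{radius_mean} "
                f"in a nucleus of axes {axes}; reduce count or size"
            )
    return centres, radii


def _render_spot(canvas, cx, cy, sigma, amplitude):
    """Add a truncated (3 sigma) isotropic Gaussian spot in place and
    return the number of pixels inside the truncation footprint."""
    h, w = canvas.shape
    rad = 3.0 * sigma
    x0, x1 = int(math.floor(cx - rad)), int(math.ceil(cx + rad)) + 1
    y0, y1 = int(math.floor(cy - rad)), int(math.ceil(cy + rad)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    inside = d2 <= rad * rad
    patch = np.where(inside, amplitude * np.exp(-d2 / (2.0 * sigma * sigma)), 0.0)
    canvas[y0:y1, x0:x1] += patch
    return int(inside.sum())


def generate_nucleus_image(params: SceneParams) -> ImageScene:
    """Render a two-channel (DAPI, GFP) scene of elliptical nuclei with
    Gaussian-profile chromocenter spots and a ground-truth sidecar.

    The GFP channel depends on ``coloc_mode``:

    - ``colocalized``: GFP spot signal proportional to the DAPI spot signal
      (plus a dim nucleoplasmic pool);
    - ``partial``: proportional signal on a random subset of spots plus a
      brighter diffuse pool;
    - ``diffuse_mislocalized``: uniform nuclear GFP, independent of the
      chromocenters.
    """
    rng = np.random.default_rng(params.seed)
    a, b = params.nucleus_axes_px
    tile = params.tile_px
    if 2 * a >= tile or 2 * b >= tile:
        raise ValueError("nucleus does not fit in tile; increase tile_px")

    n_cols = int(math.ceil(math.sqrt(max(params.n_nuclei, 1))))
    n_rows = int(math.ceil(max(params.n_nuclei, 1) / n_cols))
    h, w = n_rows * tile, n_cols * tile
    dapi = np.zeros((h, w), dtype=np.float64)
    gfp = np.zeros((h, w), dtype=np.float64)

    nuclei_truth = []
    for i in range(params.n_nuclei):
        row, col = divmod(i, n_cols)
        # jitter the nucleus inside its tile, optionally letting neighbours
        # overlap by shifting toward the shared edge
        max_jx = (tile / 2.0 - a) * (1.0 + params.nucleus_overlap)
        max_jy = (tile / 2.0 - b) * (1.0 + params.nucleus_overlap)
        cx = col * tile + tile / 2.0 + rng.uniform(-max_jx, max_jx)
        cy = row * tile + tile / 2.0 + rng.uniform(-max_jy, max_jy)

        yy, xx = np.mgrid[0:h, 0:w]
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        dapi[inside] = np.maximum(dapi[inside], _NUCLEOPLASM_DAPI)

        n_spots = max(0, int(round(rng.normal(params.chromocenters_mean,
                                              params.chromocenters_sd))))
        centres, radii = _place_spots(
            rng, n_spots, (a, b), params.separation_sigma,
            params.radius_mean_px, params.radius_sd_px,
        )

        if params.coloc_mode == "partial" and n_spots > 0:
            n_on = max(1, int(round(params.partial_fraction * n_spots)))
            on = set(rng.choice(n_spots, size=n_on, replace=False).tolist())
        else:
            on = set(range(n_spots))

        spots_truth = []
        for j, ((sx, sy), r) in enumerate(zip(centres, radii)):
            sigma = r / 2.0
            foot = _render_spot(dapi, cx + sx, cy + sy, sigma,
                                _SPOT_AMPLITUDE_DAPI)
            if params.coloc_mode == "colocalized" and j in on:
                _render_spot(gfp, cx + sx, cy + sy, sigma, _SPOT_AMPLITUDE_GFP)
            elif params.coloc_mode == "partial" and j in on:
                _render_spot(gfp, cx + sx, cy + sy, sigma, _SPOT_AMPLITUDE_GFP)
            spots_truth.append(
                {
                    "center_xy": (cx + sx, cy + sy),
                    "radius_px": r,
                    "sigma_px": sigma,
                    "area_px2": math.pi * r * r,
                    "footprint_px": foot,
                }
            )

        n_in = int(inside.sum())
        if params.coloc_mode == "colocalized":
            gfp[inside] += _NUCLEOPLASM_GFP
        elif params.coloc_mode == "partial":
            pool = _DIFFUSE_GFP * 0.7
            gfp[inside] += pool + rng.normal(0, params.diffuse_texture_sd, n_in)
        else:  # diffuse_mislocalized: textured pool, independent of spots
            gfp[inside] += _DIFFUSE_GFP + rng.normal(
                0, params.diffuse_texture_sd, n_in)

        nuclei_truth.append(
            {
                "center_xy": (cx, cy),
                "axes_px": (a, b),
                "area_px2": math.pi * a * b,
                "spots": spots_truth,
            }
        )

    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, params.noise_sd, size=dapi.shape)
        gfp = gfp + rng.normal(0.0, params.noise_sd, size=gfp.shape)

    sidecar = {
        "coloc_mode": params.coloc_mode,
        "seed": params.seed,
        "pixel_size_um": params.pixel_size_um,
        "params": asdict(params),
        "nuclei": nuclei_truth,
    }
    return ImageScene(dapi=dapi, gfp=gfp, sidecar=sidecar)


def generate_correlated_pair(target_r: float, n_pixels: int, seed: int = 0):
    """Construct paired pixel vectors with sample Pearson correlation equal
    to ``target_r`` by exact orthogonalization.

    Draw ``a`` and an independent noise vector, orthogonalize the noise
    against ``a`` in the centred inner product, standardize both, and set
    ``b = r * a_hat + sqrt(1 - r^2) * n_hat``.  The sample correlation of
    the returned pair equals ``target_r`` to floating-point precision.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    if n_pixels < 3:
        raise ValueError("n_pixels must be >= 3 (correlation degenerate)")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n_pixels)
    n = rng.standard_normal(n_pixels)
    a_c = a - a.mean()
    a_hat = a_c / np.sqrt(a_c @ a_c)
    n_c = n - n.mean()
    n_c = n_c - (n_c @ a_hat) * a_hat
    n_c = n_c - n_c.mean()  # re-centre (numerically) after projection
    n_hat = n_c / np.sqrt(n_c @ n_c)
    b = target_r * a_hat + math.sqrt(max(0.0, 1.0 - target_r**2)) * n_hat
    return a_hat, b


def generate_frap_trace(params: FrapSimParams) -> FrapTrace:
    """Simulate a FRAP experiment as three ROI intensity series.

    The bleach-ROI signal sits at plateau 1.0 pre-bleach, drops to
    ``1 - bleach_depth`` at the bleach frame and recovers along the
    single-exponential binding model; both signal ROIs decay by
    ``acquisition_bleach_rate`` per frame; the background ROI is constant.
    Additive Gaussian noise of sd ``noise_sd`` (fractions of the plateau)
    is applied to every series.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pre + params.n_post
    frame = np.arange(n)
    time_s = frame * params.dt_s

    model = np.ones(n)
    tau = (frame[params.n_pre:] - params.n_pre) * params.dt_s
    model[params.n_pre:] = (1.0 - params.bleach_depth) + (
        params.bleach_depth
        * params.mobile_fraction
        * (1.0 - np.exp(-params.rate_k * tau))
    )

    decay = (1.0 - params.acquisition_bleach_rate) ** frame
    bg = params.background_level
    roi_bleach = model * decay + bg
    roi_cell = params.cell_level * decay + bg
    roi_background = np.full(n, bg)

    if params.noise_sd > 0:
        roi_bleach = roi_bleach + rng.normal(0, params.noise_sd, n)
        roi_cell = roi_cell + rng.normal(0, params.noise_sd, n)
        roi_background = roi_background + rng.normal(0, params.noise_sd, n)

    return FrapTrace(
        frame=frame,
        time_s=time_s,
        roi_bleach=roi_bleach,
        roi_cell=roi_cell,
        roi_background=roi_background,
        bleach_frame=params.n_pre,
    )


def sample_morphometry(params: SceneParams, n_cells: int, seed: int | None = None):
    """Draw per-cell chromocenter counts and mean sizes directly from the
    scene parameter distributions, bypassing rendering.

    Useful for statistical power / type-I-error studies where rendering and
    segmenting thousands of images would add nothing but cost.  Returns
    (cn, cs) arrays of length ``n_cells``; cells drawn with zero
    chromocenters get NaN size.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cn = np.maximum(
        0, np.round(rng.normal(params.chromocenters_mean,
                               params.chromocenters_sd, n_cells))
    ).astype(int)
    cs = np.full(n_cells, np.nan)
    for i, k in enumerate(cn):
        if k > 0:
            r = np.maximum(1.0, rng.normal(params.radius_mean_px,
                                           params.radius_sd_px, k))
            cs[i] = float(np.mean(math.pi * r * r))
    return cn, cs
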