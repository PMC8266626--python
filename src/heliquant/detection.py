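"""Image correction, focus detection, trajectory linking and colocalisation.

The raw observable is a fluorescence movie (one channel of a two-colour TIRF
experiment) in camera counts.  This module takes such movies to tables of
diffraction-limited foci with sub-pixel centroids and background-subtracted
intensities, links foci across frames into intensity trajectories, builds
kymographs along flow-stretched DNA, and performs two-colour colocalisation
with the chance-coincidence model

    C = (A_R / A_FOV) * n

where A_R is the focus (matching-disc) area, A_FOV the field-of-view area and
n the number of foci in the partner channel.

Coordinate convention: 0-based pixel indices, pixel centre at integer
coordinates, Euclidean distances in pixel units.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .photobleach import IntensityTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "Focus",
    "ColocalizationChanceModel",
    "ColocalizationResult",
    "Kymograph",
    "EdgeProximityError",
    "correct_movie",
    "detect_foci",
    "detect_foci_movie",
    "integrated_intensity",
    "link_trajectories",
    "colocalize",
    "chance_colocalization",
    "make_kymograph",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Movie:
    """A time-ordered image stack for one fluorescence channel.

    ``frames`` has shape (n_frames, height, width) in camera counts; ``times``
    gives the physical start time of each frame in seconds.
    """

    frames: np.ndarray
    times: np.ndarray
    channel_label: str = ""
    pixel_size: float = float("nan")  # nm per pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, y, x) array")
        if self.times.size != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Focus:
    """One detected diffraction-limited spot in one frame."""

    frame_index: int
    x: float
    y: float
    integrated_intensity: float
    background_level: float = 0.0
    fit_sigma: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isfinite(self.integrated_intensity):
            raise ValueError("integrated_intensity must be finite")

    def distance_to(self, other: "Focus") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass
class ColocalizationChanceModel:
    """Chance-coincidence probability C = (A_R / A_FOV) * n."""

    A_R: float     # focus area, px^2
    A_FOV: float   # field-of-view area, px^2
    n: int         # number of foci

    def __post_init__(self) -> None:
        if not 0 < self.A_R <= self.A_FOV:
            raise ValueError("require 0 < A_R <= A_FOV")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.C > 1:
            warnings.warn(f"chance colocalisation C = {self.C:.3g} exceeds 1",
                          stacklevel=2)

    @property
    def C(self) -> float:
        return (self.A_R / self.A_FOV) * self.n


@dataclass
class ColocalizationResult:
    """One-to-one matched pairs between two channels plus the chance model."""

    pairs: list[tuple[int, int, float]]   # (index in A, index in B, distance px)
    fraction_colocalised: float
    chance: ColocalizationChanceModel | None = None
    radius: float = 2.0


@dataclass
class Kymograph:
    """Space-time image: one row per frame, one column per position on a line."""

    image: np.ndarray
    line: tuple[tuple[float, float], tuple[float, float]]
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.image.shape[0] != self.times.size:
            raise ValueError("row count must equal number of frames sampled")


class EdgeProximityError(ValueError):
    """Focus aperture would extend beyond the image boundary."""


# --------------------------------------------------------------------------
# Image correction
# --------------------------------------------------------------------------

def correct_movie(movie: Movie, offset: float, beam_profile: np.ndarray) -> Movie:
    """Remove the camera's electronic offset and flatten the excitation beam.

    The beam profile is normalised to unit mean, then
    ``out = (frames - offset) / profile``.  Negative residuals (offset
    over-subtraction in dark pixels) are clipped to zero; the number of
    clipped pixels is reported in ``meta['n_clipped_pixels']`` and logged.
    """
    profile = np.asarray(beam_profile, dtype=float)
    if profile.shape != movie.shape:
        raise ValueError(
            f"beam profile shape {profile.shape} != frame shape {movie.shape}")
    if np.any(profile <= 0):
        raise ValueError("beam profile must be strictly positive")
    profile = profile / profile.mean()
    corrected = (movie.frames - offset) / profile
    n_clipped = int(np.count_nonzero(corrected < 0))
    if n_clipped:
        logger.info("correct_movie: clipped %d negative pixels to 0", n_clipped)
    corrected = np.clip(corrected, 0.0, None)
    meta = dict(movie.meta)
    meta["n_clipped_pixels"] = n_clipped
    meta["offset_corrected"] = True
    return Movie(frames=corrected, times=movie.times.copy(),
                 channel_label=movie.channel_label,
                 pixel_size=movie.pixel_size, meta=meta)


# --------------------------------------------------------------------------
# Focus detection
# --------------------------------------------------------------------------

def _gaussian2d(params, xs, ys):
    amp, x0, y0, sigma, off = params
    return off + amp * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma ** 2))


def _fit_gaussian(window: np.ndarray, x_origin: int, y_origin: int,
                  sigma_bounds: tuple[float, float]) -> tuple | None:
    h, w = window.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    off0 = float(np.median(window))
    amp0 = float(window.max() - off0)
    if amp0 <= 0:
        return None
    iy, ix = np.unravel_index(int(np.argmax(window)), window.shape)
    p0 = [amp0, float(ix), float(iy), 1.3, off0]
    lo = [0.0, -1.0, -1.0, sigma_bounds[0] * 0.5, -np.inf]
    hi = [np.inf, w, h, sigma_bounds[1] * 2.0, np.inf]

    def resid(p):
        return (_gaussian2d(p, xs, ys) - window).ravel()

    try:
        res = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=200)
    except Exception:
        return None
    amp, x0, y0, sigma, off = res.x
    if not (sigma_bounds[0] <= sigma <= sigma_bounds[1]):
        return None
    if not (0 <= x0 < w and 0 <= y0 < h):
        return None
    integrated = 2.0 * math.pi * amp * sigma ** 2
    return (x_origin + x0, y_origin + y0, integrated, off, sigma)


def detect_foci(frame: np.ndarray,
                min_snr: float = 5.0,
                window: int = 7,
                frame_index: int = 0,
                sigma_bounds: tuple[float, float] = (0.5, 3.0)) -> list[Focus]:
    """Detect diffraction-limited foci in one frame with sub-pixel precision.

    Candidate local maxima above ``median + min_snr * MAD`` (MAD scaled to a
    Gaussian sigma) are refined by least-squares 2-D Gaussian fitting in a
    ``window x window`` region.  Fits with sigma outside ``sigma_bounds`` are
    discarded; duplicate detections within 1 px are merged keeping the
    brighter one.

    Returns foci sorted by descending integrated intensity.
    """
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    frame = np.asarray(frame, dtype=float)
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med))) * 1.4826
    threshold = med + min_snr * mad
    half = window // 2

    local_max = ndimage.maximum_filter(frame, size=3, mode="nearest")
    cand = np.argwhere((frame == local_max) & (frame > threshold))

    foci: list[Focus] = []
    n_discarded = 0
    for cy, cx in cand:
        y0, x0 = cy - half, cx - half
        if y0 < 0 or x0 < 0 or y0 + window > frame.shape[0] or x0 + window > frame.shape[1]:
            continue
        fit = _fit_gaussian(frame[y0:y0 + window, x0:x0 + window], x0, y0, sigma_bounds)
        if fit is None:
            n_discarded += 1
            continue
        fx, fy, integrated, bg, sigma = fit
        foci.append(Focus(frame_index=frame_index, x=fx, y=fy,
                          integrated_intensity=integrated,
                          background_level=bg, fit_sigma=sigma))
    if n_discarded:
        logger.debug("detect_foci: discarded %d degenerate fits", n_discarded)

    # merge duplicates within 1 px, keeping the brighter focus
    foci.sort(key=lambda f: -f.integrated_intensity)
    kept: list[Focus] = []
    for f in foci:
        if all(f.distance_to(g) > 1.0 for g in kept):
            kept.append(f)
    return kept


def detect_foci_movie(movie: Movie, **kwargs) -> dict[int, list[Focus]]:
    """Run :func:`detect_foci` on every frame; returns {frame_index: foci}."""
    return {
        i: detect_foci(movie.frames[i], frame_index=i, **kwargs)
        for i in range(movie.n_frames)
    }


def foci_to_table(foci: Sequence[Focus]) -> pd.DataFrame:
    """Tabulate foci as the standard CSV layout."""
    return pd.DataFrame(
        [
            {
                "frame": f.frame_index,
                "x_px": f.x,
                "y_px": f.y,
                "intensity": f.integrated_intensity,
                "background": f.background_level,
                "sigma_px": f.fit_sigma,
            }
            for f in foci
        ],
        columns=["frame", "x_px", "y_px", "intensity", "background", "sigma_px"],
    )


# --------------------------------------------------------------------------
# Aperture photometry
# --------------------------------------------------------------------------

def integrated_intensity(movie: Movie, focus: Focus,
                         disc_radius: float = 4.0,
                         annulus: tuple[float, float] = (6.0, 9.0)) -> float:
    """Disc-minus-annulus aperture photometry at a focus position.

    Sum of pixel values within ``disc_radius`` of the centroid minus the
    *median* pixel value of the background annulus times the disc pixel count.
    The median is robust against a neighbouring spot leaking into the annulus.

    Raises
    ------
    EdgeProximityError
        If the annulus extends beyond the frame; such foci are excluded from
        downstream statistics by callers.
    """
    r_in, r_out = annulus
    if r_in <= disc_radius:
        raise ValueError("annulus must lie outside the disc")
    h, w = movie.shape
    if (focus.x - r_out < -0.5 or focus.x + r_out > w - 0.5
            or focus.y - r_out < -0.5 or focus.y + r_out > h - 0.5):
        raise EdgeProximityError(
            f"focus at ({focus.x:.1f}, {focus.y:.1f}) too close to the edge")
    frame = movie.frames[focus.frame_index]
    ys, xs = np.mgrid[0:h, 0:w]
    rr = np.hypot(xs - focus.x, ys - focus.y)
    disc = rr <= disc_radius
    ann = (rr >= r_in) & (rr <= r_out)
    bg = float(np.median(frame[ann]))
    return float(frame[disc].sum() - bg * int(disc.sum()))


# --------------------------------------------------------------------------
# Trajectory linking
# --------------------------------------------------------------------------

def link_trajectories(foci_by_frame: Mapping[int, Sequence[Focus]] | Sequence[Sequence[Focus]],
                      max_step: float = 3.0,
                      max_gap: int = 1,
                      times: np.ndarray | None = None,
                      excitation_schedule: tuple[float, float] | None = None,
                      ) -> list[IntensityTrajectory]:
    """Greedy nearest-neighbour linking of foci into trajectories.

    Candidate links between active track ends and current-frame foci are
    assigned in ascending order of distance (ties broken by lowest focus
    index); links beyond ``max_step`` px are rejected and gaps of up to
    ``max_gap`` missed frames are closed.

    ``times`` maps frame index to seconds; defaults to the frame index itself.
    """
    if not isinstance(foci_by_frame, Mapping):
        foci_by_frame = {i: lst for i, lst in enumerate(foci_by_frame)}
    if not foci_by_frame:
        return []
    frames = sorted(foci_by_frame)

    tracks: list[list[Focus]] = []
    active: list[int] = []   # indices into tracks
    for fi in frames:
        foci = list(foci_by_frame[fi])
        # drop tracks whose gap exceeded max_gap
        active = [ti for ti in active
                  if fi - tracks[ti][-1].frame_index <= max_gap + 1]
        cands = []
        for ti in active:
            last = tracks[ti][-1]
            for fj, f in enumerate(foci):
                d = last.distance_to(f)
                if d <= max_step:
                    cands.append((d, fj, ti))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_foci: set[int] = set()
        for d, fj, ti in cands:
            if ti in used_tracks or fj in used_foci:
                continue
            tracks[ti].append(foci[fj])
            used_tracks.add(ti)
            used_foci.add(fj)
        for fj, f in enumerate(foci):
            if fj not in used_foci:
                tracks.append([f])
                active.append(len(tracks) - 1)

    out: list[IntensityTrajectory] = []
    for tid, tr in enumerate(tracks):
        fr = np.array([f.frame_index for f in tr], dtype=int)
        t = fr.astype(float) if times is None else np.asarray(times, float)[fr]
        out.append(IntensityTrajectory(
            times=t,
            intensities=np.array([f.integrated_intensity for f in tr]),
            excitation_schedule=excitation_schedule,
            source_focus_id=tid,
            foci=tr,
        ))
    return out


# --------------------------------------------------------------------------
# Colocalisation
# --------------------------------------------------------------------------

def chance_colocalization(A_R: float, A_FOV: float, n: int) -> float:
    """Probability of coincidental colocalisation, C = (A_R / A_FOV) * n.

    ``A_R`` is the focus (matching-disc) area and ``A_FOV`` the field-of-view
    area, both in px^2; ``n`` is the number of foci in the partner channel.
    """
    return ColocalizationChanceModel(A_R=A_R, A_FOV=A_FOV, n=n).C


def colocalize(foci_a: Sequence[Focus], foci_b: Sequence[Focus],
               radius: float = 2.0,
               fov_area: float | None = None,
               focus_area: float | None = None) -> ColocalizationResult:
    """Two-colour colocalisation by one-to-one greedy distance matching.

    Foci are paired in ascending order of centroid distance; pairs farther
    apart than ``radius`` (2 px by convention) are rejected and each focus
    joins at most one pair.  ``fraction_colocalised`` uses channel A as the
    reference denominator (the DNA channel in the loading assay).  If
    ``fov_area`` is given, the chance model is evaluated with
    ``A_R = focus_area`` (default pi * radius^2) and ``n = len(foci_b)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cands = []
    for ia, fa in enumerate(foci_a):
        for ib, fb in enumerate(foci_b):
            d = fa.distance_to(fb)
            if d <= radius:
                cands.append((d, ia, ib))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib, d))
        used_a.add(ia)
        used_b.add(ib)
    frac = len(pairs) / len(foci_a) if foci_a else 0.0
    chance = None
    if fov_area is not None:
        a_r = focus_area if focus_area is not None else math.pi * radius ** 2
        chance = ColocalizationChanceModel(A_R=a_r, A_FOV=fov_area, n=len(foci_b))
    return ColocalizationResult(pairs=pairs, fraction_colocalised=frac,
                                chance=chance, radius=radius)


# --------------------------------------------------------------------------
# Kymographs
# --------------------------------------------------------------------------

def make_kymograph(movie: Movie,
                   line: tuple[tuple[float, float], tuple[float, float]],
                   width: int = 3) -> Kymograph:
    """Build a space-time image along a line, one row per frame.

    The intensity profile is sampled at 1-px spacing along the line and
    averaged over ``width`` parallel offsets perpendicular to it (bilinear
    interpolation).  Used to visualise replication forks on flow-stretched
    DNA: a fork moving at v px/s appears as a stripe of slope v.
    """
    (x0, y0), (x1, y1) = line
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length line")
    n_samples = int(math.ceil(length)) + 1
    s = np.linspace(0.0, length, n_samples)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px, py = -uy, ux   # unit perpendicular
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0

    rows = np.empty((movie.n_frames, n_samples))
    for i in range(movie.n_frames):
        acc = np.zeros(n_samples)
        for o in offsets:
            xs = x0 + ux * s + px * o
            ys = y0 + uy * s + py * o
            acc += ndimage.map_coordinates(movie.frames[i], [ys, xs],
                                           order=1, mode="nearest")
        rows[i] = acc / len(offsets)
    return Kymograph(image=rows, line=line, times=movie.times.copy())
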