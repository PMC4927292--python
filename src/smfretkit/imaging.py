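"""Minimal dual-channel TIRF movie rendering and trace extraction.

The camera field is split by a dichroic into a donor half (left) and an
acceptor half (right): a molecule at (row, col) in the donor half images
its acceptor emission at (row, col) + ``channel_split`` offset.  Spots are
isotropic Gaussian point-spread functions integrated over pixels, on a
constant background with Gaussian read noise.  Detection averages the
first frames, finds local maxima above a robust threshold, refines them by
intensity-weighted centroid, and pairs the channels through the known
split.  Extraction sums pixels in a circular aperture and subtracts the
local annulus background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import AnalysisError, ConfigError
from .synth import Trace

__all__ = [
    "MovieConfig",
    "SpotSet",
    "RenderedMovie",
    "render_movie",
    "detect_spots",
    "extract_traces",
    "write_stack",
    "read_stack",
]


@dataclass
class MovieConfig:
    """Rendering parameters for a synthetic dual-channel movie."""

    field_size: tuple[int, int] = (64, 128)  # (rows, cols), cols split in half
    n_spots: int = 10
    psf_sd: float = 1.2  # pixels
    frame_interval: float = 0.1
    n_frames: int = 100
    background_level: float = 100.0
    noise_sd: float = 5.0
    channel_split: tuple[int, int] = None  # (drow, dcol) donor -> acceptor
    margin: int = 6  # keep spots away from edges and the split line
    min_separation: float | None = None  # pixels; default 4*psf_sd
    seed: int | None = None

    def __post_init__(self) -> None:
        rows, cols = self.field_size
        if rows <= 0 or cols <= 0 or cols % 2:
            raise ConfigError("field_size must be positive with an even column count")
        if self.n_spots < 0:
            raise ConfigError("n_spots must be >= 0")
        if self.psf_sd <= 0:
            raise ConfigError("psf_sd must be > 0")
        if self.channel_split is None:
            self.channel_split = (0, cols // 2)
        # sparse-field requirement: expected nearest-neighbour distance in a
        # random pattern, 0.5/sqrt(density), must exceed 4 PSF widths
        if self.n_spots > 1:
            half_area = rows * (cols // 2)
            expected_nn = 0.5 * np.sqrt(half_area / self.n_spots)
            if expected_nn <= 4.0 * self.psf_sd:
                raise ConfigError(
                    f"spot density too high: expected NN distance {expected_nn:.1f}px"
                    f" <= 4*psf_sd={4 * self.psf_sd:.1f}px"
                )


@dataclass
class SpotSet:
    """Detected (or ground-truth) spot positions and the channel pairing."""

    donor_positions: np.ndarray  # (N, 2) sub-pixel (row, col)
    acceptor_positions: np.ndarray  # (M, 2)
    pairs: list = field(default_factory=list)  # (donor_idx, acceptor_idx)


@dataclass
class RenderedMovie:
    stack: np.ndarray  # (n_frames, rows, cols)
    truth: SpotSet
    config: MovieConfig


def _pixel_integrated_psf(pos: np.ndarray, sd: float, shape: tuple[int, int]):
    """Unit-integral Gaussian PSF integrated over pixels in a local window.

    Returns (row_slice, col_slice, weights) with weights summing to ~1.
    """
    r0, c0 = pos
    half = int(np.ceil(5 * sd))
    rlo = max(int(np.floor(r0)) - half, 0)
    rhi = min(int(np.floor(r0)) + half + 1, shape[0])
    clo = max(int(np.floor(c0)) - half, 0)
    chi = min(int(np.floor(c0)) + half + 1, shape[1])
    rows = np.arange(rlo, rhi)
    cols = np.arange(clo, chi)
    s = sd * np.sqrt(2.0)
    wr = 0.5 * (erf((rows + 1 - r0) / s) - erf((rows - r0) / s))
    wc = 0.5 * (erf((cols + 1 - c0) / s) - erf((cols - c0) / s))
    return slice(rlo, rhi), slice(clo, chi), np.outer(wr, wc)


def render_movie(traces: Sequence[Trace], config: MovieConfig) -> RenderedMovie:
    """Render traces as PSF spots in a dual-channel movie.

    One trace per spot: the donor series drives the left-half spot, the
    acceptor series the paired right-half spot.  Spot positions are drawn
    uniformly (seeded) with a minimum pairwise separation of 4 PSF widths.
    """
    if len(traces) != config.n_spots:
        raise ConfigError(
            f"need exactly one trace per spot ({config.n_spots}), got {len(traces)}"
        )
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_size
    half_cols = cols // 2
    m = config.margin
    if config.n_spots > 0 and (rows <= 2 * m or half_cols <= 2 * m):
        raise ConfigError("field too small for the requested margin")

    positions = []
    min_sep = config.min_separation if config.min_separation is not None else 4.0 * config.psf_sd
    attempts = 0
    while len(positions) < config.n_spots:
        if attempts > 1000 * max(config.n_spots, 1):
            raise ConfigError("could not place spots at the requested separation")
        cand = np.array(
            [rng.uniform(m, rows - m), rng.uniform(m, half_cols - m)]
        )
        attempts += 1
        if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
            positions.append(cand)
    donor_pos = np.asarray(positions).reshape(config.n_spots, 2)
    acceptor_pos = donor_pos + np.asarray(config.channel_split)

    n_frames = min(config.n_frames, min((len(t) for t in traces), default=config.n_frames))
    stack = np.full((n_frames, rows, cols), config.background_level, dtype=float)
    for tr, dpos, apos in zip(traces, donor_pos, acceptor_pos):
        for pos, series in ((dpos, tr.donor), (apos, tr.acceptor)):
            rs, cs, w = _pixel_integrated_psf(pos, config.psf_sd, (rows, cols))
            stack[:, rs, cs] += series[:n_frames, None, None] * w
    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, stack.shape)
    truth = SpotSet(donor_pos, acceptor_pos, [(i, i) for i in range(config.n_spots)])
    return RenderedMovie(stack, truth, config)


# ---------------------------------------------------------------------------
# detection


def _detect_in_half(mean_img: np.ndarray, threshold_k: float, col_offset: int):
    bg = float(np.median(mean_img))
    mad = float(np.median(np.abs(mean_img - bg)))
    sd = 1.4826 * mad
    threshold = bg + threshold_k * sd
    footprint = np.ones((5, 5), dtype=bool)
    local_max = ndimage.maximum_filter(mean_img, footprint=footprint) == mean_img
    cand = np.argwhere(local_max & (mean_img > threshold))
    positions = []
    for r, c in cand:
        # intensity-weighted centroid in a 5x5 window
        rlo, rhi = max(r - 2, 0), min(r + 3, mean_img.shape[0])
        clo, chi = max(c - 2, 0), min(c + 3, mean_img.shape[1])
        win = np.clip(mean_img[rlo:rhi, clo:chi] - bg, 0, None)
        total = win.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        positions.append([(rr * win).sum() / total, (cc * win).sum() / total + col_offset])
    positions = np.asarray(positions).reshape(-1, 2)
    # plateau ties in the maximum filter yield duplicate maxima for the
    # same (possibly merged) spot: keep one detection per 2 px cluster
    unique: list[np.ndarray] = []
    for p in positions:
        if all(np.linalg.norm(p - q) > 2.0 for q in unique):
            unique.append(p)
    return np.asarray(unique).reshape(-1, 2)


def detect_spots(
    stack: np.ndarray,
    averaging_frames: int = 10,
    threshold_k: float = 4.0,
    channel_split: tuple[int, int] | None = None,
    pairing_tolerance: float = 2.0,
) -> SpotSet:
    """Detect and pair spots from the average of the first frames.

    Local maxima of the averaged image exceeding background plus
    ``threshold_k`` robust SDs are refined to sub-pixel centroids,
    per channel half; acceptor spots are paired to the donor spot whose
    split-mapped position lies within ``pairing_tolerance`` pixels.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise AnalysisError("stack must be a non-empty (frames, rows, cols) array")
    rows, cols = stack.shape[1:]
    if channel_split is None:
        channel_split = (0, cols // 2)
    mean_img = stack[: max(averaging_frames, 1)].mean(axis=0)
    half = cols // 2
    donor = _detect_in_half(mean_img[:, :half], threshold_k, 0)
    acceptor = _detect_in_half(mean_img[:, half:], threshold_k, half)

    pairs = []
    offset = np.asarray(channel_split, dtype=float)
    for j, apos in enumerate(acceptor):
        mapped = apos - offset
        if donor.size == 0:
            break
        dist = np.linalg.norm(donor - mapped, axis=1)
        i = int(np.argmin(dist))
        if dist[i] <= pairing_tolerance:
            pairs.append((i, j))
    return SpotSet(donor, acceptor, pairs)


# ---------------------------------------------------------------------------
# extraction


def _disk_mask(shape, centre, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def extract_traces(
    stack: np.ndarray,
    spots: SpotSet,
    aperture_radius: float = 3.0,
    annulus: tuple[float, float] = (5.0, 8.0),
    frame_interval: float = 0.1,
) -> list[Trace]:
    """Aperture-summed, annulus-background-subtracted traces per spot pair.

    For each paired donor/acceptor spot, per frame: sum of pixels within
    ``aperture_radius`` of the centre minus the annulus median times the
    aperture pixel count.
    """
    if aperture_radius <= 0:
        raise ValueError("aperture_radius must be > 0")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise AnalysisError("stack must be (frames, rows, cols)")
    shape = stack.shape[1:]

    def pull(pos):
        r, c = pos
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise AnalysisError(f"spot at {pos} outside the field")
        if (
            r - aperture_radius < 0
            or r + aperture_radius >= shape[0]
            or c - aperture_radius < 0
            or c + aperture_radius >= shape[1]
        ):
            raise AnalysisError(f"aperture around {pos} extends outside the field")
        ap = _disk_mask(shape, pos, aperture_radius)
        ring = _disk_mask(shape, pos, annulus[1]) & ~_disk_mask(shape, pos, annulus[0])
        flat = stack.reshape(stack.shape[0], -1)
        ap_sum = flat[:, ap.ravel()].sum(axis=1)
        bg = np.median(flat[:, ring.ravel()], axis=1) if ring.any() else 0.0
        return ap_sum - bg * ap.sum()

    traces = []
    for k, (i, j) in enumerate(spots.pairs):
        donor = pull(spots.donor_positions[i])
        acceptor = pull(spots.acceptor_positions[j])
        traces.append(Trace(f"spot{k:04d}", donor, acceptor, frame_interval))
    return traces


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
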