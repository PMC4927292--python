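"""Per-molecule efficiency histograms and two-Gaussian population analysis.

Each selected molecule contributes a single efficiency value: the mean of
its per-frame corrected efficiencies over the first 50 frames (5 s at
10 Hz), well before typical photobleaching.  The cohort histogram of these
values is decomposed into a low- and a high-efficiency Gaussian component
by least squares on the binned counts; population percentages are ratios
of component areas to the total area, and their uncertainty is the SD of
the statistic over a random equal split of the molecules into two halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .corrections import CorrectionSet, corrected_efficiency
from .errors import AnalysisError, FitError
from .synth import Trace

__all__ = [
    "EfficiencySample",
    "FretHistogram",
    "TwoGaussianFit",
    "PopulationResult",
    "per_molecule_efficiency",
    "build_histogram",
    "fit_two_gaussians",
    "population_fraction",
    "split_half_sd",
]

#: histogram defaults: 0.02-wide bins over a range that admits corrected
#: efficiencies slightly outside [0, 1]
DEFAULT_BIN_WIDTH = 0.02
DEFAULT_RANGE = (-0.2, 1.2)
DEFAULT_N_FRAMES = 50


@dataclass
class EfficiencySample:
    """One molecule's accumulated FRET efficiency."""

    molecule_id: str
    efficiency: float
    condition: dict = field(default_factory=dict)
    correction_mode: str = "leakage"


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class GaussianComponent:
    mean: float
    sd: float
    amplitude: float

    @property
    def area(self) -> float:
        return self.amplitude * self.sd * np.sqrt(2.0 * np.pi)


@dataclass
class TwoGaussianFit:
    """Low/high ordered two-Gaussian decomposition of a FRET histogram."""

    low: GaussianComponent
    high: GaussianComponent
    residual_norm: float
    converged: bool
    degenerate: bool = False
    n_samples: int = 0

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return _two_gauss(x, self.low.amplitude, self.low.mean, self.low.sd,
                          self.high.amplitude, self.high.mean, self.high.sd)


@dataclass
class PopulationResult:
    metric: str
    percent: float
    sd: float
    n_molecules: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError("percent must lie in [0, 100]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------


def per_molecule_efficiency(
    trace: Trace,
    corrections: CorrectionSet = CorrectionSet(),
    n_frames: int = DEFAULT_N_FRAMES,
    mode: str = "leakage",
    bleach_frame: int | None = None,
) -> EfficiencySample:
    """Mean per-frame corrected efficiency over the first ``n_frames`` frames.

    ``bleach_frame`` (the first detected bleach event, if any) guards the
    accumulation window: the molecule must survive the full window.
    """
    if len(trace) < n_frames:
        raise AnalysisError(
            f"trace has {len(trace)} frames, need {n_frames}"
        )
    if bleach_frame is not None and bleach_frame < n_frames:
        raise AnalysisError(
            f"bleach at frame {bleach_frame} precedes the {n_frames}-frame window"
        )
    e = corrected_efficiency(
        trace.donor[:n_frames], trace.acceptor[:n_frames], corrections, mode=mode
    )
    return EfficiencySample(
        trace.molecule_id, float(np.mean(e)), dict(trace.condition), mode
    )


def build_histogram(
    samples,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] = DEFAULT_RANGE,
) -> FretHistogram:
    """Bin efficiency values (or EfficiencySample objects) into counts."""
    values = _as_values(samples)
    if values.size == 0:
        raise AnalysisError("need at least one sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = range
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = np.linspace(lo, lo + n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    if counts.sum() == 0:
        warnings.warn("all samples fall outside the histogram range")
    return FretHistogram(edges, counts)


def _as_values(samples) -> np.ndarray:
    if len(samples) and isinstance(samples[0], EfficiencySample):
        return np.array([s.efficiency for s in samples], dtype=float)
    return np.asarray(samples, dtype=float)


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def fit_two_gaussians(
    samples,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] = DEFAULT_RANGE,
    init_strategy: str = "quantile",
) -> TwoGaussianFit:
    """Least-squares two-Gaussian fit to the binned efficiency histogram.

    Initialization places the component means at the 25th/75th percentiles
    of the samples, SDs at half the sample SD, and equal amplitudes.
    Components are ordered low/high by mean after convergence (by SD when
    the means tie).  A component whose area collapses below 1 % of the
    total marks the fit ``degenerate`` (effectively single-population data).
    """
    values = _as_values(samples)
    if values.size < 20:
        raise AnalysisError(f"need >= 20 samples to fit, got {values.size}")
    hist = build_histogram(values, bin_width, range)
    x, y = hist.bin_centers, hist.counts.astype(float)

    if init_strategy == "quantile":
        m1, m2 = np.percentile(values, [25, 75])
    elif init_strategy == "extremes":
        m1, m2 = np.percentile(values, [5, 95])
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")
    s0 = max(np.std(values) / 2.0, bin_width)
    a0 = max(y.max() / 2.0, 1.0)
    p0 = [a0, m1, s0, a0, m2, s0]
    lo, hi = range
    bounds = (
        [0.0, lo, bin_width / 4, 0.0, lo, bin_width / 4],
        [np.inf, hi, hi - lo, np.inf, hi, hi - lo],
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_two_gauss, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"two-Gaussian fit did not converge: {exc}") from exc

    c1 = GaussianComponent(popt[1], popt[2], popt[0])
    c2 = GaussianComponent(popt[4], popt[5], popt[3])
    if (c1.mean, c1.sd) > (c2.mean, c2.sd):
        c1, c2 = c2, c1
    resid = float(np.linalg.norm(_two_gauss(x, *popt) - y))
    total = c1.area + c2.area
    # degenerate: one component vanishes, or the components overlap so
    # heavily that the data are effectively single-population
    degenerate = (
        total <= 0
        or min(c1.area, c2.area) < 0.01 * total
        or (c2.mean - c1.mean) < 2.0 * max(c1.sd, c2.sd)
    )
    if degenerate:
        warnings.warn("two-Gaussian fit is degenerate (single population)")
    return TwoGaussianFit(c1, c2, resid, converged, degenerate, values.size)


def population_fraction(fit: TwoGaussianFit, which: str = "high") -> PopulationResult:
    """Percentage of molecules in one component: 100 * area / total area."""
    if which not in ("low", "high"):
        raise ValueError("which must be 'low' or 'high'")
    total = fit.low.area + fit.high.area
    if not fit.converged or total <= 0:
        raise FitError("cannot compute population fraction of a degenerate fit")
    area = fit.low.area if which == "low" else fit.high.area
    return PopulationResult(
        metric=f"% {which} population",
        percent=100.0 * area / total,
        sd=0.0,
        n_molecules=fit.n_samples,
    )


def split_half_sd(
    samples: Sequence,
    statistic: Callable,
    seed: int | None = None,
) -> tuple[float, float]:
    """Uncertainty of a cohort statistic from a random equal split.

    Molecules are shuffled (seeded) and partitioned into two halves; the
    statistic is evaluated on each half.  Returns the mean of the two
    values and their sample SD (|a - b| / sqrt(2) for two values).
    """
    n = len(samples)
    if n < 2:
        raise AnalysisError("need >= 2 samples for a split-half estimate")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    halves = (idx[: n // 2], idx[n // 2 :])
    try:
        vals = [float(statistic([samples[i] for i in h])) for h in halves]
    except Exception as exc:
        raise AnalysisError(f"statistic failed on a split half: {exc}") from exc
    return float(np.mean(vals)), float(np.std(vals, ddof=1))
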