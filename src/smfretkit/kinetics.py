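"""Two-state idealization and dwell-time kinetics.

Binding-burst traces are idealized with a two-state Gaussian-emission
hidden Markov model (state 1 = bound/high signal, state 0 = unbound/low),
dwell times are the idealized run lengths, and single-exponential rates
give k_off (bound-state exit rate), k_on (unbound-state exit rate divided
by the ligand concentration, 1/(uM s)) and K_D = k_off/k_on (uM).

For binding traces the natural emission series is the raw acceptor
intensity (the donor stays constant because the donor-labelled partner is
in solution excess); for conformational traces it is the corrected
per-frame efficiency.  Both are plain 1-D series here; the caller picks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import curve_fit

from .errors import AnalysisError, FitError

__all__ = [
    "StatePath",
    "DwellTimeSet",
    "RateFit",
    "KineticRates",
    "idealize_two_state",
    "extract_dwells",
    "fit_dwell_rate",
    "association_rate",
    "dissociation_constant",
    "rates_from_dwells",
]


@dataclass
class StatePath:
    """Idealized two-state path with its fitted emission model."""

    states: np.ndarray  # per-frame labels, 0 = unbound/low, 1 = bound/high
    means: np.ndarray  # emission means, means[1] >= means[0]
    sds: np.ndarray
    transmat: np.ndarray  # row-stochastic 2x2
    log_likelihood: float
    converged: bool
    degenerate: bool = False


@dataclass
class DwellTimeSet:
    """Dwell times in seconds, per state.

    ``bound_dwells``/``unbound_dwells`` hold the interior dwells (both
    endpoints observed inside the trace).  The first and last runs of each
    trace are censored: their durations are accumulated separately as
    ``*_censored_time`` so that rate estimation can account for the time
    spent in them, with ``*_censored_events`` counting the censored runs
    whose exit was still observed (the first run: its end is seen, only
    its beginning predates the recording).
    """

    bound_dwells: np.ndarray
    unbound_dwells: np.ndarray
    n_censored: int = 0
    concentration: float | None = None  # uM
    bound_censored_time: float = 0.0
    unbound_censored_time: float = 0.0
    bound_censored_events: int = 0
    unbound_censored_events: int = 0

    def pooled_with(self, other: "DwellTimeSet") -> "DwellTimeSet":
        if (
            self.concentration is not None
            and other.concentration is not None
            and self.concentration != other.concentration
        ):
            raise AnalysisError("cannot pool dwells across concentrations")
        return DwellTimeSet(
            np.concatenate([self.bound_dwells, other.bound_dwells]),
            np.concatenate([self.unbound_dwells, other.unbound_dwells]),
            self.n_censored + other.n_censored,
            self.concentration if self.concentration is not None else other.concentration,
            self.bound_censored_time + other.bound_censored_time,
            self.unbound_censored_time + other.unbound_censored_time,
            self.bound_censored_events + other.bound_censored_events,
            self.unbound_censored_events + other.unbound_censored_events,
        )


@dataclass
class RateFit:
    rate: float  # 1/s
    se: float
    n: int
    method: str


@dataclass
class KineticRates:
    """Binding kinetics: k_off (1/s), k_on (1/(uM s)), K_D (uM)."""

    k_off: float
    k_on: float
    kd: float
    se_k_off: float
    se_k_on: float
    n_bound: int
    n_unbound: int


# ---------------------------------------------------------------------------
# idealization


def idealize_two_state(
    series,
    max_iter: int = 200,
    tol: float = 1e-4,
    random_state: int = 0,
) -> StatePath:
    """Fit a two-state Gaussian HMM by EM and return its Viterbi path.

    Emissions are initialized at the 10th/90th percentiles of the series
    with half the sample SD; the transition matrix starts sticky (0.9 on
    the diagonal).  State 1 is the higher-mean state.  A series with no
    usable spread returns a degenerate all-zero path with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise AnalysisError("series must be 1-D with >= 10 frames")
    spread = np.percentile(x, 90) - np.percentile(x, 10)
    if spread <= 0 or np.std(x) == 0:
        warnings.warn("series has no spread; returning a single-state path")
        m = float(np.mean(x))
        return StatePath(
            states=np.zeros(x.size, dtype=int),
            means=np.array([m, m]),
            sds=np.array([0.0, 0.0]),
            transmat=np.eye(2),
            log_likelihood=np.nan,
            converged=True,
            degenerate=True,
        )

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="stmc",
        random_state=random_state,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
    model.means_ = np.percentile(x, [10, 90]).reshape(-1, 1)
    s0 = max(np.std(x) / 2.0, spread / 20.0, 1e-6)
    model.covars_ = np.full((2, 1), s0**2)
    X = x.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
        logprob, states = model.decode(X, algorithm="viterbi")
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("two-state HMM did not converge within max_iter")

    means = model.means_.ravel()
    sds = np.sqrt(np.asarray(model.covars_).ravel())
    transmat = model.transmat_
    if means[0] > means[1]:  # enforce state 1 = high
        states = 1 - states
        means = means[::-1]
        sds = sds[::-1]
        transmat = transmat[::-1, ::-1]
    if means[1] - means[0] < 2.0 * max(sds):
        # the two emission levels are not resolved: a single-level series
        # (e.g. a trace with no binding events) would otherwise be split
        # into spurious noise-driven dwells
        warnings.warn("emission levels unresolved; returning a single-state path")
        return StatePath(
            states=np.zeros(x.size, dtype=int),
            means=means,
            sds=sds,
            transmat=np.eye(2),
            log_likelihood=float(logprob),
            converged=converged,
            degenerate=True,
        )
    return StatePath(
        states=states.astype(int),
        means=means,
        sds=sds,
        transmat=transmat,
        log_likelihood=float(logprob),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# dwell times


def extract_dwells(
    path: StatePath | np.ndarray,
    frame_interval: float,
    drop_censored: bool = True,
    concentration: float | None = None,
) -> DwellTimeSet:
    """Run lengths of the idealized path, in seconds.

    The first and last runs of a trace are censored (entry/exit not
    observed) and excluded by default.
    """
    states = path.states if isinstance(path, StatePath) else np.asarray(path, int)
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if states.size == 0:
        return DwellTimeSet(np.empty(0), np.empty(0), 0, concentration)
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    lengths = (ends - starts) * frame_interval
    labels = states[starts]
    n_runs = len(lengths)
    if drop_censored and n_runs >= 1:
        interior = slice(1, n_runs - 1)
        n_censored = min(n_runs, 2)
    else:
        interior = slice(0, n_runs)
        n_censored = 0
    out = DwellTimeSet(
        bound_dwells=lengths[interior][labels[interior] == 1],
        unbound_dwells=lengths[interior][labels[interior] == 0],
        n_censored=n_censored,
        concentration=concentration,
    )
    if drop_censored:
        # first run: its exit is observed (one event); last run: censored at
        # the end of the trace (time only, no event)
        censored = [(0, n_runs > 1)] + ([(n_runs - 1, False)] if n_runs > 1 else [])
        for idx, exit_seen in censored:
            if labels[idx] == 1:
                out.bound_censored_time += lengths[idx]
                out.bound_censored_events += int(exit_seen)
            else:
                out.unbound_censored_time += lengths[idx]
                out.unbound_censored_events += int(exit_seen)
    return out


# ---------------------------------------------------------------------------
# rate fitting


def fit_dwell_rate(
    dwells,
    method: str = "mle",
    frame_interval: float = 0.0,
    n_bins: int = 30,
) -> RateFit:
    """Single-exponential rate from a set of dwell times.

    ``mle``: rate = 1/(mean - delta) with delta = frame_interval/2, the
    half-frame correction for camera-discretized dwells (a dwell is scored
    only when it claims at least one frame, so observed dwells are biased
    long by about half a frame); SE = rate/sqrt(n) from the observed
    information.  ``histogram``: least-squares single-exponential fit to
    the binned dwell histogram (the figure-style estimator), SE from the
    fit covariance.
    """
    d = np.asarray(dwells, dtype=float)
    if d.size < 10:
        raise AnalysisError(f"need >= 10 dwells, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("dwell times must be > 0")
    delta = frame_interval / 2.0
    mean = float(d.mean())
    if mean <= delta:
        raise FitError("mean dwell does not exceed the discretization offset")

    if method == "mle":
        rate = 1.0 / (mean - delta)
        return RateFit(rate, rate / np.sqrt(d.size), d.size, "mle")
    if method == "histogram":
        if np.ptp(d) == 0:
            raise FitError("zero-variance dwells cannot be histogram-fitted")
        if frame_interval > 0:
            # align bin edges to the frame grid so that the discrete dwell
            # values (integer frame counts) do not alias across bins
            width = frame_interval * max(
                1, int(np.ceil(d.max() / (n_bins * frame_interval)))
            )
            edges = np.arange(frame_interval / 2.0, d.max() + width, width)
            counts, edges = np.histogram(d, bins=edges)
        else:
            counts, edges = np.histogram(d, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        k0 = 1.0 / max(mean - delta, 1e-12)

        def expdecay(t, a, k):
            return a * np.exp(-k * t)

        try:
            popt, pcov = curve_fit(
                expdecay,
                centers[keep],
                counts[keep],
                p0=[counts.max(), k0],
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitError(f"histogram exponential fit failed: {exc}") from exc
        return RateFit(float(popt[1]), float(np.sqrt(pcov[1, 1])), d.size, "histogram")
    raise ValueError(f"unknown method {method!r}")


def association_rate(unbound_rate: float, concentration: float) -> float:
    """k_on = (unbound-state exit rate) / (ligand concentration), 1/(uM s)."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return unbound_rate / concentration


def dissociation_constant(k_off: float, k_on: float) -> float:
    """K_D = k_off / k_on, in uM."""
    if k_on <= 0:
        raise ValueError("k_on must be > 0")
    return k_off / k_on


def _censored_mle(
    dwells: np.ndarray, censored_time: float, censored_events: int, delta: float
) -> RateFit:
    """Exponential rate MLE with censored observation time.

    rate = events / (total time - events * delta): interior dwells each
    contribute one observed exit; censored runs contribute their duration
    (and an exit, for first runs whose end is seen).  This removes the
    window-censoring bias of the interior-mean estimator, which otherwise
    under-samples long dwells in finite traces.
    """
    n_events = dwells.size + censored_events
    total = float(dwells.sum()) + censored_time
    if n_events < 10:
        raise AnalysisError(f"need >= 10 observed exits, got {n_events}")
    denom = total - n_events * delta
    if denom <= 0:
        raise FitError("observed time does not exceed the discretization offset")
    rate = n_events / denom
    return RateFit(rate, rate / np.sqrt(n_events), n_events, "mle-censored")


def rates_from_dwells(
    dwells: DwellTimeSet,
    method: str = "mle",
    frame_interval: float = 0.0,
) -> KineticRates:
    """Full kinetic summary from pooled bound/unbound dwell sets.

    With ``method="mle"`` and censored-run information present, the
    censoring-aware MLE (events over total state time) is used; otherwise
    the plain per-state dwell fit.
    """
    if dwells.concentration is None:
        raise AnalysisError("dwell set has no concentration; cannot compute k_on")
    delta = frame_interval / 2.0
    has_censored = dwells.bound_censored_time > 0 or dwells.unbound_censored_time > 0
    if method == "mle" and has_censored:
        off = _censored_mle(
            dwells.bound_dwells, dwells.bound_censored_time, dwells.bound_censored_events, delta
        )
        unbound = _censored_mle(
            dwells.unbound_dwells,
            dwells.unbound_censored_time,
            dwells.unbound_censored_events,
            delta,
        )
    else:
        off = fit_dwell_rate(dwells.bound_dwells, method, frame_interval)
        unbound = fit_dwell_rate(dwells.unbound_dwells, method, frame_interval)
    k_on = association_rate(unbound.rate, dwells.concentration)
    return KineticRates(
        k_off=off.rate,
        k_on=k_on,
        kd=dissociation_constant(off.rate, k_on),
        se_k_off=off.se,
        se_k_on=unbound.se / dwells.concentration,
        n_bound=off.n,
        n_unbound=unbound.n,
    )
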