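"""Synthetic smFRET trace generation with known ground truth.

The generator is the exact inverse of the intensity-correction cascade used
by the analysis stages: per frame it computes an occupancy-weighted FRET
efficiency from a continuous-time Markov chain over conformational states,
converts it to ideal donor/acceptor photon signals, applies the gamma factor
and the two channel-leakage fractions in the forward direction, and adds
Gaussian read noise last.  Running the correction equations with the same
(alpha, beta, gamma) on a noiseless trace therefore returns the ground-truth
efficiency to machine precision, which makes every downstream stage testable
end to end without experimental data.

Defaults mirror the acquisition conditions of the experiments being
emulated: 10 Hz frame rate, 1000 frames (100 s), donor->acceptor leakage
1.7 %, acceptor->donor leakage 16.5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "TraceSimConfig",
    "BindingSimConfig",
    "TraceTruth",
    "Trace",
    "simulate_fret_trace",
    "simulate_binding_trace",
    "simulate_cohort",
    "sample_efficiency_mixture",
    "write_traces",
    "read_traces",
    "write_truth",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TraceSimConfig:
    """Parameters of a two-channel FRET trace simulation.

    ``state_efficiencies`` lists the FRET efficiency of each conformational
    state; ``transition_rates`` is a K x K matrix of per-second rates between
    states (diagonal ignored).  ``total_intensity`` is the expected detected
    signal per frame in arbitrary camera units; ``noise_sd`` is the additive
    Gaussian read-noise SD applied independently per channel and frame.
    ``efficiency_jitter_sd`` adds static per-molecule heterogeneity: each
    trace draws its own state efficiencies from a normal distribution around
    the configured values (truncated to [0, 1]), emulating the molecule-to-
    molecule spread seen in measured efficiency histograms.
    """

    state_efficiencies: Sequence[float] = (0.83,)
    transition_rates: Sequence[Sequence[float]] = ((0.0,),)
    total_intensity: float = 1000.0
    noise_sd: float = 60.0
    alpha: float = 0.165
    beta: float = 0.017
    gamma: float = 1.0
    donor_bleach_rate: float = 0.005
    acceptor_bleach_rate: float = 0.02
    frame_interval: float = 0.1
    n_frames: int = 1000
    n_traces: int = 1
    efficiency_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        eff = np.asarray(self.state_efficiencies, dtype=float)
        rates = np.atleast_2d(np.asarray(self.transition_rates, dtype=float))
        if eff.ndim != 1 or eff.size == 0:
            raise ConfigError("state_efficiencies must be a non-empty 1-D sequence")
        if np.any(eff < 0) or np.any(eff > 1):
            raise ConfigError("state efficiencies must lie in [0, 1]")
        if rates.shape != (eff.size, eff.size):
            raise ConfigError(
                f"transition_rates must be {eff.size}x{eff.size}, got {rates.shape}"
            )
        off_diag = rates[~np.eye(eff.size, dtype=bool)]
        if off_diag.size and np.any(off_diag < 0):
            raise ConfigError("off-diagonal transition rates must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.gamma <= 0:
            raise ConfigError("gamma must be > 0")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.total_intensity <= 0:
            raise ConfigError("total_intensity must be > 0")
        if self.noise_sd < 0 or self.efficiency_jitter_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ConfigError("bleach rates must be >= 0")
        if self.n_frames < 0 or self.n_traces < 0:
            raise ConfigError("n_frames and n_traces must be >= 0")
        self.state_efficiencies = eff
        self.transition_rates = rates


@dataclass
class BindingSimConfig:
    """Parameters of a binding-burst (intermolecular FRET) simulation.

    The tethered molecule alternates between unbound and bound states with
    exponential dwells: bound dwells end at rate ``k_off`` (1/s), unbound
    dwells end at rate ``k_on * concentration`` with ``k_on`` in 1/(uM s)
    and ``concentration`` in uM.  The acceptor channel reports
    ``bound_acceptor_level`` while bound and ``baseline_level`` otherwise;
    the donor channel stays at ``donor_level`` because the donor-labelled
    ligand is in large excess in solution.
    """

    k_off: float = 0.12
    k_on: float = 1.62
    concentration: float = 0.1
    bound_acceptor_level: float = 800.0
    baseline_level: float = 0.0
    donor_level: float = 500.0
    noise_sd: float = 60.0
    frame_interval: float = 0.1
    n_frames: int = 1000
    n_traces: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_off <= 0 or self.k_on <= 0 or self.concentration <= 0:
            raise ConfigError("k_off, k_on and concentration must be > 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_frames < 0 or self.n_traces < 0:
            raise ConfigError("n_frames and n_traces must be >= 0")


# ---------------------------------------------------------------------------
# trace containers


@dataclass
class TraceTruth:
    """Ground truth attached to a simulated trace."""

    state_path: np.ndarray | None = None  # majority-occupancy state per frame
    efficiency_path: np.ndarray | None = None  # occupancy-weighted E per frame
    state_efficiencies: np.ndarray | None = None  # per-molecule values
    acceptor_bleach_frame: int | None = None
    donor_bleach_frame: int | None = None
    acceptor_bleach_time: float | None = None
    donor_bleach_time: float | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    subpopulation: str | None = None
    event_times: np.ndarray | None = None  # exact state-change times (s)
    event_states: np.ndarray | None = None


@dataclass
class Trace:
    """A donor/acceptor intensity time trace for one molecule."""

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float = 0.1
    condition: dict = field(default_factory=dict)
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ConfigError("donor and acceptor must be equal-length 1-D series")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


# ---------------------------------------------------------------------------
# continuous-time Markov chain machinery


def _simulate_ctmc(
    rates: np.ndarray, t_total: float, rng: np.random.Generator, start: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie simulation of a CTMC; returns (event_times, states).

    ``event_times[0] == 0`` and ``states[i]`` holds on
    [event_times[i], event_times[i+1]).  The start state is drawn from the
    stationary distribution of the embedded chain when not given (uniform
    for a single state or an all-zero rate matrix).
    """
    k = rates.shape[0]
    exit_rates = rates.sum(axis=1) - np.diag(rates)
    if start is None:
        start = int(rng.integers(k)) if k > 1 else 0
    times = [0.0]
    states = [start]
    t = 0.0
    s = start
    while True:
        lam = exit_rates[s]
        if lam <= 0:
            break
        t += rng.exponential(1.0 / lam)
        if t >= t_total:
            break
        p = rates[s].copy()
        p[s] = 0.0
        s = int(rng.choice(k, p=p / p.sum()))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _frame_occupancy(
    event_times: np.ndarray,
    event_states: np.ndarray,
    n_frames: int,
    dt: float,
    n_states: int,
) -> np.ndarray:
    """Fraction of each frame spent in each state, shape (n_frames, K)."""
    occ = np.zeros((n_frames, n_states))
    t_total = n_frames * dt
    bounds = np.append(event_times, t_total)
    for i, s in enumerate(event_states):
        t0, t1 = bounds[i], min(bounds[i + 1], t_total)
        if t1 <= t0:
            continue
        f0 = int(t0 / dt)
        f1 = min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            lo = max(t0, f * dt)
            hi = min(t1, (f + 1) * dt)
            if hi > lo:
                occ[f, s] += (hi - lo) / dt
    return occ


# ---------------------------------------------------------------------------
# forward model


def _mix_channels(
    d_star: np.ndarray, a_star: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward channel mixing: ideal signals -> observed intensities.

    The acceptor channel collects a fraction ``beta`` of the ideal donor
    signal; the donor channel collects a fraction ``alpha`` of the observed
    acceptor channel.  This is the exact inverse of the leakage correction
    D_c = I_D - alpha*I_A, A_c = I_A - beta*D_c.
    """
    i_a = a_star + beta * d_star
    i_d = d_star + alpha * i_a
    return i_d, i_a


def simulate_fret_trace(
    config: TraceSimConfig,
    seed: int | np.random.SeedSequence | None = None,
    molecule_id: str = "mol0",
) -> Trace:
    """Simulate one conformational smFRET trace with ground truth.

    Pre-bleach ideal signals are ``D* = I(1 - E_f)`` and
    ``A* = gamma * I * E_f`` with ``E_f`` the occupancy-weighted efficiency
    of the frame.  After the acceptor bleaches, ``A* = 0`` and
    ``D* = I`` (all excitation energy reports in the donor channel, which
    is what makes the bleach-step ratio equal gamma).  After the donor
    bleaches both signals are zero.  Bleaching takes effect at the first
    frame boundary after the exponential bleach time.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_frames
    dt = config.frame_interval
    k = len(config.state_efficiencies)

    eff = np.array(config.state_efficiencies, dtype=float)
    if config.efficiency_jitter_sd > 0:
        # truncated normal by rejection: clipping would pile mass at 0 and 1
        eff = rng.normal(eff, config.efficiency_jitter_sd)
        for _ in range(1000):
            bad = (eff < 0.0) | (eff > 1.0)
            if not bad.any():
                break
            eff[bad] = rng.normal(
                np.asarray(config.state_efficiencies, float)[bad],
                config.efficiency_jitter_sd,
            )
        else:
            eff = np.clip(eff, 0.0, 1.0)

    event_times, event_states = _simulate_ctmc(
        np.asarray(config.transition_rates, float), n * dt, rng
    )
    occ = _frame_occupancy(event_times, event_states, n, dt, k)
    e_frame = occ @ eff
    state_path = np.argmax(occ, axis=1) if n else np.zeros(0, dtype=int)

    # exponential single-step bleach times (inf when the rate is zero)
    t_ab = rng.exponential(1.0 / config.acceptor_bleach_rate) if config.acceptor_bleach_rate > 0 else np.inf
    t_db = rng.exponential(1.0 / config.donor_bleach_rate) if config.donor_bleach_rate > 0 else np.inf
    f_ab = int(np.ceil(t_ab / dt)) if t_ab / dt < n else None
    f_db = int(np.ceil(t_db / dt)) if t_db / dt < n else None
    if f_ab is not None and f_db is not None and f_db <= f_ab:
        f_ab = None  # donor died first: the acceptor step is never observed

    i_tot = config.total_intensity
    d_star = i_tot * (1.0 - e_frame)
    a_star = config.gamma * i_tot * e_frame
    if f_ab is not None:
        d_star[f_ab:] = i_tot
        a_star[f_ab:] = 0.0
    if f_db is not None:
        d_star[f_db:] = 0.0
        a_star[f_db:] = 0.0

    i_d, i_a = _mix_channels(d_star, a_star, config.alpha, config.beta)
    if config.noise_sd > 0:
        i_d = i_d + rng.normal(0.0, config.noise_sd, n)
        i_a = i_a + rng.normal(0.0, config.noise_sd, n)

    truth = TraceTruth(
        state_path=state_path,
        efficiency_path=e_frame,
        state_efficiencies=eff,
        acceptor_bleach_frame=f_ab,
        donor_bleach_frame=f_db,
        acceptor_bleach_time=t_ab if np.isfinite(t_ab) else None,
        donor_bleach_time=t_db if np.isfinite(t_db) else None,
        alpha=config.alpha,
        beta=config.beta,
        gamma=config.gamma,
        event_times=event_times,
        event_states=event_states,
    )
    return Trace(molecule_id, i_d, i_a, dt, truth=truth)


def simulate_binding_trace(
    config: BindingSimConfig,
    seed: int | np.random.SeedSequence | None = None,
    molecule_id: str = "mol0",
) -> Trace:
    """Simulate one binding-burst trace (alternating exponential dwells).

    State 1 (bound) emits ``bound_acceptor_level`` in the acceptor channel,
    state 0 emits ``baseline_level``; the camera integrates, so frames are
    occupancy-weighted between the two levels.  The donor channel is
    constant.  Truth records the exact event times and the majority-
    occupancy discretized path.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_frames
    dt = config.frame_interval
    rates = np.array(
        [[0.0, config.k_on * config.concentration], [config.k_off, 0.0]]
    )
    event_times, event_states = _simulate_ctmc(rates, n * dt, rng, start=0)
    occ = _frame_occupancy(event_times, event_states, n, dt, 2)
    bound_frac = occ[:, 1]
    state_path = (bound_frac > 0.5).astype(int)

    acceptor = config.baseline_level + bound_frac * (
        config.bound_acceptor_level - config.baseline_level
    )
    donor = np.full(n, config.donor_level)
    if config.noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, n)
        donor = donor + rng.normal(0.0, config.noise_sd, n)

    truth = TraceTruth(
        state_path=state_path,
        efficiency_path=bound_frac,
        event_times=event_times,
        event_states=event_states,
    )
    return Trace(
        molecule_id,
        donor,
        acceptor,
        dt,
        condition={"concentration_uM": config.concentration},
        truth=truth,
    )


def simulate_cohort(
    subpopulations: Mapping[str, TraceSimConfig | BindingSimConfig],
    weights: Mapping[str, float],
    n_traces: int,
    seed: int | np.random.SeedSequence | None = None,
) -> list[Trace]:
    """Simulate a cohort of traces drawn from weighted subpopulations.

    Each trace first draws a subpopulation label with the given weights,
    then simulates from that subpopulation's config with an independent
    child seed; truth records the label.  Deterministic given the seed.
    """
    labels = list(subpopulations)
    if set(weights) != set(labels):
        raise ConfigError("weights must be keyed exactly by the subpopulation labels")
    w = np.array([weights[l] for l in labels], dtype=float)
    if np.any(w < 0):
        raise ConfigError("subpopulation weights must be >= 0")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError(f"subpopulation weights must sum to 1, got {w.sum():g}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(n_traces)
    traces: list[Trace] = []
    for i in range(n_traces):
        label = labels[int(label_rng.choice(len(labels), p=w))]
        cfg = subpopulations[label]
        sim = simulate_binding_trace if isinstance(cfg, BindingSimConfig) else simulate_fret_trace
        tr = sim(cfg, seed=children[i], molecule_id=f"mol{i:05d}")
        tr.condition["subpopulation"] = label
        if tr.truth is not None:
            tr.truth.subpopulation = label
        traces.append(tr)
    return traces


def sample_efficiency_mixture(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw per-molecule efficiencies from a Gaussian mixture.

    Models the molecule-level spread of a measured efficiency histogram
    directly (no truncation: corrected efficiencies may fall slightly
    outside [0, 1]).
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    w = np.asarray(weights, float)
    if not (means.shape == sds.shape == w.shape):
        raise ConfigError("means, sds and weights must have equal length")
    if np.any(sds <= 0) or np.any(w < 0):
        raise ConfigError("sds must be > 0 and weights >= 0")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w)
    return rng.normal(means[comp], sds[comp])


# ---------------------------------------------------------------------------
# delimited-text I/O


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    """Long-format table: molecule_id, frame, time_s, donor, acceptor."""
    parts = []
    for tr in traces:
        n = len(tr)
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(n),
                    "time_s": tr.times,
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["molecule_id", "frame", "time_s", "donor", "acceptor"])
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: Sequence[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path, frame_interval: float | None = None) -> list[Trace]:
    """Read traces from the long-format CSV written by :func:`write_traces`."""
    df = pd.read_csv(path)
    required = {"molecule_id", "frame", "donor", "acceptor"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        if frame_interval is None:
            t = grp["time_s"].to_numpy()
            dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.1
        else:
            dt = frame_interval
        traces.append(
            Trace(str(mol), grp["donor"].to_numpy(), grp["acceptor"].to_numpy(), dt)
        )
    return traces


def write_truth(traces: Sequence[Trace], path) -> None:
    """Companion per-molecule ground-truth summary CSV."""
    rows = []
    for tr in traces:
        t = tr.truth
        if t is None:
            continue
        rows.append(
            {
                "molecule_id": tr.molecule_id,
                "subpopulation": t.subpopulation,
                "acceptor_bleach_frame": t.acceptor_bleach_frame,
                "donor_bleach_frame": t.donor_bleach_frame,
                "gamma": t.gamma,
                "alpha": t.alpha,
                "beta": t.beta,
                "mean_efficiency": (
                    float(np.mean(t.efficiency_path)) if t.efficiency_path is not None and len(t.efficiency_path) else np.nan
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
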