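"""End-to-end pipelines, run configuration, and provenance manifests.

Two pipelines mirror the two experiment classes the package emulates:

* conformation: traces -> correction -> single-pair selection -> per-
  molecule efficiencies -> two-Gaussian decomposition -> population
  percentages with split-half SDs;
* binding: burst traces -> two-state idealization -> interior dwell
  times -> exponential rates -> k_off, k_on, K_D.

A run is described by one structured config (YAML on disk or a plain
nested dict); unknown keys are rejected so that typos cannot silently
corrupt an analysis.  All randomness derives from a single root seed.
Every run writes a manifest recording the config snapshot, the seed, and
a content hash of each output file, so re-running with the same manifest
reproduces all stochastic steps bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corrections as corr
from . import kinetics as kin
from . import populations as pop
from . import synth
from .errors import AnalysisError, ConfigError

__all__ = [
    "RunManifest",
    "load_config",
    "run_conformation_pipeline",
    "run_binding_pipeline",
]

log = logging.getLogger("smfretkit")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    pipeline: str
    config: dict
    root_seed: int | None
    outputs: dict = field(default_factory=dict)  # path -> sha256
    created: str = ""

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path) -> None:
        self.created = self.created or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    p = Path(path_or_dict)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {p} did not parse to a mapping")
    return cfg


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


def _get_traces(section: dict, kind: str, seed_seq: np.random.SeedSequence):
    """Traces from a ``simulate`` block or an ``input_traces`` CSV path."""
    if "simulate" in section and "input_traces" in section:
        raise ConfigError("give either 'simulate' or 'input_traces', not both")
    if "input_traces" in section:
        path = Path(section["input_traces"])
        if not path.exists():
            raise ConfigError(f"input trace file not found: {path}")
        return synth.read_traces(path)
    if "simulate" not in section:
        raise ConfigError("section needs a 'simulate' block or 'input_traces' path")
    sim = section["simulate"]
    _check_keys(sim, {"subpopulations", "weights", "n_traces"}, "simulate")
    cfg_cls = synth.BindingSimConfig if kind == "binding" else synth.TraceSimConfig
    subpops = {
        label: cfg_cls(**kw) for label, kw in sim["subpopulations"].items()
    }
    weights = sim.get("weights") or {l: 1.0 / len(subpops) for l in subpops}
    return synth.simulate_cohort(subpops, weights, int(sim["n_traces"]), seed_seq)


# ---------------------------------------------------------------------------
# conformation pipeline


_CONFORMATION_KEYS = {
    "simulate",
    "input_traces",
    "alpha",
    "beta",
    "gamma",
    "mode",
    "n_frames",
    "bin_width",
    "range",
    "metric",
    "window",
}


def run_conformation_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Population analysis of conformational smFRET traces.

    Returns a dict with the kept/dropped accounting, the two-Gaussian fit,
    and one :class:`~smfretkit.populations.PopulationResult` per component,
    with split-half SDs.  When ``out_dir`` is given, writes the efficiency
    samples, histogram, fit parameters and results as CSV plus a manifest.
    """
    cfg = load_config(config)
    _check_keys(cfg, {"seed", "conformation", "out_dir"}, "config")
    section = dict(cfg.get("conformation") or {})
    _check_keys(section, _CONFORMATION_KEYS, "conformation")
    root_seed = seed if seed is not None else cfg.get("seed")
    ss = np.random.SeedSequence(root_seed)
    sim_ss, split_ss = ss.spawn(2)

    traces = _get_traces(section, "conformation", sim_ss)
    if not traces:
        raise AnalysisError("no input traces")
    window = int(section.get("window", 10))
    kept, reasons = corr.select_single_pair_molecules(
        traces,
        corr.CorrectionSet(
            alpha=float(section.get("alpha", corr.DEFAULT_ALPHA)),
            beta=float(section.get("beta", corr.DEFAULT_BETA)),
        ),
        window=window,
    )
    log.info("selection kept %d / %d molecules", len(kept), len(traces))
    for mol, why in reasons.items():
        log.debug("dropped %s: %s", mol, why)
    assert len(kept) + len(reasons) == len(traces)

    gamma_cfg = section.get("gamma", 1.0)
    mode = section.get("mode", "leakage")
    if gamma_cfg == "estimate":
        gamma, _ = corr.cohort_gamma(
            kept,
            corr.CorrectionSet(
                alpha=float(section.get("alpha", corr.DEFAULT_ALPHA)),
                beta=float(section.get("beta", corr.DEFAULT_BETA)),
            ),
            window=window,
        )
        mode = "gamma"
    else:
        gamma = float(gamma_cfg)
    cset = corr.CorrectionSet(
        alpha=float(section.get("alpha", corr.DEFAULT_ALPHA)),
        beta=float(section.get("beta", corr.DEFAULT_BETA)),
        gamma=gamma,
    )

    n_frames = int(section.get("n_frames", pop.DEFAULT_N_FRAMES))
    samples = []
    for tr in kept:
        events = corr.detect_bleach_events(tr, window)
        first = min(
            [f for f in (events.acceptor_bleach_frame, events.donor_bleach_frame) if f is not None],
            default=None,
        )
        try:
            samples.append(
                pop.per_molecule_efficiency(tr, cset, n_frames, mode, bleach_frame=first)
            )
        except AnalysisError:
            reasons[tr.molecule_id] = "bleach before accumulation window"
    log.info("accumulated efficiencies for %d molecules", len(samples))
    if len(samples) + len(reasons) != len(traces):
        raise AnalysisError("molecule accounting does not reconcile")

    bin_width = float(section.get("bin_width", pop.DEFAULT_BIN_WIDTH))
    hist_range = tuple(section.get("range", pop.DEFAULT_RANGE))
    fit = pop.fit_two_gaussians(samples, bin_width, hist_range)
    results = {}
    for which in ("low", "high"):
        frac = pop.population_fraction(fit, which)

        def stat(subset, which=which):
            return pop.population_fraction(
                pop.fit_two_gaussians(subset, bin_width, hist_range), which
            ).percent

        _, sd = pop.split_half_sd(samples, stat, seed=int(split_ss.generate_state(1)[0] % 2**31))
        results[which] = pop.PopulationResult(
            metric=section.get("metric", f"% {which} population"),
            percent=frac.percent,
            sd=sd,
            n_molecules=len(samples),
        )

    out = {
        "n_input": len(traces),
        "n_kept": len(samples),
        "dropped": reasons,
        "gamma": gamma,
        "fit": fit,
        "results": results,
    }
    if out_dir is not None:
        out["manifest"] = _write_conformation_outputs(
            Path(out_dir), cfg, root_seed, samples, fit, results, bin_width, hist_range
        )
    return out


def _write_conformation_outputs(out_dir, cfg, root_seed, samples, fit, results, bin_width, hist_range):
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("conformation", cfg, root_seed)
    samples_csv = out_dir / "efficiency_samples.csv"
    pd.DataFrame(
        [{"molecule_id": s.molecule_id, "efficiency": s.efficiency, "mode": s.correction_mode} for s in samples]
    ).to_csv(samples_csv, index=False)
    hist = pop.build_histogram([s.efficiency for s in samples], bin_width, hist_range)
    hist_csv = out_dir / "histogram.csv"
    pd.DataFrame({"bin_center": hist.bin_centers, "count": hist.counts}).to_csv(hist_csv, index=False)
    fit_csv = out_dir / "fit_parameters.csv"
    pd.DataFrame(
        [
            {"component": name, "mean": c.mean, "sd": c.sd, "amplitude": c.amplitude, "area": c.area}
            for name, c in (("low", fit.low), ("high", fit.high))
        ]
    ).to_csv(fit_csv, index=False)
    results_csv = out_dir / "population_results.csv"
    pd.DataFrame(
        [
            {"metric": r.metric, "component": k, "percent": r.percent, "sd": r.sd, "n_molecules": r.n_molecules}
            for k, r in results.items()
        ]
    ).to_csv(results_csv, index=False)
    for p in (samples_csv, hist_csv, fit_csv, results_csv):
        manifest.record(p)
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# binding pipeline


_BINDING_KEYS = {"simulate", "input_traces", "concentration_uM", "method", "min_events"}


def run_binding_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Dwell-time kinetics of binding-burst traces.

    Idealizes each trace's acceptor channel, pools interior dwell times,
    and fits exponential rates.  A condition with fewer than ``min_events``
    usable dwells per state is reported as ``"no binding observed"``
    instead of rates.
    """
    cfg = load_config(config)
    _check_keys(cfg, {"seed", "binding", "out_dir"}, "config")
    section = dict(cfg.get("binding") or {})
    _check_keys(section, _BINDING_KEYS, "binding")
    root_seed = seed if seed is not None else cfg.get("seed")
    ss = np.random.SeedSequence(root_seed)

    traces = _get_traces(section, "binding", ss)
    if not traces:
        raise AnalysisError("no input traces")
    concentration = section.get("concentration_uM")
    if concentration is None:
        concentration = traces[0].condition.get("concentration_uM")
    if concentration is None:
        raise ConfigError("binding pipeline needs 'concentration_uM'")
    concentration = float(concentration)

    frame_interval = traces[0].frame_interval
    pooled = kin.DwellTimeSet(np.empty(0), np.empty(0), 0, concentration)
    n_degenerate = 0
    for tr in traces:
        path = kin.idealize_two_state(tr.acceptor)
        if path.degenerate:
            n_degenerate += 1
            continue
        pooled = pooled.pooled_with(
            kin.extract_dwells(path, tr.frame_interval, concentration=concentration)
        )
    log.info(
        "pooled %d bound / %d unbound interior dwells from %d traces (%d degenerate)",
        pooled.bound_dwells.size,
        pooled.unbound_dwells.size,
        len(traces),
        n_degenerate,
    )

    min_events = int(section.get("min_events", 10))
    out = {
        "n_traces": len(traces),
        "n_bound_dwells": int(pooled.bound_dwells.size),
        "n_unbound_dwells": int(pooled.unbound_dwells.size),
        "concentration_uM": concentration,
    }
    if min(pooled.bound_dwells.size, pooled.unbound_dwells.size) < min_events:
        out["status"] = "no binding observed"
        out["rates"] = None
    else:
        out["status"] = "ok"
        out["rates"] = kin.rates_from_dwells(
            pooled, section.get("method", "mle"), frame_interval
        )
    if out_dir is not None:
        out["manifest"] = _write_binding_outputs(Path(out_dir), cfg, root_seed, out)
    return out


def _write_binding_outputs(out_dir, cfg, root_seed, out):
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("binding", cfg, root_seed)
    rates_csv = out_dir / "rates.csv"
    r = out["rates"]
    row = {
        "status": out["status"],
        "concentration_uM": out["concentration_uM"],
        "n_bound_dwells": out["n_bound_dwells"],
        "n_unbound_dwells": out["n_unbound_dwells"],
    }
    if r is not None:
        row.update(
            k_off=r.k_off, k_on=r.k_on, kd=r.kd, se_k_off=r.se_k_off, se_k_on=r.se_k_on
        )
    pd.DataFrame([row]).to_csv(rates_csv, index=False)
    manifest.record(rates_csv)
    manifest.write(out_dir / "manifest.json")
    return manifest
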