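"""Experiment driver: runs a configured schedule and writes its outputs.

Each schedule produces CSV traces, CSV metrics and (optionally) figures in
the configured output directory.  All randomness flows from the experiment
seed, so (config, seed) -> identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .analysis import burst_series, trials_to_dip, window_extremum
from .config import ExperimentConfig
from .io import write_metrics, write_traces
from .network import build_network
from .protocol import (
    ASSOCIATIONS,
    TrialSpec,
    make_trial,
    run_magnitude_sweep,
    run_probe_schedule,
    run_standard_protocol,
    run_trial,
    summarize_sweep,
)

__all__ = ["run_experiment"]

log = logging.getLogger("vtanet")


def _standard(cfg: ExperimentConfig, out: Path) -> None:
    net = build_network(cfg.network, np.random.default_rng(cfg.seed))
    record = tuple(dict.fromkeys([*cfg.record, "VTA"]))
    res = run_standard_protocol(net, cfg.n_sensitization, cfg.n_conditioning,
                                record=record)
    log.info("standard protocol done: %d sensitization + %d conditioning trials",
             len(res.sensitization), len(res.conditioning))
    keep = [t for t in res.conditioning
            if t.trial_index in (1, 5, cfg.n_conditioning)]
    write_traces(keep, out / "traces.csv", "standard")
    rows = []
    for a in ASSOCIATIONS:
        trials = res.trials(a)
        iv = int(ASSOCIATIONS[a].interval * 1000)
        cs = burst_series(trials, "cs_onset")
        us = burst_series(trials, "us_onset")
        for k, (c, u) in enumerate(zip(cs, us), start=1):
            rows += [
                dict(experiment="standard", assoc_id=a, trial=k,
                     metric="cs_burst", value=c),
                dict(experiment="standard", assoc_id=a, trial=k,
                     metric="us_burst", value=u),
            ]
        rows.append(dict(experiment="standard", assoc_id=a,
                         trial=cfg.n_conditioning, metric="us_burst_duration_ms",
                         value=analysis.burst_duration(trials[-1]["VTA"], 1000 + iv)))
    write_metrics(rows, out / "metrics.csv")


def _probes(cfg: ExperimentConfig, out: Path) -> None:
    net = build_network(cfg.network, np.random.default_rng(cfg.seed))
    metrics, _ = run_probe_schedule(net, cfg.n_sensitization, cfg.n_conditioning)
    rows = [dict(experiment="probes", assoc_id=m.assoc_id, trial=m.trial_index,
                 metric="probe_min_vta", value=m.min_vta) for m in metrics]
    rows += [dict(experiment="probes", assoc_id=m.assoc_id, trial=m.trial_index,
                  metric="probe_max_nacc", value=m.max_nacc) for m in metrics]
    for a in ASSOCIATIONS:
        rows.append(dict(experiment="probes", assoc_id=a, trial=0,
                         metric="trials_to_dip", value=trials_to_dip(metrics, a)))
        log.info("association %d: first omission dip after %s conditioning trials",
                 a, trials_to_dip(metrics, a))
    write_metrics(rows, out / "probe_metrics.csv")


def _sweep(cfg: ExperimentConfig, out: Path) -> None:
    df = run_magnitude_sweep(cfg.magnitudes, cfg.networks, cfg.seed,
                             assoc_id=cfg.assoc_id,
                             n_sensitization=cfg.n_sensitization,
                             n_conditioning=cfg.n_conditioning,
                             cfg=cfg.network)
    df.to_csv(out / "sweep_raw.csv", index=False)
    summarize_sweep(df).to_csv(out / "sweep_summary.csv", index=False)
    log.info("magnitude sweep done: %d magnitudes x %d networks",
             len(cfg.magnitudes), cfg.networks)


def _single_probe(cfg: ExperimentConfig, out: Path, variant: str) -> None:
    """Train the standard protocol, then run one omission / early trial."""
    net = build_network(cfg.network, np.random.default_rng(cfg.seed))
    run_standard_protocol(net, cfg.n_sensitization, cfg.n_conditioning,
                          record=())
    record = tuple(dict.fromkeys([*cfg.record, "VTA", "NAcc"]))
    tr = run_trial(net, make_trial(TrialSpec(cfg.assoc_id, variant)),
                   learning_on=False, record=record)
    write_traces([tr], out / f"{variant}_trace.csv", variant)
    iv = int(ASSOCIATIONS[cfg.assoc_id].interval * 1000)
    t_ref = tr.events.get("expected_us", tr.events.get("trained_us", 1000 + iv))
    post = tr["VTA"][t_ref:t_ref + 1000]
    rows = [dict(experiment=variant, assoc_id=cfg.assoc_id, trial=0,
                 metric="min_vta_post_expected", value=float(post.min()))]
    if "us_onset" in tr.events:
        rows.append(dict(experiment=variant, assoc_id=cfg.assoc_id, trial=0,
                         metric="us_burst",
                         value=window_extremum(tr["VTA"], tr.events["us_onset"],
                                               100, "max")))
    write_metrics(rows, out / f"{variant}_metrics.csv")


def run_experiment(cfg: ExperimentConfig, figures: bool = True) -> Path:
    """Run the configured schedule; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config_used.yaml")
    log.info("schedule=%s seed=%d out=%s", cfg.schedule, cfg.seed, out)
    if cfg.schedule == "standard":
        _standard(cfg, out)
    elif cfg.schedule == "probes":
        _probes(cfg, out)
    elif cfg.schedule == "magnitude_sweep":
        _sweep(cfg, out)
    elif cfg.schedule in ("omission", "early"):
        _single_probe(cfg, out, cfg.schedule)
    if figures:
        from .plotting import render_outputs
        render_outputs(out)
    return out
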