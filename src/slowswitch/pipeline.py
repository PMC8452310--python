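"""End-to-end orchestration: detection -> metrics -> mixture -> labeling ->
connectivity -> cycle dynamics, with deterministic file outputs.

A :class:`RunConfig` carries every tunable with the canonical defaults
(0.3-4.0 Hz detection band, -40 uV negative peak, 75 uV peak-to-peak,
125-1500 ms negative and <= 1000 ms positive deflections, 10-16 Hz sigma
band with a 75th-percentile envelope threshold and 0.5-3 s durations,
p = 0.01 max-statistics threshold).  ``run_pipeline`` executes the stages
and writes tidy CSV/JSON artifacts plus a manifest; identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import connectivity_analysis
from .cycles import cycle_percentages, fit_cycle_dynamics
from .data import CLUSTERS, Hypnogram, Recording
from .detection import (cluster_density, detect_slow_waves, detect_spindles,
                        slow_wave_density, tag_cooccurrence)
from .filters import bandpass_delta, bandpass_sigma
from .io import (read_edf, read_hypnogram, waves_to_frame, spindles_to_frame,
                 write_edf, write_ground_truth, write_hypnogram, write_table)
from .mixture import classify_waves, fit_mixture, aic_trace, switcher_probability
from .synthetic import SyntheticConfig, generate_recording
from .transition import attach_phase_maps

logger = logging.getLogger(__name__)

STAGES = ("detect", "classify", "connectivity", "cycles")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"                  # "synthetic" | "files"
    edf_path: Optional[str] = None
    hypnogram_path: Optional[str] = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "swswitch_out"
    seed: int = 0
    write_raw: bool = False                  # export EDF/hypnogram of synthetic input
    # detection
    delta_band: tuple[float, float] = (0.3, 4.0)
    phase_band: tuple[float, float] = (0.16, 4.0)
    sigma_band: tuple[float, float] = (10.0, 16.0)
    neg_amp_max: float = -40.0
    p2p_min: float = 75.0
    neg_dur_bounds: tuple[float, float] = (0.125, 1.5)
    pos_dur_max: float = 1.0
    spindle_percentile: float = 75.0
    spindle_dur_bounds: tuple[float, float] = (0.5, 3.0)
    # mixture
    k_max: int = 5
    min_fit_values: int = 50
    fit_clusters: bool = False               # per-cluster fits alongside the pooled one
    # connectivity
    run_connectivity: bool = True
    n_perm: int = 1000
    p_value: float = 0.01
    min_events: int = 20
    stratify_switchers: bool = True
    stratify_spindles: bool = False
    # cycles
    max_fit_cycles: int = 3

    def to_dict(self) -> dict:
        # out_dir is where results land, not what they are: keep it out of
        # the manifest so identical analyses give identical artifacts
        d = asdict(self)
        d.pop("out_dir")
        return d

    def param_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunResult:
    recording: Recording
    hypnogram: Hypnogram
    waves: list
    spindles: list
    mixtures: dict
    connectivity: dict
    cycles: Optional[pd.DataFrame]
    decay_fits: dict
    out_dir: Path


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        rec, hyp, truth = generate_recording(config.synthetic)
        return rec, hyp, truth
    if config.mode == "files":
        if not config.edf_path or not config.hypnogram_path:
            raise ValueError("file mode needs edf_path and hypnogram_path")
        rec = read_edf(config.edf_path)
        hyp = read_hypnogram(config.hypnogram_path)
        hyp.check_alignment(rec.n_samples, rec.sampling_rate)
        return rec, hyp, None
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: RunConfig, until: str = "cycles") -> RunResult:
    """Run the pipeline through `until` (one of detect, classify,
    connectivity, cycles) and write artifacts to ``config.out_dir``."""
    if until not in STAGES:
        raise ValueError(f"until must be one of {STAGES}")
    stage_idx = STAGES.index(until)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec, hyp, truth = _load_inputs(config)
    sr = rec.sampling_rate
    if truth is not None and config.write_raw:
        write_edf(out / "recording.edf", rec)
        write_hypnogram(out / "hypnogram.csv", hyp)
        write_ground_truth(out / "ground_truth.json", truth)

    # --- detection ---------------------------------------------------------
    delta = bandpass_delta(rec.signal, sr, *config.delta_band)
    waves = detect_slow_waves(delta, hyp, sr, rec.channel_labels,
                              neg_amp_max=config.neg_amp_max,
                              p2p_min=config.p2p_min,
                              neg_dur_bounds=config.neg_dur_bounds,
                              pos_dur_max=config.pos_dur_max)
    sigma = bandpass_sigma(rec.signal, sr, *config.sigma_band)
    spindles = detect_spindles(sigma, hyp, sr, rec.channel_labels,
                               percentile=config.spindle_percentile,
                               dur_bounds=config.spindle_dur_bounds)
    phase_filtered = bandpass_delta(rec.signal, sr, *config.phase_band)
    attach_phase_maps(phase_filtered, waves, sr, rec.channel_labels)
    tag_cooccurrence(waves, spindles, skip_missing=True)
    logger.info("%d slow waves, %d spindles, %d waves with usable phase",
                len(waves), len(spindles), sum(w.phase_ok for w in waves))

    density = slow_wave_density(waves, hyp) if waves else {}
    density_rows = [{"scope": "channel", "name": ch, "density_per_min": d}
                    for ch, d in sorted(density.items())]
    if waves:
        for name, d in cluster_density(waves, hyp).items():
            density_rows.append({"scope": "cluster", "name": name,
                                 "density_per_min": d})
    write_table(out / "density.csv", pd.DataFrame(density_rows))
    write_table(out / "spindles.csv", spindles_to_frame(spindles))

    mixtures: dict = {}
    connectivity: dict = {}
    cyc_table = None
    decay_fits: dict = {}

    # --- mixture & labeling -------------------------------------------------
    if stage_idx >= STAGES.index("classify"):
        f_tau = np.array([w.f_tau for w in waves])
        if len(f_tau) >= config.min_fit_values:
            k_best = 2
            trace = aic_trace(f_tau, k_max=config.k_max,
                              min_n=config.min_fit_values,
                              random_state=config.seed)
            k_best = min(trace, key=trace.get)
            model = fit_mixture(f_tau, k=2, min_n=config.min_fit_values,
                                random_state=config.seed)
            model.aic_by_k = trace
            mixtures["pooled"] = {"selected_k": k_best, **model.to_dict()}
            classify_waves(waves, model.f_star)
            mixtures["pooled"]["p_slow_empirical"] = switcher_probability(waves)
            if config.fit_clusters:
                for cname, chs in CLUSTERS.items():
                    sub = np.array([w.f_tau for w in waves if w.channel in chs])
                    if len(sub) >= config.min_fit_values:
                        cm = fit_mixture(sub, k=2, min_n=config.min_fit_values,
                                         random_state=config.seed)
                        mixtures[cname] = cm.to_dict()
        else:
            logger.warning("only %d waves; skipping mixture fit", len(f_tau))
        (out / "mixture.json").write_text(json.dumps(mixtures, indent=1,
                                                     sort_keys=True))

    # --- connectivity -------------------------------------------------------
    if stage_idx >= STAGES.index("connectivity") and config.run_connectivity:
        strata = {"all": waves}
        if config.stratify_switchers and mixtures:
            strata = {"slow": [w for w in waves if w.switcher == "slow"],
                      "fast": [w for w in waves if w.switcher == "fast"]}
        if config.stratify_spindles:
            strata = {f"{name}_{tag}": [w for w in ws
                                        if w.has_spindle == (tag == "spindle")]
                      for name, ws in strata.items()
                      for tag in ("spindle", "nospindle")}
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(len(strata))
        gci_rows = []
        for (name, ws), child in zip(sorted(strata.items()), children):
            res = connectivity_analysis(phase_filtered, ws, sr,
                                        rec.channel_labels,
                                        n_perm=config.n_perm, p=config.p_value,
                                        min_events=config.min_events,
                                        seed=child)
            connectivity[name] = res
            for lab in res.pli_symmetric:
                df = pd.DataFrame(res.pli_symmetric[lab],
                                  index=rec.channel_labels,
                                  columns=rec.channel_labels)
                df.to_csv(conn_dir / f"pli_{name}_{lab}.csv",
                          float_format="%.10g")
                mdf = pd.DataFrame(res.significant_mask[lab].astype(int),
                                   index=rec.channel_labels,
                                   columns=rec.channel_labels)
                mdf.to_csv(conn_dir / f"mask_{name}_{lab}.csv")
                gci_rows.append({"stratum": name, "phase": lab,
                                 "phase_rad": res.phase_points[lab],
                                 "threshold": res.null_threshold[lab],
                                 "n_significant": int(res.significant_mask[lab]
                                                      .sum() // 2),
                                 "gci": res.gci[lab]})
        write_table(out / "gci.csv", pd.DataFrame(gci_rows))

    # --- cycle dynamics ------------------------------------------------------
    if stage_idx >= STAGES.index("cycles") and mixtures:
        try:
            cyc_table = cycle_percentages(waves, cycles=hyp.cycles())
            write_table(out / "cycles.csv", cyc_table)
            decay_fits = {k: f.to_dict() for k, f in
                          fit_cycle_dynamics(waves,
                                             max_cycles=config.max_fit_cycles,
                                             cycles=hyp.cycles()).items()}
            (out / "decay_fits.json").write_text(
                json.dumps(decay_fits, indent=1, sort_keys=True))
        except ValueError as exc:
            logger.warning("cycle dynamics skipped: %s", exc)

    # events table written last so switcher labels are final
    write_table(out / "events.csv", waves_to_frame(waves))
    manifest = {
        "package": "slowswitch",
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "config": config.to_dict(),
        "n_waves": len(waves),
        "n_spindles": len(spindles),
        "n_phase_ok": int(sum(w.phase_ok for w in waves)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return RunResult(recording=rec, hypnogram=hyp, waves=waves,
                     spindles=spindles, mixtures=mixtures,
                     connectivity=connectivity, cycles=cyc_table,
                     decay_fits=decay_fits, out_dir=out)
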