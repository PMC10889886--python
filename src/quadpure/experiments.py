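"""Simulator characterization experiments.

These mirror, at desk scale, the bench characterization an operator performs
on the physical instrument: a coarse parallel flow calibration at 1 CV/min
followed by repeated timed dispenses into the fraction collector.  They
exercise the artifact's own synthetic pump model (aliquot-wise Gaussian
relative noise, per-channel step-scale errors), not the hardware the bench
numbers came from, so their outputs characterize the simulator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .control import ConfigRegistry, HardwareController
from .fluidics import FlowSink, FlowSource
from .protocol import DEFAULT_RATE_CV_PER_MIN, ProtocolEngine

#: default synthetic relative noise per dispensed aliquot
DEFAULT_NOISE_SD_REL = 0.01
#: coarse mis-calibration band for uncalibrated pumps (±5%)
DEFAULT_SCALE_ERROR_BAND = 0.05


def _noisy_rig(config_name: str, noise_sd_rel: float,
               scale_errors, registry: Optional[ConfigRegistry],
               sim_name: str) -> tuple[ConfigRegistry, str]:
    registry = registry or ConfigRegistry()
    base = registry.get(config_name)
    cfg = base.model_copy(deep=True)
    cfg.name = sim_name
    for ch_cfg, err in zip(cfg.channels, scale_errors):
        ch_cfg.pump.noise_sd_rel = noise_sd_rel
        ch_cfg.pump.sim_scale_error = float(err)
    registry.register(cfg)
    return registry, sim_name


def fraction_consistency_experiment(
        config_name: str = "histrap_1ml",
        flow_path: str = "buffer",
        n_measurements: int = 30,
        noise_sd_rel: float = DEFAULT_NOISE_SD_REL,
        scale_error_band: float = DEFAULT_SCALE_ERROR_BAND,
        window_min: float = 1.0,
        seed: int = 0,
        calibrate: bool = True,
        registry: Optional[ConfigRegistry] = None) -> pd.DataFrame:
    """Repeated one-minute dispenses across all four channels in parallel.

    Each channel's virtual pump starts coarsely mis-scaled (uniform within
    ±``scale_error_band``) and carries aliquot noise of relative sd
    ``noise_sd_rel``.  All channels are first calibrated in parallel to
    1 CV/min (one measurement window each), then ``n_measurements`` timed
    dispenses are taken per channel, each as a single aliquot.

    Returns a tidy frame with one row per (measurement, channel) and the
    dispensed volume in mL and CV.
    """
    if flow_path not in ("buffer", "load"):
        raise ValueError("flow_path must be 'buffer' or 'load'")
    rng = np.random.default_rng(seed)
    scale_errors = rng.uniform(1.0 - scale_error_band, 1.0 + scale_error_band,
                               size=4)
    registry, name = _noisy_rig(config_name, noise_sd_rel, scale_errors,
                                registry, f"_sim_{config_name}_{flow_path}")
    controller = HardwareController(registry)
    controller.set_seed(int(rng.integers(2**31)))
    controller.load_configuration(name)
    engine = ProtocolEngine(controller)

    channels = list(range(1, controller.n_channels + 1))
    for ch in channels:
        source = (FlowSource.buffer(1) if flow_path == "buffer"
                  else FlowSource.load(ch))
        controller.set_flow_path(ch, source, FlowSink.FRACTION_COLLECTOR)
    if calibrate:
        for ch in channels:
            engine.calibrate_flow(ch, DEFAULT_RATE_CV_PER_MIN, window_min)

    rows = []
    for m in range(1, n_measurements + 1):
        volumes = {}
        rates = {}
        for ch in channels:
            cv = controller.config.column_volume_ml(ch)
            volumes[ch] = DEFAULT_RATE_CV_PER_MIN * cv * window_min
            rates[ch] = DEFAULT_RATE_CV_PER_MIN * cv
        results = controller.dispense_parallel(volumes, rates)
        for ch, res in results.items():
            cv = controller.config.column_volume_ml(ch)
            rows.append({"measurement": m, "channel": ch,
                         "flow_path": flow_path,
                         "volume_ml": res.delivered_ml,
                         "volume_cv": res.delivered_ml / cv})
    return pd.DataFrame(rows)


def summarize_fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-channel mean and sd of dispensed volume, in CV."""
    return (df.groupby("channel")["volume_cv"]
              .agg(["mean", "std", "count"]).reset_index())


def calibration_recovery_experiment(
        scale_error: float = 1.05,
        config_name: str = "histrap_1ml",
        channel: int = 1,
        seed: int = 0,
        registry: Optional[ConfigRegistry] = None) -> dict:
    """Noiseless single-pass calibration of a mis-scaled pump.

    Returns the relative delivery error for a commanded 1 CV dispense before
    and after one calibration pass.
    """
    registry, name = _noisy_rig(config_name, 0.0, [scale_error] * 4,
                                registry, f"_sim_cal_{config_name}")
    controller = HardwareController(registry)
    controller.set_seed(seed)
    controller.load_configuration(name)
    engine = ProtocolEngine(controller)
    cv = controller.config.column_volume_ml(channel)

    controller.set_flow_path(channel, FlowSource.buffer(1),
                             FlowSink.POST_COLUMN_WASTE)
    before = controller.run_pump(channel, cv, cv).delivered_ml
    engine.calibrate_flow(channel, DEFAULT_RATE_CV_PER_MIN, 1.0)
    after = controller.run_pump(channel, cv, cv).delivered_ml
    return {
        "scale_error": scale_error,
        "error_before_rel": before / cv - 1.0,
        "error_after_rel": after / cv - 1.0,
        "volume_per_step_ul": controller.pump_model(channel).volume_per_step_ul,
    }
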