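"""Synthetic hemodynamic waveform generation.

Emulates the four mock-circulation protocols used to characterize the
reflective PPG pathways: (i) static pressure steps without flow, (ii) flow
sweeps at constant pressure (stiff vessel), (iii) pulsatile flow against a
resistance, and (iv) intermittent flow with long zero-flow pauses. The
waveforms are phenomenological templates — no wave-propagation hemodynamics
is attempted — but they respect the protocol structure (plateau durations,
ramp smoothness, 10-s pauses, beat periodicity) that the downstream
calibration and evaluation stages rely on.

All randomness flows from the single ``seed`` in the
:class:`~rppgflow.containers.ProtocolSpec`; identical (spec, vessel, seed)
triples produce bit-identical recordings.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .containers import HemodynamicRecording, ProtocolSpec, VesselModel
from .optics import FlowOpticsParams, PressureOpticsParams, predict_ppg

__all__ = [
    "pressure_to_diameter",
    "generate_static_steps",
    "generate_flow_sweep",
    "generate_pulsatile",
    "generate_intermittent",
    "generate",
    "pressure_beat_template",
    "flow_beat_template",
]


def pressure_to_diameter(pressure, vessel: VesselModel) -> np.ndarray:
    """Diameter series (mm) from pressure (mmHg) under the linear wall law.

    D = reference_diameter + b*(P - reference_pressure); stiff vessels
    return the constant reference diameter. Warns outside 50-200 mmHg and
    raises on a non-positive result.
    """
    return vessel.diameter(pressure)


def _raised_cosine(v0: float, v1: float, n: int) -> np.ndarray:
    """Smooth monotone transition from v0 to v1 over n samples."""
    if n <= 0:
        return np.empty(0)
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * x))


def pressure_beat_template(n: int, peak_phase: float = 0.2) -> np.ndarray:
    """One beat of a normalized arterial pressure pulse on n samples, in [0, 1].

    Truncated Fourier series (fundamental plus three harmonics with fixed
    phases) giving a fast systolic upstroke and a dicrotic decay; band
    limited well below the 50-Hz low-pass used in processing. The template
    is rolled so the systolic peak sits at ``peak_phase`` of the beat,
    just after the flow-pulse peak (0.18): on a pulsatile rig the flow
    pulse slightly leads the pressure wave it generates against the distal
    resistance.
    """
    phi = np.arange(n) / n
    amp = (1.0, 0.5, 0.23, 0.10)
    pha = (0.0, 1.1, 2.2, 3.0)
    s = np.zeros(n)
    for k, (a, th) in enumerate(zip(amp, pha), start=1):
        s += a * np.cos(2.0 * np.pi * k * phi - th)
    s -= s.min()
    s /= s.max()
    return np.roll(s, int(round(peak_phase * n)) - int(np.argmax(s)))


def flow_beat_template(n: int, peak_phase: float = 0.18, shape: float = 3.0) -> np.ndarray:
    """One beat of a normalized systolic ejection pulse on n samples, in [0, 1].

    Gamma-shaped bump peaking early in the beat and decaying to a
    (near-)zero diastolic baseline before the next beat.
    """
    phi = np.arange(n) / n
    x = phi / peak_phase
    g = np.power(x, shape) * np.exp(shape * (1.0 - x))
    g[g < 0] = 0.0
    g /= g.max()
    return g


def _step_profile(levels, fs: float, plateau_s: float, ramp_s: float):
    """Piecewise-constant profile with raised-cosine ramps between levels.

    Returns the sample array and (start, stop) index pairs of each plateau.
    """
    n_plateau = int(round(plateau_s * fs))
    n_ramp = int(round(ramp_s * fs))
    chunks = []
    plateau_idx = []
    pos = 0
    prev = None
    for lv in levels:
        if prev is not None:
            chunks.append(_raised_cosine(prev, lv, n_ramp))
            pos += n_ramp
        chunks.append(np.full(n_plateau, float(lv)))
        plateau_idx.append((pos, pos + n_plateau))
        pos += n_plateau
        prev = lv
    return np.concatenate(chunks), plateau_idx


def _finalize(
    spec: ProtocolSpec,
    vessel: VesselModel,
    pressure_clean: np.ndarray,
    flow_clean: np.ndarray,
    beat_onsets=None,
    pauses=None,
    pressure_params: Optional[PressureOpticsParams] = None,
    flow_params: Optional[FlowOpticsParams] = None,
    meta: Optional[dict] = None,
) -> HemodynamicRecording:
    """Attach diameter, optional forward-model PPG, and channel noise."""
    fs = spec.sampling_rate
    n = pressure_clean.size
    t = np.arange(n) / fs
    diameter_clean = vessel.diameter(pressure_clean)

    ppg_clean = None
    if pressure_params is not None:
        clean = HemodynamicRecording(
            time=t,
            pressure=pressure_clean,
            flow=flow_clean,
            diameter=diameter_clean,
            sampling_rate=fs,
            protocol=spec.protocol,
        )
        ppg_clean = predict_ppg(
            clean,
            pressure_params,
            flow_params if flow_params is not None else FlowOpticsParams(),
            mode="P_and_Q",
        )

    rng = spec.rng()
    pressure = pressure_clean + rng.normal(0.0, spec.noise_pressure, n) if spec.noise_pressure else pressure_clean.copy()
    flow = flow_clean + rng.normal(0.0, spec.noise_flow, n) if spec.noise_flow else flow_clean.copy()
    diameter = diameter_clean + rng.normal(0.0, spec.noise_diameter, n) if spec.noise_diameter else diameter_clean.copy()
    ppg = None
    if ppg_clean is not None:
        ppg = ppg_clean + rng.normal(0.0, spec.noise_ppg, n) if spec.noise_ppg else ppg_clean

    md = dict(meta or {})
    md["seed"] = spec.seed
    return HemodynamicRecording(
        time=t,
        pressure=pressure,
        flow=flow,
        diameter=diameter,
        sampling_rate=fs,
        protocol=spec.protocol,
        ppg=ppg,
        beat_onsets=beat_onsets,
        pauses=list(pauses or []),
        meta=md,
    )


def generate_static_steps(
    spec: ProtocolSpec,
    vessel: VesselModel,
    pressure_params: Optional[PressureOpticsParams] = None,
    flow_params: Optional[FlowOpticsParams] = None,
) -> HemodynamicRecording:
    """Static protocol: pressure plateaus with smooth ramps, zero flow."""
    if spec.protocol != "static_steps":
        raise ValueError("spec.protocol must be 'static_steps'")
    if spec.pressure_levels is None or len(spec.pressure_levels) < 2:
        raise ValueError("static protocol needs at least two pressure levels")
    pressure, plateaus = _step_profile(
        spec.pressure_levels, spec.sampling_rate, spec.duration_per_level, spec.ramp_duration
    )
    flow = np.zeros_like(pressure)
    return _finalize(
        spec,
        vessel,
        pressure,
        flow,
        pressure_params=pressure_params,
        flow_params=flow_params,
        meta={"plateaus": [[int(a), int(b)] for a, b in plateaus]},
    )


def generate_flow_sweep(
    spec: ProtocolSpec,
    vessel: VesselModel,
    pressure_params: Optional[PressureOpticsParams] = None,
    flow_params: Optional[FlowOpticsParams] = None,
) -> HemodynamicRecording:
    """Flow-sweep protocol: flow plateaus at constant reference pressure.

    A stiff vessel is preferred (constant diameter removes the volume
    pathway from the sweep); plateaus must be held at least 4 s so that
    4-s window means are well defined downstream.
    """
    if spec.protocol != "flow_sweep":
        raise ValueError("spec.protocol must be 'flow_sweep'")
    if spec.flow_levels is not None:
        levels = list(spec.flow_levels)
    elif spec.flow_range is not None:
        levels = list(np.linspace(spec.flow_range[0], spec.flow_range[1], 12))
    else:
        raise ValueError("flow_levels or flow_range required")
    if min(levels) < 0:
        raise ValueError("negative flow requested; retrograde flow is not modelled")
    if spec.duration_per_level < 4.0:
        raise ValueError("flow plateaus must be held at least 4 s")
    flow, plateaus = _step_profile(
        levels, spec.sampling_rate, spec.duration_per_level, spec.ramp_duration
    )
    pressure = np.full_like(flow, float(vessel.reference_pressure))
    return _finalize(
        spec,
        vessel,
        pressure,
        flow,
        pressure_params=pressure_params,
        flow_params=flow_params,
        meta={"plateaus": [[int(a), int(b)] for a, b in plateaus]},
    )


def generate_pulsatile(
    spec: ProtocolSpec,
    vessel: VesselModel,
    pressure_params: Optional[PressureOpticsParams] = None,
    flow_params: Optional[FlowOpticsParams] = None,
) -> HemodynamicRecording:
    """Pulsatile protocol: periodic pressure/flow beats against resistance.

    Pressure beats use the truncated-Fourier template scaled exactly to
    ``pressure_range`` (diastolic, systolic); flow beats use the
    gamma-shaped ejection template scaled to ``flow_range``; both repeat at
    ``heart_rate`` and are sampled on a common grid, with the flow upstroke
    coinciding with the pressure upstroke.
    """
    if spec.protocol != "pulsatile":
        raise ValueError("spec.protocol must be 'pulsatile'")
    if spec.heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if spec.pressure_range is None or spec.flow_range is None:
        raise ValueError("pressure_range and flow_range are required")
    p_lo, p_hi = spec.pressure_range
    q_lo, q_hi = spec.flow_range
    if p_lo >= p_hi or q_lo > q_hi:
        raise ValueError("ranges must be (low, high) with low < high")
    if q_lo < 0:
        raise ValueError("negative flow requested; retrograde flow is not modelled")

    n_beat = int(round(spec.sampling_rate * 60.0 / spec.heart_rate))
    p_beat = p_lo + (p_hi - p_lo) * pressure_beat_template(n_beat)
    q_beat = q_lo + (q_hi - q_lo) * flow_beat_template(n_beat)
    pressure = np.tile(p_beat, spec.n_beats)
    flow = np.tile(q_beat, spec.n_beats)
    onsets = np.arange(spec.n_beats) * n_beat
    return _finalize(
        spec,
        vessel,
        pressure,
        flow,
        beat_onsets=onsets,
        pressure_params=pressure_params,
        flow_params=flow_params,
        meta={"heart_rate": spec.heart_rate},
    )


def generate_intermittent(
    spec: ProtocolSpec,
    vessel: VesselModel,
    pressure_params: Optional[PressureOpticsParams] = None,
    flow_params: Optional[FlowOpticsParams] = None,
    rise_duration: float = 0.3,
    fall_duration: float = 0.01,
) -> HemodynamicRecording:
    """Intermittent protocol: isolated flow pulses separated by long pauses.

    Each pulse rises smoothly to the peak flow, holds, then stops abruptly
    (the pump is switched off), followed by ``pause_duration`` seconds of
    zero flow at constant pressure. Pause segments (from deceleration end
    to the next pulse onset) are returned so that the biexponential
    relaxation can be fitted on them; ``beat_onsets`` mark pulse starts.
    """
    if spec.protocol != "intermittent":
        raise ValueError("spec.protocol must be 'intermittent'")
    q_peak = spec.flow_range[1] if spec.flow_range is not None else 328.0
    if q_peak <= 0:
        raise ValueError("peak flow must be positive")
    fs = spec.sampling_rate
    n_rise = int(round(rise_duration * fs))
    n_hold = max(int(round((spec.pulse_duration - rise_duration) * fs)), 1)
    n_fall = max(int(round(fall_duration * fs)), 2)
    n_pause = int(round(spec.pause_duration * fs))

    pulse = np.concatenate(
        [
            _raised_cosine(0.0, q_peak, n_rise),
            np.full(n_hold, q_peak),
            _raised_cosine(q_peak, 0.0, n_fall),
        ]
    )
    period = pulse.size + n_pause
    n_total = period * spec.n_beats
    flow = np.zeros(n_total)
    onsets = []
    pauses = []
    for k in range(spec.n_beats):
        s = k * period
        flow[s : s + pulse.size] = pulse
        onsets.append(s)
        pauses.append((s + pulse.size, s + period))
    pressure = np.full(n_total, float(vessel.reference_pressure))
    return _finalize(
        spec,
        vessel,
        pressure,
        flow,
        beat_onsets=np.asarray(onsets),
        pauses=pauses,
        pressure_params=pressure_params,
        flow_params=flow_params,
        meta={"peak_flow": q_peak},
    )


_GENERATORS = {
    "static_steps": generate_static_steps,
    "flow_sweep": generate_flow_sweep,
    "pulsatile": generate_pulsatile,
    "intermittent": generate_intermittent,
}


def generate(spec: ProtocolSpec, vessel: VesselModel, **kwargs) -> HemodynamicRecording:
    """Dispatch to the generator matching ``spec.protocol``."""
    return _GENERATORS[spec.protocol](spec, vessel, **kwargs)
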