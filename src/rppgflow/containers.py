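"""Core data containers for hemodynamic recordings and the artery model.

Conventions used throughout the package: time in seconds on a uniform grid,
pressure in mmHg, flow rate in mL/min, diameter in mm, PPG in arbitrary units
(a.u.). The CSV dialect is a plain UTF-8 table with header
``time_s,pressure_mmHg,flow_mlmin,diameter_mm,ppg_au``; the PPG column is
optional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VesselModel",
    "ProtocolSpec",
    "HemodynamicRecording",
    "PRESSURE_SUPPORT_MMHG",
    "CSV_COLUMNS",
]

#: Pressure range over which the linear wall law is supported (mmHg).
PRESSURE_SUPPORT_MMHG = (50.0, 200.0)

CSV_COLUMNS = ["time_s", "pressure_mmHg", "flow_mlmin", "diameter_mm", "ppg_au"]

PROTOCOLS = ("static_steps", "flow_sweep", "pulsatile", "intermittent")


@dataclass
class VesselModel:
    """Geometry and linear elastic law of the silicone artery model.

    The wall law is the linearized pressure–diameter relationship
    ``D(P) = reference_diameter + pd_slope_b * (P - reference_pressure)``,
    which is a good description of the human radial artery between 50 and
    200 mmHg. A stiff model (``is_stiff=True``) keeps its diameter constant
    regardless of pressure and is used to isolate flow effects.

    Parameters
    ----------
    reference_diameter : float
        Inner diameter at the reference pressure, mm. Must be positive.
    reference_pressure : float
        Pressure at which the reference diameter applies, mmHg.
    pd_slope_b : float
        Pressure–diameter slope b, mm/mmHg. Non-negative.
    is_stiff : bool
        If True the effective slope is zero.
    length_segment : float
        Length of the illuminated segment, mm; only used for shear-rate
        bookkeeping, never for the optics.
    """

    reference_diameter: float = 4.0
    reference_pressure: float = 100.0
    pd_slope_b: float = 1.245e-3
    is_stiff: bool = False
    length_segment: float = 50.0

    def __post_init__(self) -> None:
        if self.reference_diameter <= 0:
            raise ValueError("reference_diameter must be positive")
        if self.pd_slope_b < 0:
            raise ValueError("pd_slope_b must be non-negative")

    @property
    def effective_slope(self) -> float:
        return 0.0 if self.is_stiff else self.pd_slope_b

    def diameter(self, pressure) -> np.ndarray:
        """Diameter (mm) at the given pressure(s) (mmHg) under the wall law.

        Warns when pressures leave the supported 50–200 mmHg range and
        raises if the resulting diameter would be non-positive.
        """
        p = np.asarray(pressure, dtype=float)
        lo, hi = PRESSURE_SUPPORT_MMHG
        if p.size and (np.nanmin(p) < lo or np.nanmax(p) > hi):
            warnings.warn(
                f"pressures outside the supported {lo:g}-{hi:g} mmHg range; "
                "the linear wall law is extrapolated",
                stacklevel=2,
            )
        d = self.reference_diameter + self.effective_slope * (p - self.reference_pressure)
        if np.any(d <= 0):
            raise ValueError("wall law produced a non-positive diameter")
        return d

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VesselModel":
        return cls(**d)


@dataclass
class ProtocolSpec:
    """Specification of one synthetic in vitro protocol run.

    ``protocol`` selects among the four mock-circulation experiments:

    - ``static_steps``: pressure plateaus, no flow;
    - ``flow_sweep``: flow plateaus at constant pressure (stiff vessel
      preferred);
    - ``pulsatile``: periodic beats of pressure and flow against resistance;
    - ``intermittent``: isolated flow pulses separated by zero-flow pauses.

    Noise SDs are additive Gaussian, per channel, in the channel's units.
    Identical (spec, vessel, seed) triples generate bit-identical
    recordings.
    """

    protocol: str = "pulsatile"
    sampling_rate: float = 1000.0
    duration_per_level: float = 8.0
    ramp_duration: float = 1.0
    n_beats: int = 10
    pressure_levels: Optional[Sequence[float]] = None
    pressure_range: Optional[tuple] = None
    flow_levels: Optional[Sequence[float]] = None
    flow_range: Optional[tuple] = None
    heart_rate: float = 60.0
    pause_duration: float = 10.0
    pulse_duration: float = 1.0
    noise_pressure: float = 0.5
    noise_flow: float = 2.0
    noise_ppg: float = 5.0
    noise_diameter: float = 0.002
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.pause_duration <= 0:
            raise ValueError("pause_duration must be positive")
        for name in ("noise_pressure", "noise_flow", "noise_ppg", "noise_diameter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["pressure_range"] is not None:
            d["pressure_range"] = list(d["pressure_range"])
        if d["flow_range"] is not None:
            d["flow_range"] = list(d["flow_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        for key in ("pressure_range", "flow_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class HemodynamicRecording:
    """Uniformly sampled simultaneous pressure/flow/diameter/PPG record.

    All channels share one time grid; the PPG channel is optional (present
    when generated by the forward model or loaded from file). ``beat_onsets``
    are sample indices of beat starts for pulsatile/intermittent protocols;
    ``pauses`` are (start, stop) index pairs of zero-flow pause segments.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    diameter: np.ndarray
    sampling_rate: float
    protocol: str
    ppg: Optional[np.ndarray] = None
    beat_onsets: Optional[np.ndarray] = None
    pauses: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for name in ("pressure", "flow", "diameter"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"channel {name!r} has length {arr.size}, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite samples")
            setattr(self, name, arr)
        if self.ppg is not None:
            self.ppg = np.asarray(self.ppg, dtype=float)
            if self.ppg.size != n:
                raise ValueError("ppg channel length mismatch")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid is not uniform")
        if self.beat_onsets is not None:
            self.beat_onsets = np.asarray(self.beat_onsets, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_s": self.time,
            "pressure_mmHg": self.pressure,
            "flow_mlmin": self.flow,
            "diameter_mm": self.diameter,
        }
        if self.ppg is not None:
            data["ppg_au"] = self.ppg
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        md = {
            "sampling_rate": self.sampling_rate,
            "protocol": self.protocol,
            "n_samples": int(self.n_samples),
        }
        if self.beat_onsets is not None:
            md["beat_onsets"] = [int(i) for i in self.beat_onsets]
        if self.pauses:
            md["pauses"] = [[int(a), int(b)] for a, b in self.pauses]
        md.update(self.meta)
        return md

    def save(self, csv_path, meta_path=None) -> None:
        """Write the CSV record and, optionally, a JSON metadata sidecar."""
        self.to_csv(csv_path)
        if meta_path is not None:
            Path(meta_path).write_text(json.dumps(self.metadata(), indent=2))

    @classmethod
    def from_csv(cls, path, sampling_rate: Optional[float] = None,
                 protocol: str = "pulsatile", meta_path=None) -> "HemodynamicRecording":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"CSV is missing required columns: {missing}")
        t = df["time_s"].to_numpy(dtype=float)
        meta = {}
        beat_onsets = None
        pauses: list = []
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            sampling_rate = meta.pop("sampling_rate", sampling_rate)
            protocol = meta.pop("protocol", protocol)
            beat_onsets = meta.pop("beat_onsets", None)
            pauses = [tuple(p) for p in meta.pop("pauses", [])]
            meta.pop("n_samples", None)
        if sampling_rate is None:
            if t.size < 2:
                raise ValueError("cannot infer sampling rate from a single sample")
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        ppg = df["ppg_au"].to_numpy(dtype=float) if "ppg_au" in df.columns else None
        return cls(
            time=t,
            pressure=df["pressure_mmHg"].to_numpy(dtype=float),
            flow=df["flow_mlmin"].to_numpy(dtype=float),
            diameter=df["diameter_mm"].to_numpy(dtype=float),
            sampling_rate=float(sampling_rate),
            protocol=protocol,
            ppg=ppg,
            beat_onsets=beat_onsets,
            pauses=pauses,
            meta=meta,
        )
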