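"""Bundled in vitro calibration constants and their loader.

``data/invitro_constants.json`` carries the reference constants fitted on
the silicone-artery mock circulation: pressure-pathway slope b' = 2.15
a.u./mmHg; flow-pathway m' = 1613 a.u., Q_c = 328 mL/min, tau_d = 0.39 s,
tau_a = 1.78 s, n_d/n_a = 2.2 (gamma_c = 870 1/s in the shear domain);
receiver exponent d = 1.3; wall-law slope b = 1.245e-3 mm/mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .containers import VesselModel
from .optics import FlowOpticsParams, PressureOpticsParams, SensorModel

__all__ = ["ModelConstants", "load_constants", "builtin_constants_path"]


@dataclass
class ModelConstants:
    """One coherent set of forward-model constants."""

    pressure_optics: PressureOpticsParams
    flow_optics: FlowOpticsParams
    sensor: SensorModel
    vessel: VesselModel

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "pressure_optics": asdict(self.pressure_optics),
            "flow_optics": asdict(self.flow_optics),
            "sensor": asdict(self.sensor),
            "vessel": asdict(self.vessel),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def builtin_constants_path() -> Path:
    """Filesystem path of the bundled constants JSON."""
    return Path(resources.files("rppgflow") / "data" / "invitro_constants.json")


def load_constants(path: Optional[Union[str, Path]] = None) -> ModelConstants:
    """Load model constants from a JSON file (bundled defaults if None).

    The document maps section names (``pressure_optics``, ``flow_optics``,
    ``sensor``, ``vessel``) to field dicts matching the parameter
    dataclasses; missing sections fall back to dataclass defaults.
    """
    if path is None:
        doc = json.loads(builtin_constants_path().read_text())
    else:
        doc = json.loads(Path(path).read_text())
    return ModelConstants(
        pressure_optics=PressureOpticsParams(**doc.get("pressure_optics", {})),
        flow_optics=FlowOpticsParams(**doc.get("flow_optics", {})),
        sensor=SensorModel(**doc.get("sensor", {})),
        vessel=VesselModel(**doc.get("vessel", {})),
    )
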