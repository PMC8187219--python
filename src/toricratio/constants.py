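"""Fixed physical assumptions of the pseudophakic thin-lens eye model.

The model treats cornea and IOL as thin lenses on a common axis. Corneal
power is derived from the measured front radius with a fictitious
keratometer index; aqueous and vitreous share one medium index; the
spectacle plane sits a fixed vertex distance in front of the cornea; the
refraction lane defines the object vergence at that plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path


@dataclass(frozen=True)
class OpticalConstants:
    """Immutable bundle of the optical model's fixed parameters.

    Parameters
    ----------
    n_air : float
        Refractive index of air (dimensionless, fixed at 1.0).
    n_keratometer : float
        Keratometer index converting a corneal front radius into a total
        corneal power (dimensionless).
    n_media : float
        Refractive index of aqueous and vitreous (dimensionless). Standard
        schematic-eye value 1.336.
    vertex_distance : float
        Spectacle-plane-to-corneal-apex distance in metres.
    measurement_distance : float
        Refraction lane length in metres; the object vergence at the
        spectacle plane is ``-1/measurement_distance``.
    """

    n_air: float = 1.0
    n_keratometer: float = 1.332
    n_media: float = 1.336
    vertex_distance: float = 0.012
    measurement_distance: float = 6.0

    def __post_init__(self) -> None:
        if self.n_air != 1.0:
            raise ValueError("n_air must be exactly 1.0")
        if not self.n_keratometer > 1.0:
            raise ValueError("n_keratometer must exceed 1")
        if not self.n_media > 1.0:
            raise ValueError("n_media must exceed 1")
        if not self.vertex_distance > 0:
            raise ValueError("vertex_distance must be positive")
        if not self.measurement_distance > 0:
            raise ValueError("measurement_distance must be positive")

    # JSON config block uses short external key names
    _JSON_KEYS = {
        "n_keratometer": "n_keratometer",
        "n_media": "n_media",
        "vertex_m": "vertex_distance",
        "measurement_m": "measurement_distance",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConstants":
        """Build from a config mapping like
        ``{"n_keratometer": 1.332, "n_media": 1.336, "vertex_m": 0.012,
        "measurement_m": 6.0}``. Unknown keys are rejected."""
        kwargs = {}
        for key, value in d.items():
            if key not in cls._JSON_KEYS:
                raise ValueError(f"unknown optical-constants key: {key!r}")
            kwargs[cls._JSON_KEYS[key]] = float(value)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "OpticalConstants":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        field_to_json = {v: k for k, v in self._JSON_KEYS.items()}
        return {
            field_to_json[name]: value
            for name, value in asdict(self).items()
            if name in field_to_json
        }


DEFAULT_CONSTANTS = OpticalConstants()
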