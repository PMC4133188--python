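"""Run configuration: device geometry, fluid, solver/fit/detection settings.

The YAML/JSON config speaks human units at the boundary (µL, µL/s, mbar,
mm) and is converted to SI on load.  A config hash plus the seed makes every
pipeline run reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from penpress.device_model import DeviceGeometry, FluidProps
from penpress.errors import InvalidInputError
from penpress.units import ATM, MBAR, MM, UL, VOLUME_PER_CLICK


@dataclass
class RunConfig:
    """All tunables of a pipeline run (SI internally)."""

    geom: DeviceGeometry = field(default_factory=DeviceGeometry)
    fluid: FluidProps = field(default_factory=FluidProps)
    p_ref: float = ATM
    volume_per_click: float = VOLUME_PER_CLICK
    # detection
    threshold_sd: float = 6.0
    refractory: float = 0.020
    # flow
    truncate_tail: int = 2
    # tissue model / solver
    phi0: float = 0.01
    p0: float = ATM
    r_outer: float = 50 * MM
    n_cells: int = 200
    # fit
    fit_init_k: float = 1e-11
    fit_init_K: float = 1e5
    fit_bounds_k: tuple[float, float] = (1e-14, 1e-8)
    fit_bounds_K: tuple[float, float] = (1e3, 1e8)
    # cohort summary
    detection_floor: float = 10 * MBAR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ref", "volume_per_click", "phi0", "p0", "r_outer"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (or JSON).  Human units: µL, mm, mbar."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        kw: dict = {}
        geom_kw = raw.pop("device", {})
        if geom_kw:
            conv = {"r_s_mm": ("r_s", MM), "r_n_um": ("r_n", 1e-6), "L_n_mm": ("L_n", MM)}
            gk = {}
            for key, val in geom_kw.items():
                if key in conv:
                    name, factor = conv[key]
                    gk[name] = val * factor
                else:
                    gk[key] = val
            kw["geom"] = DeviceGeometry(**gk)
        fluid_kw = raw.pop("fluid", {})
        if fluid_kw:
            kw["fluid"] = FluidProps(**fluid_kw)
        scalar_conv = {
            "volume_per_click_uL": ("volume_per_click", UL),
            "r_outer_mm": ("r_outer", MM),
            "detection_floor_mbar": ("detection_floor", MBAR),
            "p_ref_mbar": ("p_ref", MBAR),
            "p0_mbar": ("p0", MBAR),
        }
        for key, val in raw.items():
            if key in scalar_conv:
                name, factor = scalar_conv[key]
                kw[name] = val * factor
            elif key in ("fit_bounds_k", "fit_bounds_K"):
                kw[key] = tuple(val)
            else:
                kw[key] = val
        return cls(**kw)

    def hash(self) -> str:
        payload = {
            **{k: v for k, v in asdict(self).items() if k not in ("geom", "fluid")},
            "geom": asdict(self.geom),
            "fluid": asdict(self.fluid),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
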