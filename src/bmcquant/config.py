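"""Run configuration and seeded random substreams.

Every tolerance and threshold used by the pipeline lives here with a
documented default; a YAML config may override any subset of keys (absent
keys fall back to defaults).  All randomness flows from the single
``random_seed`` through named substreams — one per stage — so a run is
reproducible end to end and stages cannot perturb each other's streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError

# fixed stream ids: adding a stage must not renumber existing ones
_STREAM_IDS = {
    "frap_sim": 1,
    "coloc_sim": 2,
    "events_sim": 3,
    "analysis": 4,
}


def substream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stage, derived from the run seed."""
    if stream not in _STREAM_IDS:
        raise InputError(f"unknown random substream {stream!r}")
    return np.random.default_rng([int(seed), _STREAM_IDS[stream]])


@dataclass
class FrapConfig:
    """Parameters of the FRAP estimation stage."""

    prebleach_frames: int = 1          # frames averaged into the prebleach profile
    window: int = 1                    # half-width (px) of the bleach-center window
    final_mode: str = "plateau"        # "plateau" (fitted) or "last_frames"
    final_frames: int = 5              # frames averaged when final_mode="last_frames"
    d_min: float = 1e-6                # μm² s⁻¹, lower edge of the D search
    d_max: float = 1e-1                # μm² s⁻¹, upper edge of the D search
    d_points_per_decade: int = 25      # log-grid density of the coarse scan
    d_rel_tol: float = 1e-3            # relative tolerance of the refinement
    joint_fit: bool = True             # refine (M, D) jointly after the two-stage fit
    m_qc_band: tuple[float, float] = (-0.05, 1.05)  # raw-M QC acceptance band


@dataclass
class ColocConfig:
    """Parameters of the colocalization stage."""

    background_offset: float = 0.0     # constant subtracted from both channels


@dataclass
class EventConfig:
    """Parameters of focus detection and event classification."""

    k_sigma: float = 3.0               # detection threshold mean + k*sd
    min_area: int = 4                  # px, minimum focus area
    persistence: int = 2               # consecutive frames a focus must persist
    concomitance_window: int = 0       # frames; |gap| <= window -> concomitant


@dataclass
class RunConfig:
    """Top-level configuration binding all stages to one seed."""

    random_seed: int = 0
    output_dir: str = "."
    frap: FrapConfig = field(default_factory=FrapConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    events: EventConfig = field(default_factory=EventConfig)
    simulate: dict = field(default_factory=dict)  # overrides for SimulationParams

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the fully resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config; keys absent from the file keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        for section, klass in (
            ("frap", FrapConfig),
            ("coloc", ColocConfig),
            ("events", EventConfig),
        ):
            sub = raw.pop(section, {})
            if sub:
                unknown = set(sub) - {f.name for f in dataclasses.fields(klass)}
                if unknown:
                    raise InputError(f"unknown {section} config keys: {sorted(unknown)}")
                setattr(cfg, section, klass(**sub))
        cfg.simulate = raw.pop("simulate", {})
        for key in ("random_seed", "output_dir"):
            if key in raw:
                setattr(cfg, key, raw.pop(key))
        if raw:
            raise InputError(f"unknown config keys: {sorted(raw)}")
        return cfg
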