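"""Run configuration, defaults and provenance records.

Every tunable that has a measured counterpart defaults to it: 30-degree
cone aperture, 50-point background tail, 5-sigma event threshold, the
inclusive 25 us - 2.5 s duration gate, 5 kHz low-pass cutoff and the 0-5 um
near-surface biofilm band.  Configs round-trip losslessly through JSON, and
each run can emit a provenance record (config hash + seed + version) from
which its outputs are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidSpecError

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "provenance_record"]


@dataclass
class RunConfig:
    """Flat bag of pipeline tunables shared by the CLI subcommands."""

    # confocal profile analysis
    aperture_deg: float = 30.0
    n_tail: int = 50
    n_sigma: float = 2.0
    k_sustain: int = 3
    bin_width_nm: float | None = None
    # nanopore analysis
    k_sigma: float = 5.0
    dmin_s: float = 25e-6
    dmax_s: float = 2.5
    cutoff_hz: float = 5000.0
    baseline_window_s: float = 0.05
    # biofilm analysis
    highpass_sigma_nm: float = 2000.0
    band_um: tuple[float, float] = (0.0, 5.0)
    per_cell_volume_um3: float = 1.0
    # shared
    seed: int = 0
    channel_roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.aperture_deg <= 180:
            raise InvalidSpecError("aperture must lie in (0, 180] degrees")
        if self.n_tail < 2 or self.k_sustain < 1:
            raise InvalidSpecError("n_tail >= 2 and k_sustain >= 1 required")
        if self.dmin_s < 0 or self.dmax_s < self.dmin_s:
            raise InvalidSpecError("need 0 <= dmin_s <= dmax_s")
        self.band_um = tuple(self.band_um)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))


def config_hash(config: RunConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def provenance_record(config: RunConfig | dict, seed: int | None = None) -> dict:
    """Machine-readable record from which a run can be regenerated exactly."""
    from . import __version__

    d = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    return {
        "config": d,
        "config_sha256": config_hash(d),
        "seed": seed if seed is not None else d.get("seed"),
        "habrush_version": __version__,
    }
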