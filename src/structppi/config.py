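"""Run configuration and provenance manifest for the pipeline commands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .docking import PredictionConfig
from .errors import FormatError
from .mutations import VerdictThresholds


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with protocol defaults."""
    confidence_threshold: float = 0.4   # interaction filter, strictly greater
    tm_threshold: float = 0.5           # redundancy clustering
    rmsd_threshold: float = 2.5         # A, redundancy clustering
    min_residues: int = 15              # engine size rule
    contact_cutoff: float = 5.0         # A, heavy-atom interface contacts
    nearby_cutoff: float = 6.0          # A, CA-CA interface neighborhood
    clash_distance: float = 2.5         # A
    max_clashes: int = 5
    potential_contact_distance: float = 6.5  # A, CB-CB scoring range
    min_matched_fraction: float = 0.5
    interface_identity_min: float = 0.5
    hotspot_match_min: int = 1
    hotspot_bonus: float = -1.0         # energy units per matched hot spot
    rel_asa_max: float = 0.20           # hot-spot burial threshold
    potential_min: float = 18.0         # hot-spot pair-potential threshold
    delta_threshold: float = 5.0        # verdict: weakened/strengthened shift
    ratio: float = 0.5                  # verdict: magnitude-ratio criterion
    probe_radius: float = 1.4           # A, SASA probe
    sphere_points: int = 960            # SASA sampling density
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def prediction_config(self) -> PredictionConfig:
        return PredictionConfig(
            min_residues=self.min_residues,
            min_matched_fraction=self.min_matched_fraction,
            interface_identity_min=self.interface_identity_min,
            max_clashes=self.max_clashes,
            clash_distance=self.clash_distance,
            potential_contact_distance=self.potential_contact_distance,
            hotspot_match_min=self.hotspot_match_min,
            hotspot_bonus=self.hotspot_bonus)

    def verdict_thresholds(self) -> VerdictThresholds:
        return VerdictThresholds(delta_threshold=self.delta_threshold,
                                 ratio=self.ratio)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, inputs: list, seed: int | None = None
                   ) -> Path:
    """Record config snapshot, input digests and timestamps next to the outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed if seed is not None else config.seed,
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
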