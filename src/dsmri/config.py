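"""Extraction configuration: every tunable knob of the feature pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from dsmri.volume_io import PLANES


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of per-scan feature extraction.

    Attributes
    ----------
    planes
        Anatomical planes whose slices are pooled (default all three).
    min_fg_fraction
        Slices whose foreground covers less than this fraction of pixels are
        excluded from aggregation; near-empty edge slices destabilise the
        statistics.
    patch_side
        Side of the random square patches used by SNR2/CNR.
    bg_guard
        Width in pixels of the guard band around the foreground excluded
        from the air region used for noise estimation (sigma_B and the
        background patch), keeping partial-volume edge pixels out.
    snrf_signal_radius_fraction
        Fraction of the maximum spectral radius counted as signal by SNRF.
    wavelet
        Wavelet family for the one-level 2-D DWT.
    glcm_levels, glcm_distance
        Grey-level count and pixel-pair distance of the co-occurrence matrix
        (four angles, 0/45/90/135 degrees, are always averaged).
    slice_step
        Take every k-th slice per plane (1 = all slices).
    seed
        Global seed; per-slice patch seeds are derived from it together with
        the scan id, plane and slice index.
    """

    planes: tuple[str, ...] = PLANES
    min_fg_fraction: float = 0.01
    patch_side: int = 5
    bg_guard: int = 8
    snrf_signal_radius_fraction: float = 0.25
    wavelet: str = "coif1"
    glcm_levels: int = 64
    glcm_distance: int = 1
    slice_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planes", tuple(self.planes))
        unknown = set(self.planes) - set(PLANES)
        if unknown:
            raise ValueError(f"unknown planes {sorted(unknown)}; expected subset of {PLANES}")
        if not self.planes:
            raise ValueError("at least one plane is required")
        if self.slice_step < 1:
            raise ValueError("slice_step must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExtractionConfig":
        """Load a config from a YAML or JSON mapping of knob names."""
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planes"] = list(d["planes"])
        return d

    def digest(self) -> str:
        """Short stable hash of the configuration, recorded as provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.blake2s(blob, digest_size=8).hexdigest()
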