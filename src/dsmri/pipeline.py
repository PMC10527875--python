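"""Per-scan feature extraction and the scans x features table.

One scan yields exactly 22 scalars: per-slice features are computed for
every retained slice of the three anatomical planes and pooled by an
unweighted mean, ignoring missing per-slice values.  Slices whose foreground
covers less than ``min_fg_fraction`` of pixels are excluded; a feature
missing on every retained slice stays missing.  The reduction across planes
keeps the feature space 22-dimensional, matching the downstream analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dsmri._version import __version__ as _version
from dsmri.config import ExtractionConfig
from dsmri.features import frequency, spatial, texture, wavelet
from dsmri.preprocessing import MaskedSlice, derive_seed, detect_foreground
from dsmri.volume_io import Volume, extract_slices, read_volume

logger = logging.getLogger(__name__)

#: Canonical feature order of the 22-dimensional vector.
FEATURE_NAMES: tuple[str, ...] = (
    "MEAN", "RNG", "VAR", "CV", "PSNR", "SNR1", "SNR2", "CNR", "CJV", "EFC",
    "SNRF", "LFR", "HFR",
    "WCS", "WQS", "WCE",
    "Contrast", "Dissimilarity", "ASM", "Homogeneity", "Correlation", "Energy",
)


class ScanRejectedError(RuntimeError):
    """Raised when a scan has no usable slice in any requested plane."""


class SchemaError(ValueError):
    """Raised when a feature-table file lacks a mandatory column."""


def compute_slice_features(
    masked: MaskedSlice, config: ExtractionConfig = ExtractionConfig(), seed: int = 0
) -> dict[str, float]:
    """All 22 features of one masked slice; missing values are nan."""
    out: dict[str, float] = {}
    out["MEAN"], out["RNG"], out["VAR"] = spatial.intensity_stats(masked)
    out["CV"] = spatial.coefficient_of_variation(masked)
    out["PSNR"], out["SNR1"], out["SNR2"], out["CNR"] = spatial.noise_metrics(
        masked, seed=seed, patch_side=config.patch_side, bg_guard=config.bg_guard
    )
    out["CJV"] = spatial.cjv(masked)
    out["EFC"] = spatial.efc(masked)

    out["SNRF"] = frequency.snrf(masked, config.snrf_signal_radius_fraction)
    out["LFR"] = frequency.lfr(masked)
    out["HFR"] = frequency.hfr(masked)

    try:
        coeffs = wavelet.wavelet_decompose(masked, config.wavelet)
    except ValueError:
        out["WCS"] = out["WQS"] = out["WCE"] = float("nan")
    else:
        out["WCS"] = wavelet.wcs(coeffs)
        out["WQS"] = wavelet.wqs(coeffs)
        out["WCE"] = wavelet.wce(coeffs)

    quantized = texture.quantize_levels(masked, config.glcm_levels)
    glcm = texture.compute_glcm(quantized, config.glcm_levels, config.glcm_distance)
    if glcm is None:
        for name in ("Contrast", "Dissimilarity", "ASM", "Homogeneity", "Correlation", "Energy"):
            out[name] = float("nan")
    else:
        props = texture.glcm_properties(glcm)
        out["Contrast"] = props.contrast
        out["Dissimilarity"] = props.dissimilarity
        out["ASM"] = props.asm
        out["Homogeneity"] = props.homogeneity
        out["Correlation"] = props.correlation
        out["Energy"] = props.energy
    return out


def compute_scan_features(
    volume: Volume, config: ExtractionConfig = ExtractionConfig()
) -> pd.Series:
    """Aggregate per-slice features of one scan into a 22-feature vector.

    Returns a Series indexed by :data:`FEATURE_NAMES`, named after the scan
    id.  Non-finite per-slice values (missing or the PSNR infinity flag) are
    excluded from the mean; a feature with no finite value on any slice is
    recorded as nan.

    Raises
    ------
    ScanRejectedError
        If no slice in any requested plane retains >= ``min_fg_fraction``
        foreground coverage.
    """
    rows: list[dict[str, float]] = []
    n_slices = 0
    for plane in config.planes:
        for index, image in enumerate(extract_slices(volume, plane)):
            if index % config.slice_step:
                continue
            n_slices += 1
            masked = detect_foreground(image)
            if not masked.usable or masked.fg_fraction < config.min_fg_fraction:
                continue
            seed = derive_seed(config.seed, volume.scan_id, plane, index)
            rows.append(compute_slice_features(masked, config, seed=seed))
    if not rows:
        raise ScanRejectedError(
            f"scan {volume.scan_id!r}: no slice with foreground coverage >= "
            f"{config.min_fg_fraction:.2%} in planes {config.planes} "
            f"({n_slices} slices examined)"
        )
    frame = pd.DataFrame(rows, columns=FEATURE_NAMES)
    values = frame.to_numpy(dtype=np.float64)
    values[~np.isfinite(values)] = np.nan
    with warnings.catch_warnings():
        # a feature missing on every slice is a documented outcome, not an error
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled = np.nanmean(values, axis=0)
    missing = [name for name, v in zip(FEATURE_NAMES, pooled) if not np.isfinite(v)]
    if missing:
        logger.info("scan %s: features missing on every slice: %s", volume.scan_id, missing)
    logger.debug("scan %s: %d/%d slices retained", volume.scan_id, len(rows), n_slices)
    return pd.Series(pooled, index=list(FEATURE_NAMES), name=volume.scan_id)


@dataclass
class FeatureTable:
    """Scans x (22 features + domain labels), with provenance.

    ``df`` holds one row per scan: a ``scan_id`` column, the 22 feature
    columns in canonical order, then any label columns.  Missing feature
    values are nan.
    """

    df: pd.DataFrame
    label_cols: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("scan_id", *FEATURE_NAMES) if c not in self.df.columns]
        if missing:
            raise SchemaError(f"feature table lacks mandatory column(s): {missing}")
        if self.df["scan_id"].duplicated().any():
            dupes = self.df.loc[self.df["scan_id"].duplicated(), "scan_id"].tolist()
            raise ValueError(f"duplicate scan_id values: {dupes}")
        self.label_cols = tuple(self.label_cols)
        order = ["scan_id", *FEATURE_NAMES, *self.label_cols]
        self.df = self.df.loc[:, order].reset_index(drop=True)

    @property
    def n_scans(self) -> int:
        return len(self.df)

    def feature_matrix(self) -> np.ndarray:
        """(n_scans, 22) float matrix in canonical feature order."""
        return self.df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=np.float64)

    def labels(self, label_col: str) -> np.ndarray:
        if label_col not in self.label_cols:
            raise SchemaError(f"no label column {label_col!r}; have {list(self.label_cols)}")
        values = self.df[label_col]
        if values.isna().any() or (values.astype(str).str.len() == 0).any():
            raise ValueError(f"label column {label_col!r} contains empty labels")
        return values.to_numpy()


def extract_features(
    volumes,
    config: ExtractionConfig = ExtractionConfig(),
    labels: pd.DataFrame | str | Path | None = None,
) -> FeatureTable:
    """Extract the feature table for a collection of scans.

    Parameters
    ----------
    volumes
        An iterable of :class:`Volume`, an iterable of NIfTI paths, or a
        directory containing ``.nii``/``.nii.gz`` files.
    labels
        Optional per-scan label table (DataFrame or CSV path) with a
        ``scan_id`` column; all other columns become label columns.
    """
    if isinstance(volumes, (str, Path)) and Path(volumes).is_dir():
        paths = sorted(
            p for p in Path(volumes).iterdir() if p.name.endswith((".nii", ".nii.gz"))
        )
        volumes = [read_volume(p) for p in paths]
    else:
        volumes = [v if isinstance(v, Volume) else read_volume(v) for v in volumes]

    rows = [compute_scan_features(v, config) for v in volumes]
    df = pd.DataFrame(rows).reset_index(names="scan_id")

    label_cols: tuple[str, ...] = ()
    if labels is not None:
        if isinstance(labels, (str, Path)):
            labels = pd.read_csv(labels, dtype={"scan_id": str})
        if "scan_id" not in labels.columns:
            raise SchemaError("label table lacks mandatory column(s): ['scan_id']")
        label_cols = tuple(c for c in labels.columns if c != "scan_id")
        df = df.merge(labels, on="scan_id", how="left", validate="one_to_one")

    provenance = {
        "tool_version": _version,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    return FeatureTable(df=df, label_cols=label_cols, provenance=provenance)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV (missing values serialize as empty cells)."""
    path = Path(path)
    table.df.to_csv(path, index=False, na_rep="")
    return path


def read_feature_table(path: str | Path, label_cols: tuple[str, ...] | None = None) -> FeatureTable:
    """Read a feature-table CSV.

    Columns are matched by header name, so permuted column order is accepted
    and re-emitted canonically.  Columns other than ``scan_id`` and the 22
    features are treated as label columns unless ``label_cols`` narrows them.
    """
    df = pd.read_csv(path, dtype={"scan_id": str})
    missing = [c for c in ("scan_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    extras = tuple(c for c in df.columns if c != "scan_id" and c not in FEATURE_NAMES)
    if label_cols is not None:
        unknown = set(label_cols) - set(extras)
        if unknown:
            raise SchemaError(f"{path}: label column(s) not found: {sorted(unknown)}")
        extras = tuple(label_cols)
    return FeatureTable(df=df, label_cols=extras)
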