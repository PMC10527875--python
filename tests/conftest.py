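"""Shared fixtures and synthetic-table helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dsmri.pipeline import FEATURE_NAMES, FeatureTable
from dsmri.preprocessing import MaskedSlice, full_mask_slice


def make_gaussian_table(
    n_per_domain: int,
    n_domains: int = 2,
    shift: float = 0.0,
    shifted_features: tuple[str, ...] | None = None,
    seed: int = 0,
) -> FeatureTable:
    """A feature table of i.i.d. standard-normal features per scan.

    ``shift`` adds a mean offset (in SD units) per successive domain, either
    to every feature or only to ``shifted_features``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for d in range(n_domains):
        x = rng.standard_normal((n_per_domain, len(FEATURE_NAMES)))
        if shift:
            if shifted_features is None:
                x += d * shift
            else:
                for name in shifted_features:
                    x[:, FEATURE_NAMES.index(name)] += d * shift
        df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
        df.insert(0, "scan_id", [f"d{d}_{i:03d}" for i in range(n_per_domain)])
        df["site"] = f"domain{d}"
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return FeatureTable(df=df, label_cols=("site",))


def masked_from_regions(
    fg_values: np.ndarray, bg_values: np.ndarray | None = None
) -> MaskedSlice:
    """Stack a foreground block left of a background block into one slice."""
    fg_values = np.asarray(fg_values, dtype=np.float64)
    if bg_values is None:
        return full_mask_slice(fg_values)
    bg_values = np.asarray(bg_values, dtype=np.float64)
    assert fg_values.shape[0] == bg_values.shape[0]
    image = np.hstack([fg_values, bg_values])
    fg = np.zeros(image.shape, dtype=bool)
    fg[:, : fg_values.shape[1]] = True
    return MaskedSlice(image=image, fg_mask=fg, bg_mask=~fg)


def diagonal_stripes(shape: tuple[int, int], values: list[float]) -> np.ndarray:
    """Periodic diagonal stripes: pixel (i, j) takes values[(i + j) % len].

    Every 5x5 window of a period-5 stripe pattern contains each value
    exactly 5 times, so all admissible patches share the same mean and SD.
    """
    i, j = np.indices(shape)
    return np.asarray(values, dtype=np.float64)[(i + j) % len(values)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def disk_slice() -> tuple[np.ndarray, np.ndarray]:
    """A noisy disk phantom slice and its true foreground mask."""
    rng = np.random.default_rng(7)
    shape = (96, 96)
    i, j = np.indices(shape)
    true_mask = (i - 48) ** 2 + (j - 48) ** 2 <= 20**2
    image = np.where(true_mask, 100.0, 0.0) + rng.normal(0, 2.0, shape)
    return image, true_mask
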