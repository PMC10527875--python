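"""Synthetic multi-site phantom cohorts with scanner-induced domain shift.

The phantom is a centered two-shell ellipsoid (a crude tissue contrast: a
bright core inside a dimmer shell) on a dark background — deliberately not
a realistic brain, so masks, volumes and noise levels all have analytic
ground truth.  A :class:`ScannerProfile` injects the acquisition effects
that drive site differences in real multi-center MRI:

* additive Gaussian noise (``noise_sd``, everywhere, emulating thermal
  noise — magnitude-image Rician statistics are not modelled);
* global contrast change via a gamma exponent on normalized tissue
  intensity (``contrast_gamma``);
* point-spread smoothing (``smoothing_fwhm`` in mm);
* a smooth multiplicative low-order polynomial bias field
  (``bias_field_amplitude``);
* isotropic voxel size (``voxel_size`` in mm) and overall intensity scale
  (``base_intensity``).

Within-site (subject-level) variability comes from three per-volume
ingredients: multiplicative jitter of the base intensity and ellipsoid
semi-axes, and a smooth random "anatomy" texture field modulating the
tissue.  The texture term matters: without it every volume of a site is
nearly identical, all 22 features separate sites perfectly, and
feature-importance rankings degenerate into arbitrary tie-breaking — unlike
real cohorts, where anatomy dominates within-site variance for intensity
and texture features while air-based noise metrics track the scanner.

Cohorts are fully reproducible from (profiles, seed); per-volume jitter is
drawn from sub-streams keyed by (seed, site, index), so adding a site never
perturbs existing volumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from dsmri.preprocessing import derive_seed
from dsmri.volume_io import Volume, write_volume

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma.
_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

#: Relative intensity of the outer shell (core = 1).
_SHELL_LEVEL = 0.6
#: Normalized radius where the core ends and the shell begins.
_CORE_RADIUS = 0.7


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition parameters of one simulated site."""

    site_name: str
    noise_sd: float = 5.0
    contrast_gamma: float = 1.0
    smoothing_fwhm: float = 1.0
    bias_field_amplitude: float = 0.1
    voxel_size: float = 1.0
    base_intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not 0 <= self.bias_field_amplitude < 1:
            raise ValueError("bias_field_amplitude must lie in [0, 1)")
        if self.contrast_gamma <= 0 or self.base_intensity <= 0:
            raise ValueError("contrast_gamma and base_intensity must be > 0")


def ellipsoid_mask(
    shape: tuple[int, int, int],
    semi_axes: tuple[float, float, float],
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of voxels inside the ellipsoid (analytic ground truth)."""
    if center is None:
        center = tuple((s - 1) / 2.0 for s in shape)
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return rho2 <= 1.0


def _normalized_radius(
    shape: tuple[int, int, int], semi_axes: tuple[float, float, float]
) -> np.ndarray:
    center = tuple((s - 1) / 2.0 for s in shape)
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return np.sqrt(rho2)


def _bias_field(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * p(x, y, z), |p| <= 1.

    p is a random low-order polynomial (linear + pairwise quadratic terms)
    over coordinates normalized to [-1, 1].
    """
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    p = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.abs(p).max()
    if peak > 0:
        p = p / peak
    return 1.0 + amplitude * p


def generate_phantom(
    profile: ScannerProfile,
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    scan_id: str = "",
    semi_axes: tuple[float, float, float] | None = None,
    base_intensity: float | None = None,
    anatomy_texture: float = 0.1,
    skull_strip: bool = False,
) -> Volume:
    """One deterministic phantom volume under a scanner profile.

    The ellipsoid semi-axes default to a quarter of each dimension, so the
    foreground spans about half the field of view.  Pipeline, in order:
    two-shell ellipsoid, gamma contrast transform, multiplicative bias
    field, additive Gaussian noise, then the Gaussian PSF applied to the
    noisy image.  Applying the PSF after noise emulates reconstruction-side
    smoothing, which attenuates the noise's high-frequency content exactly
    as a smoother scanner protocol does; the background therefore contains
    (smoothed) noise only.  Intensities are not clipped at zero; the noise
    is a Gaussian approximation of magnitude-image noise.

    With ``skull_strip=True`` every voxel outside the ellipsoid is zeroed
    after noise, emulating skull-stripped input whose background is
    identically zero (so sigma_B-dependent features go missing downstream).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError(f"shape must be 3 components >= 32, got {shape}")
    if semi_axes is None:
        semi_axes = tuple(s / 4.0 for s in shape)
    base = profile.base_intensity if base_intensity is None else float(base_intensity)
    rng = np.random.default_rng(seed)

    rho = _normalized_radius(shape, semi_axes)
    tissue = np.zeros(shape)
    tissue[rho <= 1.0] = _SHELL_LEVEL
    tissue[rho <= _CORE_RADIUS] = 1.0
    if anatomy_texture > 0:
        # smooth per-volume random field: subject-level tissue variation
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        field /= max(field.std(), 1e-12)
        tissue *= np.clip(1.0 + anatomy_texture * field, 0.0, None)

    image = base * np.power(tissue, profile.contrast_gamma, where=tissue > 0, out=np.zeros(shape))
    image *= _bias_field(shape, profile.bias_field_amplitude, rng)
    if profile.noise_sd > 0:
        image = image + rng.normal(0.0, profile.noise_sd, size=shape)
    sigma_vox = profile.smoothing_fwhm * _FWHM_TO_SIGMA / profile.voxel_size
    if sigma_vox > 0:
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)
    if skull_strip:
        image = np.where(rho <= 1.0, image, 0.0)

    return Volume(
        data=image,
        spacing=(profile.voxel_size,) * 3,
        scan_id=scan_id or f"{profile.site_name}_seed{seed}",
        source_path="",
    )


def vendor_like_profiles(sites: int) -> list[ScannerProfile]:
    """Scanner profiles with jointly varying noise, contrast and smoothing.

    Each successive site is noisier, lower-contrast and smoother than the
    last, emulating distinct vendor/protocol combinations.
    """
    return [
        ScannerProfile(
            site_name=f"site{k + 1}",
            noise_sd=5.0 + 10.0 * k,
            contrast_gamma=1.0 + 0.5 * k,
            smoothing_fwhm=1.0 + 1.5 * k,
        )
        for k in range(sites)
    ]


def generate_site(
    profile: ScannerProfile,
    n: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    jitter: float = 0.03,
    anatomy_texture: float = 0.1,
    skull_strip: bool = False,
) -> list[Volume]:
    """``n`` jittered volumes of one site (scan ids ``<site>_<index>``).

    Each volume's randomness is keyed by (seed, site name, index), so sites
    are independent and cohorts compose from per-site calls.
    """
    volumes = []
    for index in range(n):
        sub_seed = derive_seed(seed, profile.site_name, index)
        jitter_rng = np.random.default_rng(derive_seed(sub_seed, "jitter"))
        base = profile.base_intensity * (1.0 + jitter * jitter_rng.standard_normal())
        semi = tuple(
            (s / 4.0) * (1.0 + jitter * jitter_rng.standard_normal()) for s in shape
        )
        volumes.append(
            generate_phantom(
                profile,
                shape=shape,
                seed=sub_seed,
                scan_id=f"{profile.site_name}_{index:03d}",
                semi_axes=semi,
                base_intensity=base,
                anatomy_texture=anatomy_texture,
                skull_strip=skull_strip,
            )
        )
    return volumes


def generate_multisite_cohort(
    profiles: list[ScannerProfile],
    n_per_site: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    jitter: float = 0.03,
    anatomy_texture: float = 0.1,
    out_dir: str | Path | None = None,
    skull_strip: bool = False,
) -> tuple[list[Volume], pd.DataFrame]:
    """A labelled multi-site cohort of phantoms.

    Per volume, the base intensity and ellipsoid semi-axes receive a small
    multiplicative Gaussian jitter (relative SD ``jitter``) so within-site
    variance is nonzero.  With ``out_dir`` set, writes one ``.nii.gz`` per
    volume plus ``labels.csv`` and the resolved ``profiles.json``.

    Returns the volumes and a labels table with columns ``scan_id``,
    ``site``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 scanner profiles")
    if n_per_site < 2:
        raise ValueError("need at least 2 volumes per site")
    names = [p.site_name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate site names: {names}")

    volumes: list[Volume] = []
    for profile in profiles:
        volumes.extend(
            generate_site(
                profile,
                n_per_site,
                shape=shape,
                seed=seed,
                jitter=jitter,
                anatomy_texture=anatomy_texture,
                skull_strip=skull_strip,
            )
        )
    labels = pd.DataFrame(
        {
            "scan_id": [v.scan_id for v in volumes],
            "site": [v.scan_id.rsplit("_", 1)[0] for v in volumes],
        }
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for volume in volumes:
            write_volume(volume, out_dir / f"{volume.scan_id}.nii.gz")
        labels.to_csv(out_dir / "labels.csv", index=False)
        with open(out_dir / "profiles.json", "w") as fh:
            json.dump([dataclasses.asdict(p) for p in profiles], fh, indent=2)
    return volumes, labels
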