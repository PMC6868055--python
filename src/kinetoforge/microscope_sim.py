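"""Widefield fluorescence image simulation with a Gaussian PSF.

Point emitters are convolved with an anisotropic 3D Gaussian approximation
of the widefield point-spread function,

    sigma_xy = 0.21 * lambda / NA
    sigma_z  = 0.66 * lambda * n / NA**2   (n = 1.515, immersion oil),

and accumulated into a multi-channel z-stack of expected photon counts.
In-plane contributions are integrated exactly over pixel extents
(error-function differences); the axial profile is point-sampled at plane
centers and weighted by the plane spacing, so the summed stack of a single
emitter carries approximately ``photons_per_fluorophore`` photons.

A separate camera-noise step applies Poisson shot noise, Gaussian read
noise and a constant baseline offset.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.special import erf

from .fluorophores import FluorophoreSet

__all__ = ["OpticsParams", "NoiseParams", "ImageStack", "psf_sigma",
           "render_stack", "add_noise", "write_stack", "read_stack"]

logger = logging.getLogger(__name__)

REFRACTIVE_INDEX = 1.515     # immersion oil
SIGMA_XY_COEF = 0.21
SIGMA_Z_COEF = 0.66


@dataclass
class OpticsParams:
    """Imaging geometry of the simulated widefield microscope.

    ``pixel_size`` of 65 nm corresponds to a 6.5 um camera pixel behind a
    100x objective. ``n_zplanes`` must be odd so a central focal plane
    exists; planes are spaced ``z_step`` apart and centered on z = 0.
    """

    numerical_aperture: float = 1.4
    wavelengths: dict = field(default_factory=lambda: {"green": 510.0, "red": 580.0})
    pixel_size: float = 65.0
    n_zplanes: int = 7
    z_step: float = 300.0
    image_size: tuple = (50, 50)        # (rows, cols) pixels
    photons_per_fluorophore: float = 2000.0

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0 or self.pixel_size <= 0 \
                or self.z_step <= 0 or self.photons_per_fluorophore <= 0:
            raise ValueError("optics parameters must be positive")
        if self.n_zplanes < 1 or self.n_zplanes % 2 == 0:
            raise ValueError("n_zplanes must be a positive odd count")
        self.image_size = tuple(int(v) for v in self.image_size)

    @property
    def channel_names(self) -> list:
        return list(self.wavelengths)


@dataclass
class NoiseParams:
    """Camera noise model: shot noise, read noise and baseline offset."""

    read_noise_sd: float = 3.0
    baseline: float = 100.0
    apply_shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class ImageStack:
    """Multi-channel z-stack of (expected or noisy) photon counts.

    ``voxels`` has shape (channels, z, rows, cols); the channel order is
    that of ``optics.channel_names``.
    """

    voxels: np.ndarray
    optics: OpticsParams
    channel_map: list

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        ny, nx = self.optics.image_size
        expected = (len(self.channel_map), self.optics.n_zplanes, ny, nx)
        if self.voxels.shape != expected:
            raise ValueError(f"voxel shape {self.voxels.shape} != {expected}")
        if np.any(self.voxels < 0):
            raise ValueError("negative voxel values")

    def channel(self, name: str) -> np.ndarray:
        return self.voxels[self.channel_map.index(name)]


def psf_sigma(optics: OpticsParams, channel: str) -> tuple[float, float]:
    """Gaussian PSF widths (sigma_xy, sigma_z) in nm for one channel."""
    lam = optics.wavelengths[channel]
    sigma_xy = SIGMA_XY_COEF * lam / optics.numerical_aperture
    sigma_z = SIGMA_Z_COEF * lam * REFRACTIVE_INDEX / optics.numerical_aperture**2
    return sigma_xy, sigma_z


def _axis_edges(n: int, pitch: float) -> np.ndarray:
    """Pixel-edge coordinates (nm) for an n-pixel axis centered on 0."""
    return (np.arange(n + 1) - n / 2.0) * pitch


def render_stack(fluors: FluorophoreSet, optics: OpticsParams) -> ImageStack:
    """Render a fluorophore set into an expected-photon-count z-stack.

    Model coordinates map onto the image with +x along columns, +y along
    rows, and the field center at the coordinate origin. Each fluorophore
    adds ``intensity * photons_per_fluorophore`` photons distributed over
    the stack; contributions are summed per channel (linearity).
    """
    present = set(fluors.channels)
    unknown = present - set(optics.channel_names)
    if unknown:
        raise ValueError(f"fluorophore channels {sorted(unknown)} not in optics "
                         f"channel map {optics.channel_names}")
    ny, nx = optics.image_size
    nz = optics.n_zplanes
    voxels = np.zeros((len(optics.channel_names), nz, ny, nx), dtype=float)
    x_edges = _axis_edges(nx, optics.pixel_size)
    y_edges = _axis_edges(ny, optics.pixel_size)
    z_centers = (np.arange(nz) - (nz - 1) / 2.0) * optics.z_step

    for ci, ch in enumerate(optics.channel_names):
        sub = fluors.select_channel(ch)
        if not len(sub):
            continue
        sxy, sz = psf_sigma(optics, ch)
        sq2 = np.sqrt(2.0)
        # (n_fluor, n_edges) error-function CDFs along each in-plane axis
        cx = erf((x_edges[None, :] - sub.xyz[:, 0:1]) / (sq2 * sxy)) / 2.0
        cy = erf((y_edges[None, :] - sub.xyz[:, 1:2]) / (sq2 * sxy)) / 2.0
        px = np.diff(cx, axis=1)                     # (n, nx) pixel masses
        py = np.diff(cy, axis=1)                     # (n, ny)
        wz = np.exp(-(z_centers[None, :] - sub.xyz[:, 2:3])**2 / (2.0 * sz**2))
        wz *= optics.z_step / (np.sqrt(2.0 * np.pi) * sz)   # (n, nz)
        amp = sub.intensity * optics.photons_per_fluorophore
        # sum_n amp_n * wz[n,k] * py[n,i] * px[n,j]
        voxels[ci] = np.einsum("n,nk,ni,nj->kij", amp, wz, py, px, optimize=True)

    return ImageStack(np.clip(voxels, 0.0, None), optics, optics.channel_names)


def add_noise(stack: ImageStack, noise: NoiseParams, seed: int) -> ImageStack:
    """Apply the camera noise model to an expected-photon stack."""
    rng = np.random.default_rng(seed)
    v = stack.voxels
    if noise.apply_shot_noise:
        v = rng.poisson(v).astype(float)
    else:
        v = v.copy()
    if noise.read_noise_sd > 0:
        v += rng.normal(0.0, noise.read_noise_sd, size=v.shape)
    v = np.clip(v, 0.0, None) + noise.baseline
    return ImageStack(v, stack.optics, list(stack.channel_map))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a 16-bit multi-page TIFF plus a JSON sidecar.

    Pages are ordered channel-major (all z planes of channel 0, then
    channel 1, ...). Voxels are clipped to [0, 65535] and rounded; the
    sidecar records the optics parameters and channel order.
    """
    path = Path(path)
    data = np.clip(np.rint(stack.voxels), 0, 65535).astype(np.uint16)
    c, z, ny, nx = data.shape
    tifffile.imwrite(path, data.reshape(c * z, ny, nx))
    sidecar = {
        "optics": asdict(stack.optics),
        "channel_map": list(stack.channel_map),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    A missing sidecar is tolerated: default optics are assumed (with a
    warning) and the page count must then match the defaults.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        try:
            opt_kwargs = dict(meta["optics"])
            opt_kwargs["image_size"] = tuple(opt_kwargs["image_size"])
            optics = OpticsParams(**opt_kwargs)
            channel_map = list(meta["channel_map"])
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed stack sidecar {sidecar_path.name}: {exc}") from exc
    else:
        warnings.warn(f"no sidecar for {path.name}; assuming default optics")
        optics = OpticsParams()
        channel_map = optics.channel_names
    c, z = len(channel_map), optics.n_zplanes
    if pages.shape[0] != c * z:
        raise ValueError(f"stack {path.name}: expected {c * z} pages "
                         f"(channels x z-planes), found {pages.shape[0]}")
    voxels = pages.reshape(c, z, *pages.shape[1:]).astype(float)
    return ImageStack(voxels, optics, channel_map)
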