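"""Band-power scalp images: ERPs -> 3-plane (alpha/beta/gamma) topomaps.

Per-channel power spectral density is estimated with Welch's method over
the full epoch and integrated over the alpha (9-13 Hz), beta (14-30 Hz)
and gamma (31-60 Hz) bands. Electrode positions are projected from the
unit sphere to the plane (azimuthal equidistant about the vertex), band
powers are min-max normalized per band, interpolated over the scalp disk
(piecewise-cubic inside the electrode hull, nearest-neighbor between hull
and disk edge) and the three band planes are stacked as the R, G and B
channels of one image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay

from .montage import Montage, project_montage

__all__ = [
    "BandDef",
    "DEFAULT_BANDS",
    "BandpowerMatrix",
    "TopomapImage",
    "compute_bandpowers",
    "render_topomap",
    "topomap_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi")


DEFAULT_BANDS = (
    BandDef("alpha", 9.0, 13.0),
    BandDef("beta", 14.0, 30.0),
    BandDef("gamma", 31.0, 60.0),
)


@dataclass
class BandpowerMatrix:
    """Per-channel integrated band power (uV^2), (n_channels, n_bands)."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]


@dataclass
class TopomapImage:
    """H x W x 3 scalp image in [0, 1] with rendering metadata.

    Row 0 is anterior (nose); columns run subject-left to subject-right.
    Plane order matches the band order (R = alpha, G = beta, B = gamma for
    the defaults). ``norm`` holds the per-band (min, max) power used for
    normalization; ``electrode_pixels`` the (row, col) per electrode.
    """

    pixels: np.ndarray
    mask: np.ndarray
    norm: np.ndarray              # (n_bands, 2)
    electrode_pixels: np.ndarray  # (n_channels, 2) int
    channel_names: tuple[str, ...]
    band_names: tuple[str, ...]


def compute_bandpowers(erp: np.ndarray, sfreq: float,
                       bands=DEFAULT_BANDS) -> BandpowerMatrix:
    """Welch PSD per channel integrated (trapezoid) over each band.

    ``erp`` is (n_channels, n_times) covering the full epoch. Welch uses
    Hann windows of min(256, n_times) samples with 50% overlap.
    """
    erp = np.asarray(erp, dtype=float)
    if erp.ndim != 2:
        raise ValueError("erp must be (n_channels, n_times)")
    for b in bands:
        if b.hi > sfreq / 2:
            raise ValueError(
                f"band {b.name} ({b.lo}-{b.hi} Hz) unobservable at sfreq={sfreq}")
    nper = min(256, erp.shape[1])
    freqs, psd = signal.welch(erp, fs=sfreq, window="hann", nperseg=nper,
                              noverlap=nper // 2, axis=-1)
    vals = np.empty((erp.shape[0], len(bands)))
    for j, b in enumerate(bands):
        # integrate the piecewise-linear PSD over [lo, hi] exactly: interior
        # bins plus interpolated values at the band edges, so band powers
        # are additive over any partition of a band
        inner = freqs[(freqs > b.lo) & (freqs < b.hi)]
        grid = np.concatenate([[max(b.lo, freqs[0])], inner,
                               [min(b.hi, freqs[-1])]])
        if grid[-1] <= grid[0]:
            raise ValueError(f"band {b.name}: no PSD support; epoch too short")
        interp = np.vstack([np.interp(grid, freqs, psd[c])
                            for c in range(psd.shape[0])])
        vals[:, j] = np.trapezoid(interp, grid, axis=-1)
    names = tuple(f"ch{i}" for i in range(erp.shape[0]))
    return BandpowerMatrix(values=vals, channel_names=names,
                           band_names=tuple(b.name for b in bands))


class _Renderer:
    """Reusable interpolation geometry for one montage/grid combination."""

    def __init__(self, coords2d: np.ndarray, grid: tuple[int, int] = (32, 32),
                 head_scale: float = 1.02):
        self.coords2d = np.asarray(coords2d, dtype=float)
        if len(self.coords2d) < 4:
            raise ValueError("need at least 4 electrodes to render")
        self.grid = grid
        self.radius = head_scale * np.max(np.hypot(*self.coords2d.T))
        H, W = grid
        # Row 0 anterior: y decreases with row index.
        self.xs = np.linspace(-self.radius, self.radius, W)
        self.ys = np.linspace(self.radius, -self.radius, H)
        gx, gy = np.meshgrid(self.xs, self.ys)
        self.gxy = np.column_stack([gx.ravel(), gy.ravel()])
        self.mask = (gx**2 + gy**2 <= self.radius**2)
        self.tri = Delaunay(self.coords2d)
        col = np.clip(np.round((self.coords2d[:, 0] + self.radius)
                               / (2 * self.radius) * (W - 1)), 0, W - 1)
        row = np.clip(np.round((self.radius - self.coords2d[:, 1])
                               / (2 * self.radius) * (H - 1)), 0, H - 1)
        self.electrode_pixels = np.column_stack([row, col]).astype(int)

    def plane(self, values01: np.ndarray) -> np.ndarray:
        interp = CloughTocher2DInterpolator(self.tri, values01)
        z = interp(self.gxy)
        bad = np.isnan(z)
        if bad.any():
            near = NearestNDInterpolator(self.coords2d, values01)
            z[bad] = near(self.gxy[bad])
        z = z.reshape(self.grid)
        z[~self.mask] = 0.0
        return np.clip(z, 0.0, 1.0)


def render_topomap(bp: BandpowerMatrix, coords2d: np.ndarray,
                   grid: tuple[int, int] = (32, 32),
                   renderer: _Renderer | None = None) -> TopomapImage:
    """Render one band-stacked scalp image from a bandpower matrix.

    Each band is min-max normalized over electrodes before interpolation;
    a constant band maps to a uniform 0.5 plane with a warning.
    """
    r = renderer if renderer is not None else _Renderer(coords2d, grid)
    n_bands = bp.values.shape[1]
    pixels = np.zeros(r.grid + (n_bands,), dtype=np.float32)
    norm = np.empty((n_bands, 2))
    for j in range(n_bands):
        v = bp.values[:, j].astype(float)
        vmin, vmax = float(v.min()), float(v.max())
        norm[j] = (vmin, vmax)
        if vmax == vmin:
            logger.warning("band %s constant; rendering uniform 0.5 plane",
                           bp.band_names[j])
            plane = np.where(r.mask, 0.5, 0.0)
        else:
            plane = r.plane((v - vmin) / (vmax - vmin))
        pixels[:, :, j] = plane
    return TopomapImage(pixels=pixels, mask=r.mask, norm=norm,
                        electrode_pixels=r.electrode_pixels,
                        channel_names=bp.channel_names,
                        band_names=bp.band_names)


def topomap_pipeline(erps: np.ndarray, sfreq: float, montage: Montage,
                     bands=DEFAULT_BANDS,
                     grid: tuple[int, int] = (32, 32)) -> tuple[np.ndarray, TopomapImage]:
    """Convert a stack of ERPs (n, channels, times) to images (n, H, W, 3).

    Returns the image stack and the last TopomapImage (carrying the shared
    electrode-pixel geometry).
    """
    coords = project_montage(montage)
    r = _Renderer(coords, grid)
    out = np.empty((erps.shape[0],) + grid + (len(bands),), dtype=np.float32)
    last = None
    for i in range(erps.shape[0]):
        bp = compute_bandpowers(erps[i], sfreq, bands)
        bp.channel_names = montage.channel_names
        last = render_topomap(bp, coords, grid, renderer=r)
        out[i] = last.pixels
    return out, last
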