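"""64-channel scalp montage on an idealized unit sphere.

Electrode positions follow the extended 10-10 layout used by 64-channel
caps that include the cerebellar sites CB1/CB2 below the occipital row.
Coordinates are constructed analytically rather than taken from a digitized
head model so that left/right mirror pairs are exactly symmetric: the outer
temporal ring lies on a circle 72 degrees from the vertex with sites every
18 degrees of azimuth, and each coronal chain (F, FC, C, CP, P, ...) is
spherically interpolated from its left ring electrode through its midline
electrode to its right ring electrode.

Axes: +x = subject's right ear, +y = nose (anterior), +z = vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "default_montage", "project_montage"]


@dataclass(frozen=True)
class Montage:
    """Channel names plus unit-sphere xyz coordinates (n_channels, 3)."""

    channel_names: tuple[str, ...]
    coords3d: np.ndarray

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(names) != len(set(names)):
            raise ValueError("channel names must be unique")
        coords = np.asarray(self.coords3d, dtype=float)
        if coords.shape != (len(names), 3):
            raise ValueError("coords3d must be (n_channels, 3)")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=0.01):
            raise ValueError("montage coordinates must lie on the unit sphere")
        object.__setattr__(self, "coords3d", coords)

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tx\ty\tz\n")
            for name, (x, y, z) in zip(self.channel_names, self.coords3d):
                fh.write(f"{name}\t{x:.9f}\t{y:.9f}\t{z:.9f}\n")

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        names, rows = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                name, x, y, z = line.split("\t")
                names.append(name)
                rows.append([float(x), float(y), float(z)])
        return cls(tuple(names), np.array(rows))


def _sph(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at a polar angle from the vertex and an azimuth from the
    nose (positive toward the right ear)."""
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _chain(left: np.ndarray, mid: np.ndarray, right: np.ndarray, n: int) -> list[np.ndarray]:
    """n evenly spaced points from `left` through `mid` to `right` (two
    great-circle halves, so the chain passes exactly through the midline)."""
    out = []
    for i in range(n):
        t = i / (n - 1)
        if t <= 0.5:
            out.append(_slerp(left, mid, 2 * t))
        else:
            out.append(_slerp(mid, right, 2 * t - 1))
    return out


_RING_POLAR = 72.0  # outer 10% ring, degrees from the vertex


def default_montage() -> Montage:
    """The packaged 64-channel extended 10-10 montage (includes CB1/CB2)."""
    pos: dict[str, np.ndarray] = {}

    # Outer ring: 18-degree azimuth steps, 72 degrees from the vertex.
    ring = {
        "FPZ": 0, "FP2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
        "TP8": 108, "P8": 126, "PO8": 144, "O2": 162, "OZ": 180,
        "O1": -162, "PO7": -144, "P7": -126, "TP7": -108, "T7": -90,
        "FT7": -72, "F7": -54, "AF7": -36, "FP1": -18,
    }
    for name, az in ring.items():
        pos[name] = _sph(_RING_POLAR, az)

    # Midline: 18-degree polar steps front (az 0) and back (az 180).
    pos["CZ"] = _sph(0.0, 0.0)
    pos["FCZ"] = _sph(18.0, 0.0)
    pos["FZ"] = _sph(36.0, 0.0)
    pos["CPZ"] = _sph(18.0, 180.0)
    pos["PZ"] = _sph(36.0, 180.0)
    pos["POZ"] = _sph(54.0, 180.0)

    # Coronal chains interpolated between the temporal ring electrodes.
    chains = [
        (["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"], "FZ"),
        (["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"], "FCZ"),
        (["T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"], "CZ"),
        (["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"], "CPZ"),
        (["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"], "PZ"),
        (["PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8"], "POZ"),
    ]
    for names, mid in chains:
        pts = _chain(pos[names[0]], pos[mid], pos[names[-1]], len(names))
        for name, p in zip(names, pts):
            pos[name] = p

    # Anterior-frontal interior sites between AF7/AF8 and the midline point
    # at 54 degrees (AFz position, itself not part of this cap).
    afz = _sph(54.0, 0.0)
    pos["AF3"] = _slerp(pos["AF7"], afz, 0.5)
    pos["AF4"] = _slerp(afz, pos["AF8"], 0.5)

    # Cerebellar sites below the occipital ring.
    pos["CB1"] = _sph(100.0, -162.0)
    pos["CB2"] = _sph(100.0, 162.0)

    order = [
        "FP1", "FPZ", "FP2", "AF7", "AF3", "AF4", "AF8",
        "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
        "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
        "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
        "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
        "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
        "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
        "CB1", "O1", "OZ", "O2", "CB2",
    ]
    coords = np.array([pos[name] / np.linalg.norm(pos[name]) for name in order])
    return Montage(tuple(order), coords)


def project_montage(montage: Montage) -> np.ndarray:
    """Azimuthal equidistant projection about the vertex.

    Each electrode maps to a 2-D point whose distance from the origin equals
    its great-circle (polar) angle from the vertex, so the vertex lands at
    the exact center and radial distances are preserved. Returns an
    (n_channels, 2) array of (x, y) with +x = right, +y = anterior.
    """
    xyz = montage.coords3d
    polar = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    horiz = np.hypot(xyz[:, 0], xyz[:, 1])
    out = np.zeros((len(xyz), 2))
    nz = horiz > 1e-12
    out[nz, 0] = polar[nz] * xyz[nz, 0] / horiz[nz]
    out[nz, 1] = polar[nz] * xyz[nz, 1] / horiz[nz]
    return out
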