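"""Circular imaging domain and the 16-electrode measurement protocol.

The imaging plane is modelled as a 2D disc triangulated into linear (P1)
finite elements.  Sixteen electrodes sit on the boundary at equal angular
spacing; current is driven through diametrically opposite electrode pairs
and differential voltages are measured on adjacent pairs.  Measurement
pairs that contain a driving electrode are discarded (their voltages are
dominated by unmeasurable contact impedance), leaving 12 valid channels
per excitation and 192 channels in total.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

N_ELECTRODES = 16
MIN_ELEMENTS = 64


@dataclass(frozen=True)
class Mesh:
    """Conforming triangulation of a disc with 16 boundary electrodes.

    Attributes
    ----------
    nodes : (N, 2) float array of node coordinates (metres).
    triangles : (T, 3) int array, counterclockwise connectivity.
    areas : (T,) float array of element areas (m^2).
    electrode_nodes : (16,) int array; ``electrode_nodes[k]`` is the
        boundary node for electrode ``k`` (0-based, counterclockwise
        from angle 0).
    radius : disc radius (metres).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    areas: np.ndarray
    electrode_nodes: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be an (N, 2) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be a (T, 3) array")
        if np.any(self.areas <= 0):
            raise ValueError("all element areas must be positive")
        if len(self.electrode_nodes) != N_ELECTRODES:
            raise ValueError(f"expected {N_ELECTRODES} electrodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def centroids(self) -> np.ndarray:
        """(T, 2) element centroids."""
        return self.nodes[self.triangles].mean(axis=1)

    def element_diameter(self) -> float:
        """Longest element edge in the mesh (localization tolerance unit)."""
        pts = self.nodes[self.triangles]
        edges = np.stack(
            [
                pts[:, 0] - pts[:, 1],
                pts[:, 1] - pts[:, 2],
                pts[:, 2] - pts[:, 0],
            ],
            axis=1,
        )
        return float(np.linalg.norm(edges, axis=2).max())

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        return h.hexdigest()[:16]


def _signed_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = nodes[triangles]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def build_circular_mesh(radius: float, target_element_count: int) -> Mesh:
    """Triangulate a disc of the given radius with ~``target_element_count``
    elements and 16 equally spaced boundary electrodes.

    Nodes are laid out on concentric rings (alternate rings angularly
    offset for well-shaped triangles) and triangulated with Delaunay.
    The outer ring has a multiple of 16 nodes with one node exactly at
    angle 0, so the 16 electrode nodes sit exactly at angles 2*pi*k/16,
    counterclockwise, electrode 0 at angle 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if target_element_count < MIN_ELEMENTS:
        raise ValueError(f"target_element_count must be >= {MIN_ELEMENTS}")

    n_rings = max(2, int(round(np.sqrt(target_element_count / (2 * np.pi)))))
    # outer ring: multiple of 16 (exact electrode spacing) and >= 32 so the
    # inscribed polygon area stays within 2% of the disc area
    n_outer = max(2 * N_ELECTRODES,
                  N_ELECTRODES * int(round(2 * np.pi * n_rings / N_ELECTRODES)))

    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        if k == n_rings:
            n_k, offset = n_outer, 0.0
        else:
            n_k = max(6, int(round(n_outer * k / n_rings)))
            offset = 0.5 * (k % 2)
        theta = 2 * np.pi * (np.arange(n_k) + offset) / n_k
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    triangles = tri.simplices.copy()
    sa = _signed_areas(nodes, triangles)
    flip = sa < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    areas = np.abs(sa)

    # outer-ring nodes are the last n_outer; electrode k nearest to 2*pi*k/16
    boundary = np.arange(len(nodes) - n_outer, len(nodes))
    angles = np.arctan2(nodes[boundary, 1], nodes[boundary, 0]) % (2 * np.pi)
    targets = 2 * np.pi * np.arange(N_ELECTRODES) / N_ELECTRODES
    diff = np.abs(angles[None, :] - targets[:, None])
    diff = np.minimum(diff, 2 * np.pi - diff)
    electrode_nodes = boundary[np.argmin(diff, axis=1)]
    if len(np.unique(electrode_nodes)) != N_ELECTRODES:
        raise RuntimeError("electrode assignment produced duplicate nodes")

    return Mesh(
        nodes=nodes,
        triangles=triangles,
        areas=areas,
        electrode_nodes=electrode_nodes,
        radius=float(radius),
    )


@dataclass(frozen=True)
class Protocol:
    """Opposite-excitation / adjacent-measurement channel bookkeeping.

    ``channels`` lists valid (excitation index, measurement-pair index)
    combinations in canonical order: excitation-major, measurement-pair
    minor.  This ordering is the column order of every frame series.
    """

    excitations: tuple  # 16 pairs (k, k+8 mod 16)
    measurements: tuple  # 16 adjacent pairs (j, j+1 mod 16)
    valid_mask: np.ndarray  # (16, 16) bool [excitation, measurement pair]
    channels: tuple = field(default=())  # canonical (i, j) list

    @property
    def n_electrodes(self) -> int:
        return N_ELECTRODES

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def flatten(self, excitation: int, pair: int) -> int:
        """Canonical channel index of a valid (excitation, pair) combination."""
        try:
            return self.channels.index((excitation, pair))
        except ValueError:
            raise KeyError(f"({excitation}, {pair}) is not a valid channel") from None

    def unflatten(self, channel: int) -> tuple:
        return self.channels[channel]

    def content_hash(self) -> str:
        h = hashlib.sha256(repr((self.excitations, self.measurements,
                                 self.channels)).encode())
        return h.hexdigest()[:16]


def make_protocol() -> Protocol:
    """Build the 16-electrode opposite-drive / adjacent-measurement protocol.

    A measurement pair is valid for an excitation iff it contains neither
    driving electrode, giving exactly 12 valid pairs per excitation and
    192 channels in total.
    """
    excitations = tuple((k, (k + 8) % N_ELECTRODES) for k in range(N_ELECTRODES))
    measurements = tuple((j, (j + 1) % N_ELECTRODES) for j in range(N_ELECTRODES))
    valid = np.ones((N_ELECTRODES, N_ELECTRODES), dtype=bool)
    for i, (a, b) in enumerate(excitations):
        for j, (m1, m2) in enumerate(measurements):
            if {a, b} & {m1, m2}:
                valid[i, j] = False
    channels = tuple(
        (i, j)
        for i in range(N_ELECTRODES)
        for j in range(N_ELECTRODES)
        if valid[i, j]
    )
    return Protocol(
        excitations=excitations,
        measurements=measurements,
        valid_mask=valid,
        channels=channels,
    )
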