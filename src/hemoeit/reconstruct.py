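"""Damped-least-squares difference imaging.

The sensitivity (Jacobian) matrix S of the boundary voltages with respect
to per-element conductivity is computed on a homogeneous circular model
with the adjoint method; the reconstruction matrix

    B = [S^T S + lambda * diag(S^T S)]^(-1) S^T,   lambda = 0.1

maps normalized voltage differences dv = (v_t - v_ref) / v_ref to an
impedance-change image.  Images follow the convention that a conductive
anomaly (blood) produces *negative* values (a regional impedance
reduction); B * dv estimates the conductivity change, so the image is its
negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .forward import ForwardModel, FrameSeries
from .mesh import Mesh, Protocol

__all__ = [
    "SensitivityMatrix",
    "ReconstructionMatrix",
    "EitImage",
    "ImageSeries",
    "DegenerateReferenceError",
    "DegenerateSensitivityError",
    "compute_sensitivity",
    "build_b",
    "normalized_difference",
    "reconstruct_series",
]

DEFAULT_LAMBDA = 0.1
REFERENCE_FLOOR_REL = 1e-6


class DegenerateReferenceError(ValueError):
    """Reference voltages too small for a stable normalized difference."""


class DegenerateSensitivityError(ValueError):
    """diag(S^T S) has a zero entry; an element is invisible to all channels."""


@dataclass
class SensitivityMatrix:
    """Linearized sensitivity dv/dsigma on a homogeneous background.

    ``values[c, e]`` is the derivative of channel ``c``'s voltage with
    respect to element ``e``'s conductivity, at the stated background and
    drive current.  ``reference_voltages`` are the homogeneous-model
    channel voltages used to row-normalize S for reconstruction in the
    same (dimensionless) units as the normalized voltage differences.
    """

    values: np.ndarray  # (n_channels, n_elements), volts per (S/m)
    reference_voltages: np.ndarray  # (n_channels,), volts
    background_conductivity: float
    current: float
    mesh_hash: str = ""
    sign_convention: str = "dv/dsigma"

    def normalized(self) -> np.ndarray:
        """Row-normalized sensitivity: values / reference voltage per channel."""
        return self.values / self.reference_voltages[:, None]


def compute_sensitivity(
    mesh: Mesh,
    protocol: Protocol,
    background_conductivity: float = 0.3,
    current: float = 1e-3,
) -> SensitivityMatrix:
    """Adjoint-method sensitivity matrix on the homogeneous disc.

    For channel c = (drive pair d, measurement pair m), with u the drive
    potential at the actual current and w the potential of a unit current
    driven through the measurement pair,

        dv_c / dsigma_e = - area_e * grad(u_d) . grad(w_m)  on element e,

    which is the exact derivative of the discrete FEM system.
    """
    if background_conductivity <= 0:
        raise ValueError("background conductivity must be positive")
    model = ForwardModel(mesh, protocol, current)
    sigma = np.full(mesh.n_elements, float(background_conductivity))
    enodes = mesh.electrode_nodes
    drive_inj = [(enodes[a], enodes[b]) for a, b in protocol.excitations]
    meas_inj = [(enodes[a], enodes[b]) for a, b in protocol.measurements]
    u = model.solve_potentials(sigma, drive_inj)  # (N, 16) at drive current
    w = model.solve_potentials(sigma, meas_inj, current=1.0)  # unit adjoint

    # per-element gradients of each solution: (T, 2, n_solutions)
    def element_grads(potentials: np.ndarray) -> np.ndarray:
        nodal = potentials[mesh.triangles]  # (T, 3, n)
        return np.einsum("tid,tin->tdn", model.grads, nodal)

    gu = element_grads(u)
    gw = element_grads(w)
    idx = np.array(protocol.channels)
    dot = np.einsum("tdc,tdc->tc", gu[:, :, idx[:, 0]], gw[:, :, idx[:, 1]])
    s = -(mesh.areas[:, None] * dot).T  # (n_channels, n_elements)
    v_hom = model.boundary_voltages(sigma)
    return SensitivityMatrix(
        values=s,
        reference_voltages=v_hom,
        background_conductivity=float(background_conductivity),
        current=float(current),
        mesh_hash=mesh.content_hash(),
    )


@dataclass
class ReconstructionMatrix:
    b: np.ndarray  # (n_elements, n_channels)
    lam: float
    regularizer: str = "diag(StS)"
    mesh_hash: str = ""


def build_b(s, lam: float = DEFAULT_LAMBDA) -> ReconstructionMatrix:
    """Assemble the damped-least-squares reconstruction matrix.

    ``s`` may be a plain (channels x elements) array or a
    :class:`SensitivityMatrix` (in which case its row-normalized values
    are used, matching the normalized differences the matrix is applied
    to).
    """
    if lam <= 0:
        raise ValueError("regularization parameter must be positive")
    mesh_hash = ""
    if isinstance(s, SensitivityMatrix):
        mesh_hash = s.mesh_hash
        s = s.normalized()
    s = np.asarray(s, dtype=float)
    sts = s.T @ s
    d = np.diag(sts).copy()
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0])
        raise DegenerateSensitivityError(
            f"diag(S^T S) is zero for element {bad}; it is invisible to all channels"
        )
    a = sts + lam * np.diag(d)
    b = linalg.solve(a, s.T, assume_a="pos")
    return ReconstructionMatrix(b=b, lam=float(lam), mesh_hash=mesh_hash)


def normalized_difference(
    v_t: np.ndarray, v_ref: np.ndarray, floor_rel: float = REFERENCE_FLOOR_REL
) -> np.ndarray:
    """Elementwise (v_t - v_ref) / v_ref; v_t may be one frame or a stack."""
    v_t = np.asarray(v_t, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    if v_t.shape[-1] != v_ref.shape[0]:
        raise ValueError("v_t and v_ref channel counts differ")
    floor = floor_rel * np.median(np.abs(v_ref))
    bad = np.flatnonzero(np.abs(v_ref) < floor)
    if bad.size or floor == 0:
        raise DegenerateReferenceError(
            f"reference voltage below floor on channels {bad.tolist()}"
        )
    return (v_t - v_ref) / v_ref


@dataclass
class EitImage:
    """Per-element impedance change (dimensionless normalized units)."""

    values: np.ndarray  # (n_elements,); negative = impedance reduction
    time: float
    ref_time: float | None = None


@dataclass
class ImageSeries:
    times: np.ndarray
    values: np.ndarray  # (n_frames, n_elements)
    ref_time: float | None = None
    sign_convention: str = "conductive anomaly -> negative"

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> EitImage:
        return EitImage(self.values[i], float(self.times[i]), self.ref_time)


def reconstruct_series(
    recon: ReconstructionMatrix, frames, ref: np.ndarray,
    times=None,
) -> ImageSeries:
    """Difference images for each frame against the reference voltages.

    ``frames`` may be a FrameSeries (typically the injection component) or
    a (n_frames x channels) array with ``times`` supplied.  The image is
    -B * dv so that a conductivity increase (blood pool) appears as a
    negative impedance change.
    """
    if isinstance(frames, FrameSeries):
        values, times = frames.voltages, frames.times
    else:
        values = np.asarray(frames, dtype=float)
        if times is None:
            times = np.arange(len(values), dtype=float)
    if values.shape[1] != recon.b.shape[1]:
        raise ValueError(
            f"frame channel count {values.shape[1]} does not match "
            f"reconstruction matrix ({recon.b.shape[1]} channels)"
        )
    dv = normalized_difference(values, ref)
    images = -(dv @ recon.b.T)
    return ImageSeries(times=np.asarray(times, dtype=float), values=images)
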