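"""Canonical Met-centered reference frame via a two-quaternion construction.

Every cluster is reduced to six 3-tuples: the Met CG-SD-CE scaffold and the
aromatic centroids.  The scaffold is mapped to a canonical pose in three
steps:

1. translate so SD sits at the origin;
2. rotate by quaternion Q1 -- about the axis ``cross(SD->CE, x_hat)`` through
   the angle ``alpha`` whose cosine is the direction cosine of SD->CE with
   the x-axis -- so the SD-CE bond lies along +x;
3. rotate by quaternion Q2 about the x-axis through ``-beta`` so CG falls in
   the x,y-plane with y >= 0 (the CH2 arm points along +y).

Aromatic centroids are carried into the frame by the composed rotation
Q2*Q1 applied after the translation.  Quaternions are unit, scalar-first,
right-handed, and act as active rotations ``v' = q v q*``.

Because both steps are proper rotations the mapping is a rigid motion:
local coordinates are invariant under any proper rigid motion of the input
structure, while a mirror image flips exactly the z-coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bridge_graph import BridgeCluster
from .structure_io import MetSite, ResidueRef

_X = np.array([1.0, 0.0, 0.0])

# ---------------------------------------------------------------------------
# minimal scalar-first quaternion algebra


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion (w, x, y, z) rotating by `angle` about `axis` (right-hand rule)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    half = 0.5 * angle
    return np.concatenate(([np.cos(half)], np.sin(half) * axis / norm))


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1*q2 (apply q2 first, then q1)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Active rotation of vector(s) v by unit quaternion q."""
    return np.asarray(v) @ quat_to_matrix(q).T


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------


@dataclass
class FrameTransform:
    """The rigid motion taking a Met scaffold to its canonical pose."""

    translation: np.ndarray  # -SD
    alpha_rad: float         # angle between SD->CE and x_hat
    q1: np.ndarray           # aligns SD->CE with +x
    beta_rad: float          # rotation about x bringing CG into the x,y-plane
    q2: np.ndarray
    composed: np.ndarray     # q2 * q1

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = quat_rotate(self.composed, pts + self.translation)
        return out if np.asarray(points).ndim > 1 else out[0]


@dataclass
class LocalFramePoint:
    """An aromatic centroid expressed in the canonical Met frame."""

    residue_type: str
    position: np.ndarray
    structure_id: str
    met_ref: ResidueRef
    aromatic_ref: ResidueRef


def met_frame_transform(met: MetSite) -> FrameTransform:
    """Build the canonical-frame transform for one Met scaffold.

    Raises a degenerate-geometry error (naming the residue) when CG, SD, CE
    are collinear to within 1 degree, where the frame is unstable.
    """
    u = met.ce - met.sd
    g = met.cg - met.sd
    nu, ng = np.linalg.norm(u), np.linalg.norm(g)
    if nu == 0 or ng == 0:
        raise ValueError(f"degenerate Met geometry at {met.ref}: zero bond length")
    wedge = np.degrees(np.arccos(np.clip(np.dot(u / nu, g / ng), -1.0, 1.0)))
    if wedge < 1.0 or wedge > 179.0:
        raise ValueError(
            f"degenerate Met geometry at {met.ref}: CG-SD-CE near collinear "
            f"({wedge:.2f} deg)")

    u_hat = u / nu
    cos_alpha = float(np.clip(np.dot(u_hat, _X), -1.0, 1.0))
    alpha = float(np.arccos(cos_alpha))
    axis = np.cross(u_hat, _X)
    if np.linalg.norm(axis) < 1e-12:
        # SD->CE already on the x-axis: identity, or 180 deg about z if antiparallel
        q1 = (np.array([1.0, 0.0, 0.0, 0.0]) if cos_alpha > 0
              else quat_from_axis_angle(np.array([0.0, 0.0, 1.0]), np.pi))
    else:
        q1 = quat_from_axis_angle(axis, alpha)

    g1 = quat_rotate(q1, g)
    beta = float(np.arctan2(g1[2], g1[1]))
    q2 = quat_from_axis_angle(_X, -beta)
    return FrameTransform(translation=-met.sd, alpha_rad=alpha, q1=q1,
                          beta_rad=beta, q2=q2, composed=quat_multiply(q2, q1))


def apply_frame(transform: FrameTransform, points: np.ndarray) -> np.ndarray:
    """Map points (n, 3) into the canonical Met frame."""
    return transform.apply(points)


def cluster_to_local_frame(cluster: BridgeCluster,
                           structure_id: str = "") -> list[LocalFramePoint]:
    """Aromatic centroids of one cluster in the Met frame, one point per partner."""
    try:
        t = met_frame_transform(cluster.met)
    except ValueError as exc:
        raise ValueError(f"{structure_id}: {exc}") from exc
    points = []
    for aro, _contact in cluster.partners:
        points.append(LocalFramePoint(
            residue_type=aro.ref.residue_name,
            position=t.apply(aro.centroid),
            structure_id=structure_id,
            met_ref=cluster.met.ref,
            aromatic_ref=aro.ref))
    return points


def local_points_to_rows(points: list[LocalFramePoint]) -> list[dict]:
    """Flatten local-frame points for CSV export (scatter-plot input)."""
    return [{
        "residue_type": p.residue_type,
        "x": p.position[0], "y": p.position[1], "z": p.position[2],
        "structure_id": p.structure_id,
        "met_chain": p.met_ref.chain_id,
        "met_number": p.met_ref.residue_number,
        "aromatic_chain": p.aromatic_ref.chain_id,
        "aromatic_number": p.aromatic_ref.residue_number,
    } for p in points]
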