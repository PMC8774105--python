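"""Met-aromatic contact detection.

A contact exists when the configured distance between a methionine thioether
and an aromatic ring is within the cutoff (inclusive; default 6.0 A).  Two
distance conventions are supported and both are always reported so the choice
is auditable:

``sd_to_nearest_midpoint``
    minimum distance from the Met SD to any ring-bond midpoint (the
    convention of the original Met-aromatic screening algorithm);
``sd_to_centroid``
    distance from SD to the unweighted ring centroid.

The angular position of the ring relative to the two sulfur lone-pair
direction estimates is reported on every contact but, by default, never
filtered on (angle cutoff 360 degrees, i.e. disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import AromaticSite, MetSite, ResidueRef

DISTANCE_METRICS = ("sd_to_nearest_midpoint", "sd_to_centroid")


@dataclass
class DetectionConfig:
    """Parameters of the contact criterion."""

    cutoff_distance: float = 6.0
    distance_metric: str = "sd_to_nearest_midpoint"
    angle_cutoff_deg: float = 360.0
    interchain: bool = True
    include_mse: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_distance <= 0:
            raise ValueError("cutoff_distance must be positive")
        if not 0 < self.angle_cutoff_deg <= 360:
            raise ValueError("angle_cutoff_deg must be in (0, 360]")
        if self.distance_metric not in DISTANCE_METRICS:
            raise ValueError(f"distance_metric must be one of {DISTANCE_METRICS}")


@dataclass
class PairContact:
    """One Met-aromatic edge of the residue interaction graph."""

    met: ResidueRef
    aromatic: ResidueRef
    distance: float            # under the configured metric
    centroid_distance: float   # SD -> centroid, always reported
    midpoint_distance: float   # SD -> nearest ring-bond midpoint, always reported
    met_theta_deg: float       # angle(SD->ring reference, lone pair 1)
    met_phi_deg: float         # angle(SD->ring reference, lone pair 2)
    met_site: MetSite = field(repr=False, default=None)
    aromatic_site: AromaticSite = field(repr=False, default=None)


def lone_pair_directions(met: MetSite) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors estimating the two sulfur lone-pair directions.

    Constructed from the CG-SD-CE wedge: both lie opposite the wedge
    (obtuse to SD->CG and SD->CE), displaced symmetrically out of the
    CG-SD-CE plane, and swap under exchanging CG and CE.
    """
    a = met.cg - met.sd
    b = met.ce - met.sd
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError(f"degenerate Met geometry at {met.ref}: zero bond length")
    a, b = a / na, b / nb
    normal = np.cross(a, b)
    nn = np.linalg.norm(normal)
    if nn < 1e-8:
        raise ValueError(f"degenerate Met geometry at {met.ref}: CG-SD-CE collinear")
    normal /= nn
    anti = -(a + b)
    anti /= np.linalg.norm(anti)
    lp1 = anti + normal
    lp2 = anti - normal
    return lp1 / np.linalg.norm(lp1), lp2 / np.linalg.norm(lp2)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def met_aromatic_pairs(mets: list[MetSite], aromatics: list[AromaticSite],
                       config: DetectionConfig | None = None) -> list[PairContact]:
    """All (Met, aromatic) pairs within the configured cutoff (inclusive).

    A Met paired with k aromatics yields k contacts.  With ``interchain``
    false, pairs spanning different chains are excluded.  If an angle cutoff
    below 360 is set, a contact additionally requires
    ``min(met_theta, met_phi) <= angle_cutoff_deg``.
    """
    config = config or DetectionConfig()
    contacts: list[PairContact] = []
    for met in mets:
        try:
            lp1, lp2 = lone_pair_directions(met)
        except ValueError:
            lp1 = lp2 = None
        for aro in aromatics:
            if not config.interchain and met.ref.chain_id != aro.ref.chain_id:
                continue
            d_cen = float(np.linalg.norm(aro.centroid - met.sd))
            d_mid = float(np.linalg.norm(aro.midpoints - met.sd, axis=1).min())
            d = d_mid if config.distance_metric == "sd_to_nearest_midpoint" else d_cen
            if d > config.cutoff_distance:
                continue
            if config.distance_metric == "sd_to_nearest_midpoint":
                i = int(np.linalg.norm(aro.midpoints - met.sd, axis=1).argmin())
                ref_vec = aro.midpoints[i] - met.sd
            else:
                ref_vec = aro.centroid - met.sd
            if lp1 is None:
                theta = phi = float("nan")
            else:
                theta = _angle_deg(ref_vec, lp1)
                phi = _angle_deg(ref_vec, lp2)
            if config.angle_cutoff_deg < 360 and not (
                    min(theta, phi) <= config.angle_cutoff_deg):
                continue
            contacts.append(PairContact(
                met=met.ref, aromatic=aro.ref, distance=d,
                centroid_distance=d_cen, midpoint_distance=d_mid,
                met_theta_deg=theta, met_phi_deg=phi,
                met_site=met, aromatic_site=aro))
    return contacts


def contacts_to_rows(structure_id: str, contacts: list[PairContact]) -> list[dict]:
    """Flatten contacts for CSV export."""
    return [{
        "structure_id": structure_id,
        "met_chain": c.met.chain_id,
        "met_number": c.met.residue_number,
        "aromatic_chain": c.aromatic.chain_id,
        "aromatic_number": c.aromatic.residue_number,
        "aromatic_resname": c.aromatic.residue_name,
        "distance": c.distance,
        "centroid_distance": c.centroid_distance,
        "midpoint_distance": c.midpoint_distance,
        "met_theta": c.met_theta_deg,
        "met_phi": c.met_phi_deg,
    } for c in contacts]
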