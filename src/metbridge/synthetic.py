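"""Synthetic PDB fixtures with geometrically planted Met-aromatic clusters.

Structures are assembled in the canonical Met frame -- SD at the origin,
CE along +x, CG in the x,y-plane -- where aromatic centroids are planted at
exact spherical coordinates (r, theta, phi); theta is the polar angle from
+z, phi the azimuth from +x.  A seeded random rigid motion is then applied
to every atom so no fixture accidentally sits in the canonical frame, and
the file is written in fixed-column PDB format.  The planted local
coordinates, distances and compositions are returned as a ground-truth
table against which detection and frame recovery can be scored.

Geometry conventions (fixture conventions, configurable, not claims about
real proteins): Met |CG-SD| = 1.81 A, |SD-CE| = 1.79 A, wedge 100 degrees;
Phe/Tyr rings are regular hexagons of circumradius 1.39 A; Trp is an
idealized planar fused pentagon+hexagon of bond length 1.40 A.  Aromatic
residues carry ring + CB atoms only and Met carries CB-CG-SD-CE (the
minimum the pipeline needs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AromaticSite, MetSite, ResidueRef, RING_ATOMS, RING_BONDS

MET_CG_SD = 1.81
MET_SD_CE = 1.79
MET_WEDGE_DEG = 100.0
RING_RADIUS = 1.39
TRP_BOND = 1.40

_ELEMENTS = {"N": "N", "C": "C", "O": "O", "S": "S", "SE": "SE"}


# ---------------------------------------------------------------------------
# canonical geometry templates


def canonical_met_coords() -> dict[str, np.ndarray]:
    """CB-CG-SD-CE of a Met in its canonical frame."""
    w = np.radians(MET_WEDGE_DEG)
    sd = np.zeros(3)
    ce = np.array([MET_SD_CE, 0.0, 0.0])
    cg = MET_CG_SD * np.array([np.cos(w), np.sin(w), 0.0])
    cb = cg + 1.53 * _unit(np.array([-0.3, 0.8, 0.9]))
    return {"CB": cb, "CG": cg, "SD": sd, "CE": ce}


def canonical_met_site(ref: ResidueRef | None = None) -> MetSite:
    ref = ref or ResidueRef("A", 1, "", "MET")
    c = canonical_met_coords()
    return MetSite(ref=ref, cg=c["CG"], sd=c["SD"], ce=c["CE"])


def ring_template(residue_type: str) -> dict[str, np.ndarray]:
    """Planar ring-atom template centered on its (9-atom for Trp) centroid."""
    if residue_type in ("PHE", "TYR"):
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")  # hexagon order
        coords = {
            n: RING_RADIUS * np.array([np.cos(a), np.sin(a), 0.0])
            for n, a in zip(names, np.radians(np.arange(0, 360, 60)))
        }
    elif residue_type == "TRP":
        coords = _indole_template()
    else:
        raise ValueError(f"no ring template for {residue_type}")
    centroid = np.mean([coords[n] for n in RING_ATOMS[residue_type]], axis=0)
    return {n: p - centroid for n, p in coords.items()}


def _indole_template() -> dict[str, np.ndarray]:
    """Idealized planar indole: pentagon and hexagon fused on CD2-CE2."""
    b = TRP_BOND
    hex_center = np.array([b * np.cos(np.radians(30)), 0.0])
    hex_names = {210: "CD2", 270: "CE3", 330: "CZ3", 30: "CH2", 90: "CZ2", 150: "CE2"}
    coords = {n: hex_center + b * np.array([np.cos(np.radians(a)),
                                            np.sin(np.radians(a))])
              for a, n in hex_names.items()}
    r5 = (b / 2) / np.sin(np.radians(36))
    pent_center = np.array([-(b / 2) / np.tan(np.radians(36)), 0.0])
    for a, n in ((108, "NE1"), (180, "CD1"), (252, "CG")):
        coords[n] = pent_center + r5 * np.array([np.cos(np.radians(a)),
                                                 np.sin(np.radians(a))])
    return {n: np.array([p[0], p[1], 0.0]) for n, p in coords.items()}


def spherical_to_cartesian(r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = np.radians(theta_deg), np.radians(phi_deg)
    return r * np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def make_aromatic_residue(residue_type: str, centroid: np.ndarray,
                          normal: np.ndarray | None = None,
                          spin_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Ring + CB atoms with the ring centroid at `centroid` and plane
    perpendicular to `normal` (default +z), spun by `spin_deg` about it."""
    template = ring_template(residue_type)
    rot = _orientation_matrix(normal, spin_deg)
    atoms = {n: centroid + rot @ p for n, p in template.items()}
    cg = atoms["CG"]
    away = cg - centroid
    away = _unit(away) if np.linalg.norm(away) > 1e-9 else np.array([1.0, 0, 0])
    atoms["CB"] = cg + 1.50 * away
    return atoms


def make_aromatic_site(residue_type: str, centroid: np.ndarray,
                       ref: ResidueRef | None = None,
                       normal: np.ndarray | None = None,
                       spin_deg: float = 0.0) -> AromaticSite:
    """In-memory AromaticSite at exact coordinates (no file round-trip)."""
    ref = ref or ResidueRef("A", 2, "", residue_type)
    atoms = make_aromatic_residue(residue_type, centroid, normal, spin_deg)
    ring = {n: atoms[n] for n in RING_ATOMS[residue_type]}
    cen = np.mean(list(ring.values()), axis=0)
    mids = np.vstack([(ring[a] + ring[b]) / 2 for a, b in RING_BONDS[residue_type]])
    return AromaticSite(ref=ref, ring_atoms=ring, centroid=cen, midpoints=mids)


def _orientation_matrix(normal: np.ndarray | None, spin_deg: float) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    spin = np.radians(spin_deg)
    cs, sn = np.cos(spin), np.sin(spin)
    r_spin = np.array([[cs, -sn, 0], [sn, cs, 0], [0, 0, 1.0]])
    if normal is None:
        return r_spin
    n = _unit(np.asarray(normal, dtype=float))
    axis = np.cross(z, n)
    if np.linalg.norm(axis) < 1e-12:
        r_tilt = np.eye(3) if n[2] > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        r_tilt = _axis_angle_matrix(_unit(axis),
                                    np.arccos(np.clip(n[2], -1.0, 1.0)))
    return r_tilt @ r_spin


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# plant specification and file assembly


@dataclass
class PlantSpec:
    """Recipe for one synthetic structure.

    ``partners`` are (residue_type, r, theta_deg, phi_deg) tuples giving the
    ring-centroid spherical coordinates in the canonical Met frame; ring
    orientations are drawn from the seed.  ``decoys`` non-interacting
    residues (mixed ALA and aromatic types) are placed with ring centroids
    at least ``decoy_exclusion`` from the Met SD and the planted centroids.
    """

    structure_id: str = "SYNTH"
    partners: list[tuple[str, float, float, float]] = field(default_factory=list)
    decoys: int = 4
    decoy_exclusion: float = 9.0
    b_factor_plan: dict[str, float] | float = 20.0
    ec_label: str | None = None
    seed: int = 0
    apply_global_motion: bool = True

    def __post_init__(self) -> None:
        for p in self.partners:
            if p[1] <= 0:
                raise ValueError("partner radius must be positive")


@dataclass
class TruthRow:
    """Ground truth for one generated structure."""

    structure_id: str
    has_cluster: bool          # >= 3 planted partners
    n_partners: int
    met_ref: ResidueRef
    partner_refs: list[ResidueRef]
    partner_types: list[str]
    local_coords: np.ndarray   # (k, 3) planted centroids, canonical Met frame
    sd_centroid_distances: list[float]
    composition: str           # e.g. "PHE-TRP-TYR", sorted; "" if <3 partners
    ec_label: str | None

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "has_cluster": self.has_cluster,
            "n_partners": self.n_partners,
            "met_chain": self.met_ref.chain_id,
            "met_number": self.met_ref.residue_number,
            "partner_numbers": ";".join(str(r.residue_number)
                                        for r in self.partner_refs),
            "partner_types": ";".join(self.partner_types),
            "local_coords": ";".join(
                f"{x:.6f},{y:.6f},{z:.6f}" for x, y, z in self.local_coords),
            "sd_centroid_distances": ";".join(
                f"{d:.6f}" for d in self.sd_centroid_distances),
            "composition": self.composition,
            "ec_label": self.ec_label or "",
        }


def build_structure(spec: PlantSpec) -> tuple[str, TruthRow]:
    """Assemble one fixture; returns (PDB file content, truth-table row)."""
    rng = np.random.default_rng(spec.seed)
    residues: list[tuple[str, int, dict[str, np.ndarray]]] = []

    met_num = 1
    residues.append(("MET", met_num, canonical_met_coords()))

    partner_refs, partner_types, local_coords, dists = [], [], [], []
    centroids: list[np.ndarray] = []
    num = 2
    for rtype, r, theta, phi in spec.partners:
        centroid = spherical_to_cartesian(r, theta, phi)
        normal = _unit(rng.normal(size=3))
        spin = rng.uniform(0, 360)
        residues.append((rtype, num, make_aromatic_residue(rtype, centroid,
                                                           normal, spin)))
        partner_refs.append(ResidueRef("A", num, "", rtype))
        partner_types.append(rtype)
        local_coords.append(centroid)
        dists.append(float(np.linalg.norm(centroid)))
        centroids.append(centroid)
        num += 1

    decoy_types = ["ALA", "PHE", "ALA", "TYR", "ALA", "TRP"]
    for i in range(spec.decoys):
        rtype = decoy_types[i % len(decoy_types)]
        pos = _place_decoy(rng, centroids, spec.decoy_exclusion)
        if rtype == "ALA":
            atoms = _ala_coords(pos)
        else:
            atoms = make_aromatic_residue(rtype, pos, _unit(rng.normal(size=3)),
                                          rng.uniform(0, 360))
        residues.append((rtype, num, atoms))
        num += 1

    if spec.apply_global_motion:
        rot = random_rotation(rng)
        trans = rng.uniform(-20, 20, size=3)
        residues = [(rn, ri, {n: rot @ p + trans for n, p in atoms.items()})
                    for rn, ri, atoms in residues]

    residues = _realize_on_grid(residues, len(spec.partners), dists)

    content = _render_pdb(spec.structure_id, residues, spec.b_factor_plan,
                          spec.ec_label)
    n_partners = len(spec.partners)
    row = TruthRow(
        structure_id=spec.structure_id,
        has_cluster=n_partners >= 3,
        n_partners=n_partners,
        met_ref=ResidueRef("A", met_num, "", "MET"),
        partner_refs=partner_refs,
        partner_types=partner_types,
        local_coords=(np.vstack(local_coords) if local_coords
                      else np.empty((0, 3))),
        sd_centroid_distances=dists,
        composition=("-".join(sorted(partner_types)) if n_partners >= 3 else ""),
        ec_label=spec.ec_label)
    return content, row


def _realize_on_grid(residues, n_partners: int, targets: list[float]):
    """Snap coordinates to the 1e-3 A PDB grid, then nudge each planted
    partner so its written SD-centroid distance sits in (r - 5e-4, r].

    Plain rounding can push a planted distance up to ~9e-4 A either way; a
    distance planted exactly at the cutoff must never round *outside* it,
    so the rings are converged onto the grid from just inside the target.
    """
    from .structure_io import RING_ATOMS

    snapped = [(rn, ri, {n: np.round(p, 3) for n, p in atoms.items()})
               for rn, ri, atoms in residues]
    sd = snapped[0][2]["SD"]
    for k in range(n_partners):
        rn, ri, atoms = residues[1 + k]  # continuous coordinates
        target = targets[k]
        ring_names = RING_ATOMS[rn]
        cen0 = np.mean([atoms[n] for n in ring_names], axis=0)
        u = (cen0 - sd) / np.linalg.norm(cen0 - sd)
        offset, best, best_score = 0.0, None, np.inf
        for _ in range(200):
            trial = {n: np.round(p + offset * u, 3) for n, p in atoms.items()}
            cen = np.mean([trial[n] for n in ring_names], axis=0)
            err = float(np.linalg.norm(cen - sd)) - target
            score = abs(err + 2.5e-4)
            if score < best_score:
                best, best_score = trial, score
            if -5e-4 < err <= 0:
                best = trial
                break
            offset -= err + 2.5e-4
        snapped[1 + k] = (rn, ri, best)
    return snapped


def _place_decoy(rng: np.random.Generator, centroids: list[np.ndarray],
                 exclusion: float, max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        pos = rng.uniform(-1, 1, size=3)
        norm = np.linalg.norm(pos)
        if norm < 1e-6:
            continue
        pos = pos / norm * rng.uniform(exclusion, exclusion + 6.0)
        if all(np.linalg.norm(pos - c) >= exclusion for c in centroids):
            return pos
    raise RuntimeError("could not place decoy respecting the exclusion radius")


def _ala_coords(ca: np.ndarray) -> dict[str, np.ndarray]:
    return {"N": ca + np.array([-1.46, 0, 0]), "CA": ca,
            "CB": ca + np.array([0.6, 1.2, 0.7]),
            "C": ca + np.array([1.52, 0, 0]),
            "O": ca + np.array([2.15, 1.05, 0])}


# ---------------------------------------------------------------------------
# fixed-column PDB rendering


def _atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
               pos: np.ndarray, occ: float, b: float, element: str,
               altloc: str = " ", record: str = "ATOM") -> str:
    if len(element) == 2 or len(name) == 4:
        name_field = f"{name:<4s}"
    else:
        name_field = f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:>4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def _residue_b(plan: dict[str, float] | float, resnum: int) -> float:
    if isinstance(plan, dict):
        return float(plan.get(str(resnum), plan.get("default", 20.0)))
    return float(plan)


def _render_pdb(structure_id: str, residues, b_plan, ec_label: str | None) -> str:
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   "
             f"{structure_id[:4].upper():<4s}"]
    lines.append(f"COMPND    MOL_ID: 1;")
    lines.append(f"COMPND   2 MOLECULE: SYNTHETIC MET-AROMATIC FIXTURE;")
    if ec_label:
        lines.append(f"COMPND   3 EC: {ec_label};")
    serial = 1
    for resname, resnum, atoms in residues:
        b = _residue_b(b_plan, resnum)
        for name, pos in atoms.items():
            element = _ELEMENTS.get(name if len(name) <= 2 else name[0], name[0])
            lines.append(_atom_line(serial, name, resname, "A", resnum, pos,
                                    1.00, b, element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# defect fixtures (exercise each parser design decision on purpose)


def build_altloc_fixture(structure_id: str = "ALTL") -> str:
    """Met whose SD has altlocs A (occupancy 0.7) and B (0.3)."""
    met = canonical_met_coords()
    sd_b = met["SD"] + np.array([0.8, 0.0, 0.0])
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   {structure_id:<4s}"]
    serial = 1
    for name in ("CB", "CG"):
        lines.append(_atom_line(serial, name, "MET", "A", 1, met[name], 1.0, 20.0, "C"))
        serial += 1
    lines.append(_atom_line(serial, "SD", "MET", "A", 1, met["SD"], 0.70, 20.0, "S",
                            altloc="A"))
    serial += 1
    lines.append(_atom_line(serial, "SD", "MET", "A", 1, sd_b, 0.30, 20.0, "S",
                            altloc="B"))
    serial += 1
    lines.append(_atom_line(serial, "CE", "MET", "A", 1, met["CE"], 1.0, 20.0, "C"))
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_mse_fixture(structure_id: str = "MSEF") -> str:
    """Selenomethionine residue (SE in place of SD)."""
    met = canonical_met_coords()
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   {structure_id:<4s}"]
    serial = 1
    for name, elem in (("CB", "C"), ("CG", "C"), ("SE", "SE"), ("CE", "C")):
        pos = met["SD"] if name == "SE" else met[name]
        lines.append(_atom_line(serial, name, "MSE", "A", 1, pos, 1.0, 20.0, elem,
                                record="HETATM"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_missing_ring_fixture(structure_id: str = "MISS") -> str:
    """Complete Met plus a Tyr missing its CZ ring atom."""
    met = canonical_met_coords()
    tyr = make_aromatic_residue("TYR", np.array([0.0, 0.0, 4.5]))
    del tyr["CZ"]
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   {structure_id:<4s}"]
    serial = 1
    for name in ("CB", "CG", "SD", "CE"):
        elem = "S" if name == "SD" else "C"
        lines.append(_atom_line(serial, name, "MET", "A", 1, met[name], 1.0, 20.0, elem))
        serial += 1
    for name, pos in tyr.items():
        lines.append(_atom_line(serial, name, "TYR", "A", 2, pos, 1.0, 20.0, "C"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_multimodel_fixture(structure_id: str = "MULT") -> str:
    """Two-model file; model 1 holds a canonical Met, model 2 a shifted copy."""
    met = canonical_met_coords()
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   {structure_id:<4s}"]
    for model_no, shift in ((1, np.zeros(3)), (2, np.array([10.0, 0, 0]))):
        lines.append(f"MODEL     {model_no:>4d}")
        serial = 1
        for name in ("CB", "CG", "SD", "CE"):
            elem = "S" if name == "SD" else "C"
            lines.append(_atom_line(serial, name, "MET", "A", 1, met[name] + shift,
                                    1.0, 20.0, elem))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_waters_only_fixture(structure_id: str = "WATR") -> str:
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-20   {structure_id:<4s}"]
    for i in range(3):
        pos = np.array([4.0 * i, 0.0, 0.0])
        lines.append(_atom_line(i + 1, "O", "HOH", "A", i + 1, pos, 1.0, 30.0, "O",
                                record="HETATM"))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# survey-scale generation


#: Default composition mix for planted clusters, echoing that Phe-rich and
#: mixed clusters dominate while Trp appears more than its background rate.
DEFAULT_MIX: dict[tuple[str, ...], float] = {
    ("PHE", "PHE", "PHE"): 0.25,
    ("PHE", "PHE", "TYR"): 0.2,
    ("PHE", "TRP", "TYR"): 0.2,
    ("PHE", "PHE", "TRP"): 0.15,
    ("TYR", "TYR", "TYR"): 0.1,
    ("TRP", "TRP", "TYR"): 0.1,
}


def build_survey(n_structures: int, planting_rate: float,
                 mix: dict[tuple[str, ...], float] | None = None,
                 seed: int = 0, out_dir: str | Path | None = None,
                 ec_labels: tuple[str | None, ...] = ("1.1.1.1", "3.2.1.14",
                                                      None),
                 ) -> tuple[dict[str, str], list[TruthRow]]:
    """Generate a reproducible survey-scale fixture set.

    Exactly ``round(planting_rate * n_structures)`` structures receive a
    3-bridge cluster (deterministic allocation, not Bernoulli); cluster
    compositions follow ``mix`` by largest-remainder apportionment.
    Non-planted structures carry 0-2 sub-threshold aromatic partners so the
    graph stage sees non-trivial negatives.  Returns ``{filename: content}``
    and the truth table; with ``out_dir`` the files and ``truth.csv`` plus a
    ``params.json`` sidecar are also written.
    """
    if not 0 <= planting_rate <= 1:
        raise ValueError("planting_rate must be in [0, 1]")
    mix = mix or DEFAULT_MIX
    rng = np.random.default_rng(seed)
    n_planted = int(round(planting_rate * n_structures))
    planted_flags = np.zeros(n_structures, dtype=bool)
    planted_flags[rng.permutation(n_structures)[:n_planted]] = True

    comps = _apportion(mix, n_planted)
    comp_iter = iter(comps)

    files: dict[str, str] = {}
    truth: list[TruthRow] = []
    sub_counts = [0, 1, 2]  # partners in non-planted structures, cycled
    sub_i = 0
    for i in range(n_structures):
        sid = f"S{i:04d}"
        if planted_flags[i]:
            comp = next(comp_iter)
            partners = [(rtype, float(rng.uniform(3.8, 5.4)),
                         float(rng.uniform(20, 160)), float(rng.uniform(0, 360)))
                        for rtype in comp]
            partners = _spread_partners(partners, rng)
        else:
            k = sub_counts[sub_i % len(sub_counts)]
            sub_i += 1
            types = rng.choice(["PHE", "TYR", "TRP"], size=k)
            partners = [(str(t), float(rng.uniform(3.8, 5.4)),
                         float(rng.uniform(20, 160)), float(rng.uniform(0, 360)))
                        for t in types]
            partners = _spread_partners(partners, rng)
        spec = PlantSpec(structure_id=sid, partners=partners,
                         decoys=int(rng.integers(2, 6)),
                         b_factor_plan=float(rng.uniform(10, 40)),
                         ec_label=ec_labels[i % len(ec_labels)],
                         seed=int(rng.integers(0, 2**31 - 1)))
        content, row = build_structure(spec)
        files[f"{sid.lower()}.pdb"] = content
        truth.append(row)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, content in files.items():
            (out_dir / fname).write_text(content)
        write_truth_csv(truth, out_dir / "truth.csv")
        (out_dir / "params.json").write_text(json.dumps({
            "n_structures": n_structures, "planting_rate": planting_rate,
            "mix": {"-".join(k): v for k, v in mix.items()}, "seed": seed,
        }, indent=2))
    return files, truth


def _spread_partners(partners, rng, min_sep: float = 3.0, max_tries: int = 500):
    """Resample angles until planted centroids are mutually separated."""
    out: list[tuple[str, float, float, float]] = []
    placed: list[np.ndarray] = []
    for rtype, r, theta, phi in partners:
        for _ in range(max_tries):
            c = spherical_to_cartesian(r, theta, phi)
            if all(np.linalg.norm(c - p) >= min_sep for p in placed):
                break
            theta = float(rng.uniform(20, 160))
            phi = float(rng.uniform(0, 360))
        placed.append(spherical_to_cartesian(r, theta, phi))
        out.append((rtype, r, theta, phi))
    return out


def _apportion(mix: dict[tuple[str, ...], float], total: int) -> list[tuple[str, ...]]:
    """Largest-remainder apportionment of `total` slots over the mix."""
    if total == 0:
        return []
    weights = np.array(list(mix.values()), dtype=float)
    weights = weights / weights.sum()
    raw = weights * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for j in order[:rem]:
        base[j] += 1
    out: list[tuple[str, ...]] = []
    for comp, count in zip(mix.keys(), base):
        out.extend([tuple(sorted(comp))] * int(count))
    return out


def write_truth_csv(truth: list[TruthRow], path: str | Path) -> None:
    import csv
    rows = [t.to_dict() for t in truth]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
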