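"""Reading protein coordinate files into a uniform structure model.

PDB and mmCIF parsing is delegated to :mod:`gemmi`; this module flattens the
selected model into plain :class:`AtomRecord` rows, resolves alternate
locations, and extracts the two kinds of sites the bridge survey needs:
methionine thioether scaffolds (CG-SD-CE) and aromatic rings (Phe/Tyr/Trp)
with their centroids and ring-bond midpoints.
"""

from __future__ import annotations

import logging
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

#: Ring heavy atoms per aromatic residue type.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

#: Ring bonds (adjacent atom pairs) per residue type.  For Trp these are the
#: 10 bonds of the fused indole bicycle with the shared CD2-CE2 bond counted
#: once; midpoints of these bonds are the alternative distance references.
RING_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "PHE": (
        ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
        ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
    ),
    "TYR": (
        ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
        ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
    ),
    "TRP": (
        ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"), ("CE2", "CD2"),
        ("CD2", "CG"),
        ("CD2", "CE3"), ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"),
        ("CZ2", "CE2"),
    ),
}

#: Six-membered-ring atoms of Trp, for the optional benzene-only centroid.
TRP_HEXAGON = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass(frozen=True)
class ResidueRef:
    """Identity of one residue within one model of one structure."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str

    def __str__(self) -> str:  # e.g. "A/MET230"
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{icode}"


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str
    alt_loc: str
    occupancy: float
    b_factor: float
    position: np.ndarray  # (3,) float64, Angstrom
    model_number: int = 1

    @property
    def residue_ref(self) -> ResidueRef:
        return ResidueRef(self.chain_id, self.residue_number,
                          self.insertion_code, self.residue_name)


@dataclass
class StructureModel:
    """Atoms of one selected model plus per-entry metadata."""

    structure_id: str
    atoms: list[AtomRecord]
    ec_numbers: list[str] = field(default_factory=list)
    resolution: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class MetSite:
    """The CG-SD-CE (CH2-S-CH3) scaffold of one methionine."""

    ref: ResidueRef
    cg: np.ndarray
    sd: np.ndarray
    ce: np.ndarray

    def atoms(self) -> np.ndarray:
        return np.vstack([self.cg, self.sd, self.ce])


@dataclass
class AromaticSite:
    """An aromatic ring: named atoms, unweighted centroid, bond midpoints."""

    ref: ResidueRef
    ring_atoms: dict[str, np.ndarray]
    centroid: np.ndarray
    midpoints: np.ndarray  # (n_bonds, 3)


def _warn(model_warnings: list[str], msg: str) -> None:
    model_warnings.append(msg)
    log.warning(msg)


def parse_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Only the first model is kept (X-ray survey convention).  Alternate
    locations are resolved per atom to the highest-occupancy conformer, ties
    broken toward altloc ``A``.  Hydrogens and waters are dropped.

    Parameters
    ----------
    path
        Coordinate file.
    dialect
        ``"pdb"`` or ``"mmcif"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if dialect not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'pdb' or 'mmcif')")

    fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {dialect} file {path}: {exc}") from exc

    # the file stem is the unique handle (PDB accessions are lower-case on
    # disk by convention); header idCode is unreliable for fixtures
    structure_id = path.stem.upper()
    model_warnings: list[str] = []

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    ec_numbers = _extract_ec(path, dialect, st)

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        _warn(model_warnings, f"{structure_id}: no models in file")
    else:
        if len(st) > 1:
            _warn(model_warnings,
                  f"{structure_id}: {len(st)} models present; keeping model 1 only")
        model = st[0]
        for chain in model:
            for residue in chain:
                if residue.name == "HOH":
                    continue
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    seqid = residue.seqid
                    atoms.append(AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        chain_id=chain.name,
                        residue_name=residue.name,
                        residue_number=seqid.num,
                        insertion_code=(seqid.icode or "").strip(),
                        alt_loc=(atom.altloc or "").strip(),
                        occupancy=float(atom.occ),
                        b_factor=float(atom.b_iso),
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        model_number=1,
                    ))

    atoms = _resolve_altlocs(atoms, structure_id, model_warnings)
    if not atoms:
        _warn(model_warnings, f"{structure_id}: zero atoms after model selection")
    return StructureModel(structure_id=structure_id, atoms=atoms,
                          ec_numbers=ec_numbers, resolution=resolution,
                          warnings=model_warnings)


def _extract_ec(path: Path, dialect: str, st: gemmi.Structure) -> list[str]:
    """EC strings from COMPND records (PDB) or _entity.pdbx_ec (mmCIF)."""
    ecs: list[str] = []
    if dialect == "pdb":
        with open(path, errors="replace") as fh:
            for line in fh:
                if line.startswith("COMPND") and "EC:" in line:
                    chunk = line.split("EC:", 1)[1]
                    for token in chunk.replace(";", ",").split(","):
                        token = token.strip().rstrip(".")
                        if token and token[0].isdigit():
                            ecs.append(token)
                elif line.startswith(("ATOM", "HETATM")):
                    break
    else:
        try:
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            for val in block.find_values("_entity.pdbx_ec"):
                val = gemmi.cif.as_string(val).strip()
                if val and val not in {"?", "."}:
                    for token in val.replace(";", ",").split(","):
                        token = token.strip()
                        if token and token[0].isdigit():
                            ecs.append(token)
        except (RuntimeError, ValueError):
            pass
    # de-duplicate, order preserving
    seen: set[str] = set()
    return [e for e in ecs if not (e in seen or seen.add(e))]


def _resolve_altlocs(atoms: list[AtomRecord], structure_id: str,
                     model_warnings: list[str]) -> list[AtomRecord]:
    """Keep one conformer per (residue, atom name): highest occupancy, tie -> 'A'."""
    groups: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code,
               a.residue_name, a.atom_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)

    out: list[AtomRecord] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        # sort: occupancy desc, then altloc letter asc ('' sorts first, then A)
        best = sorted(group, key=lambda a: (-a.occupancy, a.alt_loc or "~"))[0]
        _warn(model_warnings,
              f"{structure_id}: altloc conflict at {group[0].residue_ref} "
              f"{group[0].atom_name}; kept altloc {best.alt_loc!r} "
              f"(occupancy {best.occupancy:.2f})")
        out.append(best)
    return out


def extract_met_sites(model: StructureModel, include_mse: bool = False) -> list[MetSite]:
    """One :class:`MetSite` per Met with a complete CG-SD-CE scaffold.

    With ``include_mse``, selenomethionine is accepted treating SE as SD.
    Residues missing any scaffold atom are skipped with a warning; bond
    lengths outside (1.0, 2.5) A draw a warning but the site is kept.
    """
    wanted = {"MET"} | ({"MSE"} if include_mse else set())
    sites: list[MetSite] = []
    for ref, res_atoms in _iter_residues(model):
        if ref.residue_name not in wanted:
            continue
        sd_name = "SE" if ref.residue_name == "MSE" else "SD"
        coords = {}
        for name in ("CG", sd_name, "CE"):
            if name in res_atoms:
                coords[name] = res_atoms[name].position
        if len(coords) < 3:
            missing = {"CG", sd_name, "CE"} - set(coords)
            _warn(model.warnings,
                  f"{model.structure_id}: {ref} missing {sorted(missing)}; skipped")
            continue
        site = MetSite(ref=ref, cg=coords["CG"], sd=coords[sd_name], ce=coords["CE"])
        for bond, (a, b) in (("CG-SD", (site.cg, site.sd)),
                             ("SD-CE", (site.sd, site.ce))):
            d = float(np.linalg.norm(a - b))
            if not 1.0 < d < 2.5:
                _warn(model.warnings,
                      f"{model.structure_id}: {ref} unusual {bond} length {d:.2f} A")
        sites.append(site)
    return sites


def extract_aromatic_sites(model: StructureModel,
                           trp_centroid: str = "indole") -> list[AromaticSite]:
    """One :class:`AromaticSite` per Phe/Tyr/Trp with a complete ring.

    ``trp_centroid`` selects the Trp centroid convention: ``"indole"`` averages
    all 9 ring heavy atoms (default), ``"hexagon"`` only the 6-membered ring.
    Incomplete rings are skipped with a warning; rings deviating more than
    0.25 A from their best-fit plane draw a warning but are kept.
    """
    if trp_centroid not in {"indole", "hexagon"}:
        raise ValueError("trp_centroid must be 'indole' or 'hexagon'")
    sites: list[AromaticSite] = []
    for ref, res_atoms in _iter_residues(model):
        names = RING_ATOMS.get(ref.residue_name)
        if names is None:
            continue
        if any(n not in res_atoms for n in names):
            missing = [n for n in names if n not in res_atoms]
            _warn(model.warnings,
                  f"{model.structure_id}: {ref} missing ring atoms {missing}; skipped")
            continue
        ring = {n: res_atoms[n].position for n in names}
        pts = np.vstack([ring[n] for n in names])
        if ref.residue_name == "TRP" and trp_centroid == "hexagon":
            centroid = np.vstack([ring[n] for n in TRP_HEXAGON]).mean(axis=0)
        else:
            centroid = pts.mean(axis=0)
        dev = _max_out_of_plane(pts)
        if dev > 0.25:
            _warn(model.warnings,
                  f"{model.structure_id}: {ref} ring non-planar "
                  f"(max deviation {dev:.2f} A)")
        mids = np.vstack([(ring[a] + ring[b]) / 2.0
                          for a, b in RING_BONDS[ref.residue_name]])
        sites.append(AromaticSite(ref=ref, ring_atoms=ring,
                                  centroid=centroid, midpoints=mids))
    return sites


def _max_out_of_plane(pts: np.ndarray) -> float:
    """Largest distance of any point from the points' best-fit plane."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return float(np.abs(centered @ vt[-1]).max())


def _iter_residues(model: StructureModel):
    """Yield (ResidueRef, {atom_name: AtomRecord}) in file order."""
    current_key = None
    current: dict[str, AtomRecord] = {}
    current_ref: ResidueRef | None = None
    for a in model.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        if key != current_key:
            if current_ref is not None:
                yield current_ref, current
            current_key = key
            current_ref = a.residue_ref
            current = {}
        current[a.atom_name] = a
    if current_ref is not None:
        yield current_ref, current


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text structure-ID list: one ID per line, ``#`` comments
    and blank lines tolerated, case-normalized to upper, de-duplicated with
    order preserved."""
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip().upper()
            if not token:
                continue
            if token not in seen:
                seen.add(token)
                ids.append(token)
    if not ids:
        warnings.warn(f"ID list {path} is empty", stacklevel=2)
    return ids


def fetch_structure(structure_id: str, dest_dir: str | Path,
                    base_url: str = "https://files.rcsb.org/download") -> Path:
    """Opt-in download helper for 4-character PDB accessions.

    Never called by default code paths or tests; survey runs are offline
    against a local structure directory unless fetching is requested.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / f"{structure_id.lower()}.pdb"
    if out.exists():
        return out
    url = f"{base_url}/{structure_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=60) as resp:
        out.write_bytes(resp.read())
    return out
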