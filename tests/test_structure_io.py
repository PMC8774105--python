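"""Parsing, site extraction, and ID-list reading."""

import gemmi
import numpy as np
import pytest

from metbridge.structure_io import (RING_BONDS, extract_aromatic_sites,
                                    extract_met_sites, parse_structure,
                                    read_id_list)
from metbridge.synthetic import (PlantSpec, build_altloc_fixture,
                                 build_missing_ring_fixture,
                                 build_mse_fixture, build_multimodel_fixture,
                                 build_structure, build_waters_only_fixture,
                                 canonical_met_coords, make_aromatic_residue,
                                 ring_template)


def _write(tmp_path, name, content):
    p = tmp_path / name
    p.write_text(content)
    return p


def test_roundtrip_preserves_atom_count_and_coordinates(tmp_path):
    """Every atom the fixture writer plants comes back, at PDB precision."""
    spec = PlantSpec(structure_id="RT01",
                     partners=[("PHE", 4.0, 60, 30), ("TRP", 5.0, 120, 200)],
                     decoys=3, seed=11, apply_global_motion=False)
    content, _ = build_structure(spec)
    n_written = sum(1 for line in content.splitlines()
                    if line.startswith(("ATOM", "HETATM")))
    model = parse_structure(_write(tmp_path, "rt01.pdb", content))
    assert len(model) == n_written
    met = extract_met_sites(model)[0]
    truth = canonical_met_coords()
    for name, got in (("CG", met.cg), ("SD", met.sd), ("CE", met.ce)):
        assert np.abs(got - truth[name]).max() < 1e-3


def test_bfactor_roundtrip(tmp_path):
    spec = PlantSpec(structure_id="BF01", partners=[("TYR", 4.5, 90, 0)],
                     decoys=0, b_factor_plan={"1": 13.57, "2": 41.02}, seed=1)
    content, _ = build_structure(spec)
    model = parse_structure(_write(tmp_path, "bf01.pdb", content))
    by_res = {}
    for a in model.atoms:
        by_res.setdefault(a.residue_number, set()).add(round(a.b_factor, 2))
    assert by_res[1] == {13.57}
    assert by_res[2] == {41.02}


def test_altloc_keeps_highest_occupancy(tmp_path):
    """Altloc A at occupancy 0.7 vs B at 0.3: A's position is retained."""
    model = parse_structure(_write(tmp_path, "altl.pdb", build_altloc_fixture()))
    sds = [a for a in model.atoms if a.atom_name == "SD"]
    assert len(sds) == 1
    assert sds[0].occupancy == pytest.approx(0.70)
    assert np.abs(sds[0].position - canonical_met_coords()["SD"]).max() < 1e-3
    assert any("altloc" in w for w in model.warnings)


def test_mse_flag_semantics(tmp_path):
    path = _write(tmp_path, "msef.pdb", build_mse_fixture())
    model = parse_structure(path)
    assert extract_met_sites(model, include_mse=False) == []
    sites = extract_met_sites(model, include_mse=True)
    assert len(sites) == 1
    assert np.abs(sites[0].sd - canonical_met_coords()["SD"]).max() < 1e-3


def test_incomplete_residues_skipped_with_warning(tmp_path):
    model = parse_structure(_write(tmp_path, "miss.pdb",
                                   build_missing_ring_fixture()))
    assert len(extract_met_sites(model)) == 1
    assert extract_aromatic_sites(model) == []
    assert any("missing ring atoms" in w for w in model.warnings)


def test_met_missing_scaffold_atom_skipped(tmp_path):
    content = build_missing_ring_fixture()
    content = "\n".join(l for l in content.splitlines()
                        if not (" CE " in l and "MET" in l)) + "\n"
    model = parse_structure(_write(tmp_path, "nose.pdb", content))
    assert extract_met_sites(model) == []
    assert any("missing" in w and "CE" in w for w in model.warnings)


def test_multimodel_keeps_model_one(tmp_path):
    model = parse_structure(_write(tmp_path, "mult.pdb",
                                   build_multimodel_fixture()))
    assert len(model) == 4  # one Met, not two
    assert any("keeping model 1" in w for w in model.warnings)
    met = extract_met_sites(model)[0]
    assert np.abs(met.sd - canonical_met_coords()["SD"]).max() < 1e-3


def test_waters_only_yields_empty_extraction(tmp_path):
    model = parse_structure(_write(tmp_path, "watr.pdb",
                                   build_waters_only_fixture()))
    assert extract_met_sites(model) == []
    assert extract_aromatic_sites(model) == []


def test_phe_centroid_is_ring_center():
    """Regular hexagon of circumradius 1.39 centered at (3, -2, 7)."""
    from metbridge.structure_io import AtomRecord, StructureModel
    center = np.array([3.0, -2.0, 7.0])
    atoms = []
    for name, pos in make_aromatic_residue("PHE", center).items():
        atoms.append(AtomRecord(atom_name=name, element="C", chain_id="A",
                                residue_name="PHE", residue_number=1,
                                insertion_code="", alt_loc="", occupancy=1.0,
                                b_factor=20.0, position=pos))
    model = StructureModel(structure_id="HEX", atoms=atoms)
    site = extract_aromatic_sites(model)[0]
    assert np.abs(site.centroid - center).max() < 1e-9


def test_trp_centroid_equals_nine_atom_mean():
    """Independent 9-atom average, and the hexagon-only option differs."""
    from metbridge.structure_io import (AtomRecord, RING_ATOMS,
                                        StructureModel, TRP_HEXAGON)
    center = np.array([1.0, 2.0, 3.0])
    coords = make_aromatic_residue("TRP", center, normal=[1, 1, 1], spin_deg=40)
    atoms = [AtomRecord(atom_name=n, element=n[0], chain_id="A",
                        residue_name="TRP", residue_number=5,
                        insertion_code="", alt_loc="", occupancy=1.0,
                        b_factor=10.0, position=p) for n, p in coords.items()]
    model = StructureModel(structure_id="TRPC", atoms=atoms)
    site = extract_aromatic_sites(model)[0]
    hand_mean = np.mean([coords[n] for n in RING_ATOMS["TRP"]], axis=0)
    assert np.abs(site.centroid - hand_mean).max() < 1e-9

    site_hex = extract_aromatic_sites(model, trp_centroid="hexagon")[0]
    hex_mean = np.mean([coords[n] for n in TRP_HEXAGON], axis=0)
    assert np.abs(site_hex.centroid - hex_mean).max() < 1e-9
    assert np.linalg.norm(site_hex.centroid - site.centroid) > 0.1


@pytest.mark.parametrize("rtype,n_mid", [("PHE", 6), ("TYR", 6), ("TRP", 10)])
def test_midpoint_count_matches_ring_bonds(rtype, n_mid):
    from metbridge.structure_io import AtomRecord, StructureModel
    coords = make_aromatic_residue(rtype, np.zeros(3))
    atoms = [AtomRecord(atom_name=n, element=n[0], chain_id="A",
                        residue_name=rtype, residue_number=1,
                        insertion_code="", alt_loc="", occupancy=1.0,
                        b_factor=0.0, position=p) for n, p in coords.items()]
    site = extract_aromatic_sites(StructureModel(structure_id="X", atoms=atoms))[0]
    assert len(site.midpoints) == n_mid == len(RING_BONDS[rtype])


def test_extraction_invariant_to_atom_order(tmp_path, rng):
    spec = PlantSpec(structure_id="ORD1", partners=[("TYR", 4.2, 80, 10)],
                     decoys=0, seed=5)
    content, _ = build_structure(spec)
    lines = content.splitlines()
    head = [l for l in lines if not l.startswith("ATOM")]
    atom_lines = [l for l in lines if l.startswith("ATOM")]
    perm = list(rng.permutation(len(atom_lines)))
    # shuffle atoms *within* each residue (residue order itself is free too,
    # as long as residues stay contiguous for the grouping iterator)
    shuffled = sorted((atom_lines[i] for i in perm), key=lambda l: int(l[22:26]))
    model_a = parse_structure(_write(tmp_path, "a.pdb", content))
    model_b = parse_structure(_write(
        tmp_path, "b.pdb", "\n".join(head[:-1] + shuffled + ["END"]) + "\n"))
    sa = extract_aromatic_sites(model_a)[0]
    sb = extract_aromatic_sites(model_b)[0]
    assert np.abs(sa.centroid - sb.centroid).max() < 1e-12
    ma, mb = extract_met_sites(model_a)[0], extract_met_sites(model_b)[0]
    assert np.abs(ma.sd - mb.sd).max() < 1e-12


def test_mmcif_dialect_matches_pdb(tmp_path):
    spec = PlantSpec(structure_id="CIF1",
                     partners=[("PHE", 4.0, 70, 45)], decoys=2, seed=9)
    content, _ = build_structure(spec)
    pdb_path = _write(tmp_path, "cif1.pdb", content)
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "cif1.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    model_pdb = parse_structure(pdb_path, dialect="pdb")
    model_cif = parse_structure(cif_path, dialect="mmcif")
    assert len(model_pdb) == len(model_cif)
    sd_pdb = extract_met_sites(model_pdb)[0].sd
    sd_cif = extract_met_sites(model_cif)[0].sd
    assert np.abs(sd_pdb - sd_cif).max() < 1e-3


def test_ec_parsed_from_compnd(tmp_path):
    spec = PlantSpec(structure_id="EC01", partners=[], decoys=1,
                     ec_label="3.2.1.14", seed=2)
    content, _ = build_structure(spec)
    model = parse_structure(_write(tmp_path, "ec01.pdb", content))
    assert model.ec_numbers == ["3.2.1.14"]


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError):
        parse_structure("/nonexistent/file.pdb")


def test_read_id_list(tmp_path):
    p = tmp_path / "ids.txt"
    p.write_text("2CYP\n5VWS\n2cyp\n\n# a comment\n1a4e  # trailing\n")
    assert read_id_list(p) == ["2CYP", "5VWS", "1A4E"]
    empty = tmp_path / "empty.txt"
    empty.write_text("# nothing\n\n")
    with pytest.warns(UserWarning):
        assert read_id_list(empty) == []
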