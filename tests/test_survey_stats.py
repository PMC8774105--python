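"""Survey aggregation: tallies, EC classes, histograms, B-factor context."""

import json

import numpy as np
import pytest

from metbridge.bridge_graph import build_graph, find_n_bridges
from metbridge.pair_detection import DetectionConfig, met_aromatic_pairs
from metbridge.structure_io import parse_structure
from metbridge.survey_stats import (COMPOSITIONS_3, bfactor_context,
                                    composition_tally, distance_histogram,
                                    ec_class_tally, primary_ec_class,
                                    scan_structure, survey_run)
from metbridge.synthetic import PlantSpec, build_structure

from test_bridge_graph import _star

CFG = DetectionConfig(distance_metric="sd_to_centroid")


def _cluster(types):
    """A BridgeCluster with the given partner residue types."""
    from metbridge.structure_io import ResidueRef
    from metbridge.synthetic import canonical_met_site, make_aromatic_site
    met = canonical_met_site()
    aros = []
    for k, t in enumerate(types):
        d = np.array([np.cos(2.0 * k), np.sin(2.0 * k), 0.3 * k - 0.3])
        aros.append(make_aromatic_site(
            t, met.sd + (4.0 + 0.3 * k) * d / np.linalg.norm(d),
            ref=ResidueRef("A", 10 + k, "", t)))
    g = build_graph(met_aromatic_pairs([met], aros, CFG))
    clusters = find_n_bridges(g, min(3, len(types)))
    assert len(clusters) == 1
    return clusters[0]


class TestCompositionTally:
    def test_empty_input_all_ten_keys_zero(self):
        tally = composition_tally([])
        assert len(tally) == 10
        assert set(tally) == set(COMPOSITIONS_3)
        assert all(v == 0 for v in tally.values())

    def test_planted_truth_table(self):
        clusters = ([_cluster(["PHE", "PHE", "TRP"])] * 2
                    + [_cluster(["TYR", "TYR", "TYR"])] * 3)
        tally = composition_tally(clusters)
        assert tally[("PHE", "PHE", "TRP")] == 2
        assert tally[("TYR", "TYR", "TYR")] == 3
        assert sum(tally.values()) == 5

    def test_oversize_nearest_and_skip(self):
        """A 4-partner cluster is tallied by its 3 nearest partners, or
        dropped in skip mode."""
        cl = _cluster(["PHE", "TYR", "TRP", "TRP"])
        assert cl.size == 4
        nearest3 = tuple(sorted(
            a.ref.residue_name
            for a, _ in sorted(cl.partners, key=lambda p: p[1].distance)[:3]))
        tally = composition_tally([cl], oversize="nearest")
        assert tally[nearest3] == 1 and sum(tally.values()) == 1
        assert sum(composition_tally([cl], oversize="skip").values()) == 0

    def test_undersized_cluster_rejected(self):
        with pytest.raises(ValueError):
            composition_tally([_cluster(["PHE", "TYR"])])


class TestEcTally:
    def test_first_digit_of_first_ec(self, tmp_path):
        content, _ = build_structure(PlantSpec(structure_id="E3",
                                               ec_label="3.2.1.14", seed=1))
        (tmp_path / "e3.pdb").write_text(content)
        assert primary_ec_class(parse_structure(tmp_path / "e3.pdb")) == "EC3"

    def test_absent_and_malformed_ec(self):
        from metbridge.structure_io import StructureModel
        assert primary_ec_class(StructureModel("X", [])) == "unclassified"
        bad = StructureModel("Y", [], ec_numbers=["9.1.1.1"])
        assert primary_ec_class(bad) == "unclassified"

    def test_planted_class_percentages(self):
        from metbridge.structure_io import StructureModel
        models = ([StructureModel(f"A{i}", [], ec_numbers=["3.2.1.1"])
                   for i in range(4)]
                  + [StructureModel(f"B{i}", []) for i in range(3)]
                  + [StructureModel(f"C{i}", [], ec_numbers=["1.1.1.1"])
                     for i in range(3)])
        counts, percent = ec_class_tally(models)
        assert counts["EC3"] == 4 and counts["EC1"] == 3
        assert counts["unclassified"] == 3
        assert percent["EC3"] == pytest.approx(40.0)
        assert percent["EC1"] == pytest.approx(30.0)
        assert percent["unclassified"] == pytest.approx(30.0)
        assert sum(percent.values()) == pytest.approx(100.0, abs=1e-9)


class TestDistanceHistogram:
    def test_single_value(self):
        edges, counts = distance_histogram([3.7], bin_width=1.0)
        assert counts[3] == 1 and counts.sum() == 1
        assert edges[3] == 3.0 and edges[4] == 4.0

    def test_planted_distances(self):
        edges, counts = distance_histogram([2.5, 2.5, 5.9], bin_width=1.0)
        assert counts[2] == 2
        assert counts[5] == 1
        assert counts.sum() == 3

    def test_half_open_bins(self):
        _, counts = distance_histogram([2.0, 3.0], bin_width=1.0)
        assert counts[2] == 1 and counts[3] == 1  # boundary goes right

    def test_conservation(self, rng):
        d = rng.uniform(0, 6, 500)
        _, counts = distance_histogram(d, bin_width=0.5)
        assert counts.sum() == 500

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            distance_histogram([1.0], bin_width=0)


class TestBFactorContext:
    def _model_with_cluster(self, tmp_path, b_plan):
        spec = PlantSpec(structure_id="BFC1",
                         partners=[("PHE", 4.0, 60, 0), ("TYR", 4.4, 90, 120),
                                   ("TRP", 4.8, 120, 240)],
                         decoys=90, decoy_exclusion=9.0,
                         b_factor_plan=b_plan, seed=6)
        content, _ = build_structure(spec)
        path = tmp_path / "bfc1.pdb"
        path.write_text(content)
        res = scan_structure(path, CFG, n=3)
        assert len(res.clusters) == 1
        return res.clusters[0], res.model

    def test_uniform_b_sits_at_midrank(self, tmp_path):
        cluster, model = self._model_with_cluster(tmp_path, 20.0)
        ctx = bfactor_context(cluster, model)
        assert ctx.mean_b_cluster == pytest.approx(20.0)
        assert ctx.mean_b_protein == pytest.approx(20.0)
        assert ctx.percentile_of_cluster_mean == pytest.approx(50.0)

    def test_rigid_cluster_ranks_low(self, tmp_path):
        """Cluster residues at B=10 among 90 decoys at B=50 rank below the
        5th percentile."""
        plan = {"default": 50.0, "1": 10.0, "2": 10.0, "3": 10.0, "4": 10.0}
        cluster, model = self._model_with_cluster(tmp_path, plan)
        ctx = bfactor_context(cluster, model)
        assert ctx.mean_b_cluster == pytest.approx(10.0)
        assert ctx.percentile_of_cluster_mean < 5.0

    def test_percentile_affine_invariant(self, tmp_path):
        plan = {"default": 30.0, "1": 18.0, "2": 24.0, "3": 36.0, "4": 12.0}
        cluster, model = self._model_with_cluster(tmp_path, plan)
        base = bfactor_context(cluster, model).percentile_of_cluster_mean
        for atom in model.atoms:
            atom.b_factor = 3.0 * atom.b_factor + 7.0
        rescaled = bfactor_context(cluster, model).percentile_of_cluster_mean
        assert rescaled == pytest.approx(base, abs=1e-9)

    def test_all_zero_b_flagged(self, tmp_path):
        cluster, model = self._model_with_cluster(tmp_path, 0.0)
        assert bfactor_context(cluster, model).uninformative


class TestSurveyRun:
    def _small_survey(self, tmp_path):
        from metbridge.synthetic import build_survey
        files, truth = build_survey(12, 0.25, seed=5, out_dir=tmp_path)
        return sorted(tmp_path.glob("*.pdb")), truth

    def test_counts_match_truth(self, tmp_path):
        paths, truth = self._small_survey(tmp_path)
        summary, results = survey_run(paths)
        assert summary.n_structures_scanned == 12
        expected = sum(t.has_cluster for t in truth)
        assert summary.n_structures_with_cluster == expected == 3
        assert summary.fraction_with_cluster == pytest.approx(25.0)
        assert sum(summary.composition_counts.values()) == \
            summary.n_clusters_total

    def test_order_invariance_and_determinism(self, tmp_path):
        paths, _ = self._small_survey(tmp_path)
        s1, _ = survey_run(paths)
        s2, _ = survey_run(list(reversed(paths)))
        j1 = json.dumps(s1.to_json_dict(), sort_keys=True)
        j2 = json.dumps(s2.to_json_dict(), sort_keys=True)
        assert j1 == j2

    def test_failures_isolated(self, tmp_path):
        paths, _ = self._small_survey(tmp_path)
        bad = tmp_path / "badfile.pdb"
        bad.write_text("not a coordinate file at all\nATOM broken\n")
        missing = tmp_path / "ghost.pdb"
        summary, _ = survey_run(list(paths) + [missing])
        assert summary.n_structures_failed >= 1
        assert summary.n_structures_scanned >= 12

    def test_empty_survey(self):
        summary, results = survey_run([])
        assert summary.n_structures_scanned == 0
        assert summary.fraction_with_cluster == 0.0
        assert results == []
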