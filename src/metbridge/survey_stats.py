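"""Survey-level aggregation: composition tallies, EC breakdown, distance
histograms, local-frame scatter export, and B-factor context."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
from scipy import stats

from .bridge_graph import BridgeCluster, build_graph, find_n_bridges
from .met_frame import LocalFramePoint, cluster_to_local_frame
from .pair_detection import DetectionConfig, met_aromatic_pairs
from .structure_io import (StructureModel, extract_aromatic_sites,
                           extract_met_sites, parse_structure)

log = logging.getLogger(__name__)

AROMATIC_TYPES = ("PHE", "TRP", "TYR")

#: The 10 possible unordered compositions of a 3-bridge cluster.
COMPOSITIONS_3 = tuple(combinations_with_replacement(AROMATIC_TYPES, 3))

EC_CLASSES = ("EC1", "EC2", "EC3", "EC4", "EC5", "EC6", "EC7", "unclassified")


@dataclass
class SurveySummary:
    n_structures_scanned: int
    n_structures_failed: int
    n_structures_with_cluster: int
    n_clusters_total: int
    fraction_with_cluster: float  # percent
    composition_counts: dict[tuple[str, ...], int]
    ec_counts: dict[str, int]
    ec_percent: dict[str, float]
    distance_histogram: tuple[np.ndarray, np.ndarray]  # (edges, counts)

    def to_json_dict(self) -> dict:
        edges, counts = self.distance_histogram
        return {
            "n_structures_scanned": self.n_structures_scanned,
            "n_structures_failed": self.n_structures_failed,
            "n_structures_with_cluster": self.n_structures_with_cluster,
            "n_clusters_total": self.n_clusters_total,
            "fraction_with_cluster_pct": self.fraction_with_cluster,
            "composition_counts": {"-".join(k): v
                                   for k, v in self.composition_counts.items()},
            "ec_counts": dict(self.ec_counts),
            "ec_percent": dict(self.ec_percent),
            "distance_histogram": {"edges": [float(e) for e in edges],
                                   "counts": [int(c) for c in counts]},
        }


@dataclass
class BFactorContext:
    cluster_id: str
    mean_b_cluster: float
    mean_b_protein: float
    percentile_of_cluster_mean: float
    uninformative: bool = False


def composition_tally(clusters: list[BridgeCluster],
                      oversize: str = "nearest") -> dict[tuple[str, ...], int]:
    """Count clusters over the 10 unordered {Phe,Tyr,Trp} size-3 compositions.

    Clusters with more than 3 partners are tallied by their 3 nearest
    partners (``oversize="nearest"``) or dropped (``oversize="skip"``).
    All 10 keys are present even at zero count.
    """
    if oversize not in {"nearest", "skip"}:
        raise ValueError("oversize must be 'nearest' or 'skip'")
    counts: dict[tuple[str, ...], int] = {k: 0 for k in COMPOSITIONS_3}
    for cl in clusters:
        if cl.size < 3:
            raise ValueError(
                f"cluster at {cl.met.ref} has {cl.size} partners; "
                "composition tally requires order-3 clusters")
        partners = cl.partners
        if cl.size > 3:
            if oversize == "skip":
                continue
            partners = sorted(partners, key=lambda p: p[1].distance)[:3]
        key = tuple(sorted(a.ref.residue_name for a, _ in partners))
        counts[key] += 1
    return counts


def primary_ec_class(model: StructureModel) -> str:
    """EC1..EC7 from the first digit of the first EC number, else unclassified."""
    for ec in model.ec_numbers:
        digit = ec.strip()[:1]
        if digit.isdigit() and 1 <= int(digit) <= 7:
            return f"EC{digit}"
        log.warning("%s: malformed EC string %r; counted as unclassified",
                    model.structure_id, ec)
    return "unclassified"


def ec_class_tally(models_with_clusters: list[StructureModel]
                   ) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and percentages of primary EC class over structures that
    contain at least one cluster.  All classes present, zeros included."""
    counts = {k: 0 for k in EC_CLASSES}
    for m in models_with_clusters:
        counts[primary_ec_class(m)] += 1
    total = sum(counts.values())
    percent = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return counts, percent


def distance_histogram(distances: np.ndarray, bin_width: float = 0.5,
                       upper: float | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of contact distances over half-open bins [lo, hi) from 0.

    The final edge is extended so every input falls in some bin; counts
    conserve the number of inputs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = np.asarray(distances, dtype=float)
    if upper is None:
        top = float(distances.max()) if distances.size else bin_width
        upper = bin_width * np.ceil(top / bin_width + 1e-12)
        upper = max(upper, bin_width)
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    if distances.size and distances.max() >= edges[-1]:
        edges = np.append(edges, edges[-1] + bin_width)
    idx = np.floor(distances / bin_width).astype(int)
    counts = np.bincount(idx, minlength=len(edges) - 1) if distances.size else \
        np.zeros(len(edges) - 1, dtype=int)
    return edges, counts[:len(edges) - 1]


def bfactor_context(cluster: BridgeCluster, model: StructureModel) -> BFactorContext:
    """Flexibility of a cluster relative to its protein.

    The cluster mean is over all atoms of the Met plus partner residues; the
    reference distribution is the per-residue mean B of all protein residues;
    the percentile uses mid-rank tie handling so a uniform B column sits at 50.
    """
    cluster_refs = {cluster.met.ref} | {a.ref for a, _ in cluster.partners}
    residue_b: dict = {}
    cluster_b: list[float] = []
    for atom in model.atoms:
        ref = atom.residue_ref
        residue_b.setdefault(ref, []).append(atom.b_factor)
        if ref in cluster_refs:
            cluster_b.append(atom.b_factor)
    per_residue_means = np.array([np.mean(v) for v in residue_b.values()])
    all_b = np.concatenate([np.asarray(v, dtype=float) for v in residue_b.values()])
    mean_cluster = float(np.mean(cluster_b))
    mean_protein = float(np.mean(all_b))
    uninformative = bool(np.allclose(all_b, 0.0))
    percentile = float(stats.percentileofscore(per_residue_means, mean_cluster,
                                               kind="mean"))
    cid = f"{model.structure_id}:{cluster.met.ref}"
    return BFactorContext(cluster_id=cid, mean_b_cluster=mean_cluster,
                          mean_b_protein=mean_protein,
                          percentile_of_cluster_mean=percentile,
                          uninformative=uninformative)


# ---------------------------------------------------------------------------
# whole-survey driver


@dataclass
class StructureResult:
    model: StructureModel
    clusters: list[BridgeCluster]
    local_points: list[LocalFramePoint]
    contacts: list = field(default_factory=list)


def scan_structure(path: str | Path, config: DetectionConfig | None = None,
                   n: int = 3, combinatorial: bool = False) -> StructureResult:
    """Run the full per-structure pipeline: parse, detect, bridge, frame."""
    config = config or DetectionConfig()
    model = parse_structure(path)
    mets = extract_met_sites(model, include_mse=config.include_mse)
    aromatics = extract_aromatic_sites(model)
    contacts = met_aromatic_pairs(mets, aromatics, config)
    graph = build_graph(contacts)
    clusters = find_n_bridges(graph, n=n, combinatorial=combinatorial)
    points: list[LocalFramePoint] = []
    for cl in clusters:
        try:
            points.extend(cluster_to_local_frame(cl, model.structure_id))
        except ValueError as exc:
            log.warning("skipping frame for degenerate cluster: %s", exc)
    return StructureResult(model=model, clusters=clusters,
                           local_points=points, contacts=contacts)


def survey_run(paths: list[str | Path], config: DetectionConfig | None = None,
               n: int = 3, combinatorial: bool = False,
               bin_width: float = 0.5
               ) -> tuple[SurveySummary, list[StructureResult]]:
    """Aggregate the pipeline over many structures.

    Unparseable entries are logged, counted as failed, and excluded from
    denominators.  Output is deterministic: results are keyed by sorted
    structure path, so scan order never changes the summary.
    """
    config = config or DetectionConfig()
    results: list[StructureResult] = []
    n_failed = 0
    for path in sorted(Path(p) for p in paths):
        try:
            results.append(scan_structure(path, config, n=n,
                                          combinatorial=combinatorial))
        except (ValueError, FileNotFoundError, RuntimeError) as exc:
            n_failed += 1
            log.warning("failed to scan %s: %s", path, exc)
    results.sort(key=lambda r: r.model.structure_id)

    n_scanned = len(results)
    with_cluster = [r for r in results if r.clusters]
    all_clusters = [cl for r in results for cl in r.clusters]
    tally = (composition_tally(all_clusters) if n == 3
             else {k: 0 for k in COMPOSITIONS_3})
    ec_counts, ec_percent = ec_class_tally([r.model for r in with_cluster])
    dists = np.array([c.distance for r in results for c in r.contacts])
    hist = distance_histogram(dists, bin_width=bin_width,
                              upper=config.cutoff_distance)
    frac = 100.0 * len(with_cluster) / n_scanned if n_scanned else 0.0
    if n_scanned == 0:
        log.warning("survey scanned zero structures")
    summary = SurveySummary(
        n_structures_scanned=n_scanned,
        n_structures_failed=n_failed,
        n_structures_with_cluster=len(with_cluster),
        n_clusters_total=len(all_clusters),
        fraction_with_cluster=frac,
        composition_counts=tally,
        ec_counts=ec_counts,
        ec_percent=ec_percent,
        distance_histogram=hist)
    return summary, results
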