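# metbridge

Detection and geometric survey of **methionine–aromatic n-bridge clusters**
in protein structures.

The thioether group of methionine ([-CH₂-S-CH₃]) makes weak, favorable
(~1–3 kcal mol⁻¹) non-covalent contacts with the π faces of phenylalanine,
tyrosine and tryptophan — a blend of S–π and CH–π interactions. A
*3-bridge cluster* is a Met whose side chain is surrounded by three such
aromatic partners at once, a recurring structural motif proposed to balance
stability and flexibility in proteins of every enzyme class. This package
implements the complete survey pipeline:

1. **structure_io** — parse PDB/mmCIF coordinate files (via gemmi) into a
   flat atom model; select model 1, resolve altlocs by highest occupancy,
   extract Met CG-SD-CE scaffolds and aromatic rings with centroids and
   ring-bond midpoints; read EC annotations and survey ID lists.
2. **pair_detection** — find Met–aromatic contacts under a 6.0 Å inclusive
   distance cutoff with the angle criterion disabled (360°). Two distance
   conventions are computed for every pair: SD→nearest ring-bond midpoint
   (the default) and SD→ring centroid.
3. **bridge_graph** — treat Mets and aromatics as nodes of a bipartite
   interaction graph (networkx) and enumerate n-bridge clusters: Mets with
   aromatic degree ≥ n, with n = 3 the motif of interest.
4. **met_frame** — map each cluster into a canonical Met-centered frame by
   a two-quaternion construction: translate SD to the origin, rotate by Q1
   about cross(SD→CE, x̂) through α = arccos of the direction cosine of
   SD→CE with x̂ so the S–CH₃ bond lies on +x, then rotate by Q2 about x̂
   through −β so CG lands in the x,y-plane with y ≥ 0. Aromatic centroids
   carried by Q2·Q1 become directly comparable across structures.
5. **survey_stats** — aggregate: cluster composition tallies over the 10
   possible {Phe,Tyr,Trp} triples, EC-class breakdown, contact-distance
   histograms, and per-cluster B-factor context (cluster mean vs the
   per-residue distribution of the whole protein).
6. **synthetic** — a first-class generator of valid fixed-column PDB
   fixtures with clusters planted at exact spherical coordinates in the
   canonical frame, decoy residues, defect fixtures (altlocs, missing ring
   atoms, selenomethionine, multi-model files) and a ground-truth table,
   so the entire pipeline is testable without downloading anything.

## Worked example

Generate a 200-structure synthetic survey with 3-bridge clusters planted in
12% of entries, scan it, and aggregate:

```sh
metbridge fixtures --n 200 --rate 0.12 --seed 20211221 -o scratch/fixtures
metbridge scan scratch/fixtures -o scratch/scan
metbridge stats scratch/scan
```

The scan prints:

```
scanned 200 structures (0 failed); 24 with >= 1 cluster (12.0%); 24 clusters total
```

and `scratch/scan/` holds `contacts.csv` (one row per Met–aromatic pair
with both distance conventions and the two lone-pair angles),
`clusters.csv` (one row per maximal 3-bridge with its composition),
`local_frame.csv` (aromatic centroids in the canonical Met frame — the
input for spatial-distribution plots) and `summary.json`. On this fixture
set the 247 detected contacts peak at 3.0–3.5 Å, the 24 recovered clusters
match the planted truth table with precision = recall = 1.0, and their
compositions reproduce the planted mix exactly (e.g. 6× Phe-Phe-Phe,
5× Phe-Trp-Tyr).

The same steps are scripted as a narrative analysis under `analysis/`
(`01_build_fixtures.py` … `05_worked_examples.py`), writing their tables
to `results/`. The final script checks published positive controls
(2-bridges Met230–{Trp191,Tyr187} and Met231–{Trp191,Phe202} in cytochrome
c peroxidase 2CYP; the Met24 3-bridge in cytochrome P450 5VWS; two
3-bridges in yeast catalase 1A4E; one in haloalkane dehalogenase 1B6G) and
needs the deposited coordinate files — it fetches them on demand when a
network is available and reports them as unavailable otherwise.

Scanning a real survey works the same way: `metbridge scan --id-list
ids.txt --structure-dir /path/to/pdb -o out` (add `--fetch` to download
missing accessions).

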