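# Methods

## The model

A pharmacophore here is an ordered set of typed features in Cartesian
ångström coordinates — hydrogen-bond acceptor (ACC), donor (DON) and
hydrophobic centroid (HYD), each with a tolerance-sphere radius — plus
optional projected site points (ACC_PROJ / DON_PROJ) that pin the direction
of a hydrogen bond toward the putative receptor partner, and a set of
excluded volumes marking receptor-occupied space. The bundled default query
emulates the classic type II kinase inhibitor arrangement: a hinge-region
acceptor, an αC-helix-glutamate donor, a DFG-aspartate acceptor (each with a
projection 3 Å out) and one broad hydrophobe for the allosteric back
pocket, with 30 excluded volumes on a 12 Å shell. Its numeric geometry is
illustrative — chosen once to be realistic and to satisfy the separation
condition required by the planted-library guarantees (every feature pair
farther apart than the sum of its radii) — not fitted to any particular
crystal structure.

Serialization is canonical JSON with 6-decimal floats, so identical models
produce byte-identical files; consequently save∘load is the exact identity
on models whose coordinates carry at most six decimals.

## Feature perception

Perception is SMARTS-driven (RDKit matching) with conventional defaults:

- donors: N or O bearing at least one hydrogen (`[#7;!H0]`, `[#8;!H0]`);
- acceptors: N or O, not positively charged, excluding amide nitrogen;
- hydrophobes: carbon atoms grouped into all-carbon rings of ≥ 5 atoms and
  acyclic connected carbon components of ≥ 3 atoms; the feature sits at the
  unweighted group centroid.

Projected site points lie `projection_distance` (default 3.0 Å, a typical
donor···acceptor separation) from the parent heavy atom: for donors along
the heavy-atom→H unit vector (the lowest-index hydrogen when several are
bonded — a deterministic tie-break), for acceptors opposite the mean unit
vector to bonded heavy neighbours, a lone-pair-direction proxy. An acceptor
with no heavy neighbour (an isolated water-like oxygen) or a perfectly
symmetric neighbour shell has no defined direction and receives no
projection. Donor projection requires an explicit hydrogen; the SDF reader
adds missing hydrogens with generated coordinates at load time. Features are
ordered by kind and then by lowest owning atom index, which fixes every
downstream tie-break.

## Model construction from complexes

Complexes are superposed onto a chosen reference with the Kabsch algorithm
on paired α-carbon coordinates (≥ 3 non-collinear pairs per complex; the
pairing defaults to identical residue ids and can be supplied explicitly).
Interactions are detected with field-conventional cutoffs: a hydrogen bond
iff donor-heavy···acceptor ≤ 3.5 Å **and** D–H···A ≥ 120°; a hydrophobic
contact iff a ligand hydrophobe centroid lies within 4.5 Å of at least 3
apolar (C/S) protein atoms. Protein-side donors must carry an explicit
hydrogen within 1.25 Å; pairs without one are never counted as hydrogen
bonds, keeping the distance+angle contract exact rather than silently
falling back to a distance-only rule.

Like-kind interaction points are clustered by single linkage with a 1.5 Å
link tolerance; a cluster becomes a common feature (at its centroid) when
supported by at least `min_support` distinct complexes — by default all of
them, i.e. features common to every complex. Excluded-volume candidates are
protein heavy atoms within 5 Å of any ligand atom, excluding those within
2 Å of a feature center; up to 30 are kept by greedy maximin selection
(first the candidate farthest from the features, then repeatedly the
candidate maximizing the minimum distance to those already kept), with ties
broken on (residue id, atom name, complex id) so placement is deterministic.
Candidate model enumeration is specification-driven: each named feature
subset (with optional per-feature radius overrides) becomes one query
sharing the common volume list.

## Screening

The engine mirrors the usual two-stage pharmacophore search. The distance
prefilter enumerates kind-compatible injective assignments of molecule
features to the query's required features, pruning any partial assignment
with a pair violating |d_mol − d_query| ≤ r_i + r_j. This slack makes the
filter admissible: after optimal rigid alignment, per-feature deviations
e_i bound every pair's distance change by e_i + e_j, so an assignment whose
deviations all fit inside the tolerance spheres can never be eliminated.
Each surviving assignment is superposed by closed-form Kabsch (SVD with the
determinant correction, so reflections are never returned; coincident
degenerate input yields the identity rotation and centroid translation).
RMSD is computed over feature centers (mains and projections), not atoms.
The minimum-RMSD assignment wins, ties going to the first in lexicographic
mapping order. The winning transform is applied to all conformer atoms; a
clash is any atom strictly closer than volume radius + atom radius (default
1.0 Å) to a volume center — touching exactly is not a clash. A hit requires
RMSD ≤ threshold (default 1.0 Å) and no clash; by default all query
features are required (no partial matching), with `required_feature_ids`
available to relax that.

Per molecule, the reported result is the minimum-RMSD conformer (ties to
the lowest conformer index); if the minimum-RMSD conformer clashes while
another conformer hits, the best *hit* is reported so the molecule's hit
flag and listed RMSD stay consistent. Hit lists sort ascending by RMSD. A
conformer with no surviving mapping reports RMSD = +inf and no mapping.

## Validation metrics

Confusion counts are summed across targets before any metric is computed —
metrics of a sum, never averages of per-target metrics. All eight metrics
(Se, Sp, Ya, E, Acc, DR, F1, MCC; formulas in the README) are evaluated in
exact rational arithmetic; MCC uses one floating square root. Reported
precision is 3 decimals (4 for F1 and MCC) with half-up rounding. Enrichment
uses whole-set prevalence, E = Ya·N/A. The discrimination ratio is DR =
Se/Sp. A metric with a vanishing denominator is flagged undefined, never
silently zeroed; F1, the harmonic mean of Se and Ya, is undefined whenever
Ya is. `back_solve_counts` searches tp ∈ [0, A] and hits ∈ [max(tp,1),
tp+D] exhaustively for integer counts whose exact Se and Ya round to given
printed values; the bundled 17-row reference table is verified row by row by
requiring all eight recomputed metrics to round to the printed row.

## Synthetic data

The planted library emulates a per-kinase active/decoy benchmark: three
targets with 26/801, 20/600 and 27/913 actives/decoys (≈30 decoys per
active, 2387 compounds in total), and planted totals of 55 true and 91
false positives split uniformly at random across targets under the seed.
Planted matchers place, for every required main feature, a minimal fragment
(carbonyl for ACC, hydroxyl for DON — which also contributes an acceptor, as
perception sees it — propane for HYD) at the query position plus a jitter
vector clipped to rmsd_threshold/2, then re-pose the molecule rigidly; the
identity assignment therefore survives the prefilter and scores below
threshold, so hits are guaranteed analytically, not probabilistically.
Non-matchers either lack one required feature kind entirely or have all
anchors scaled ×2 about the feature centroid; each scaled candidate's exact
feature geometry is checked against the prefilter at build time and falls
back to the kind-dropping construction in the (for the default query,
never observed) event a scaled geometry slips through. Generators are pure
functions of their seeds, and SDF/CSV output is byte-stable.

What this does and does not show: planted libraries exercise perception,
prefiltering, superposition, clash testing and bookkeeping end to end with
an exactly known ground truth, but their "molecules" are disconnected
fragment assemblies with trivial conformational behaviour. Recovering the
planted confusion matrix validates the machinery, not the biological
realism of any particular query; screening real conformer ensembles from
real decoy sets remains subject to perception-scheme and conformer-quality
differences between tools.

Toy complexes serve the construction path the same way: each requested
hydrogen bond is a ligand hydroxyl donating to a lone protein carbonyl
oxygen at an exact distance/angle (default 2.9 Å, 160°), each hydrophobic
contact a ligand propane ringed by three protein carbons at 4 Å, sites
spaced 14 Å apart so they cannot interact, plus three non-collinear
α-carbons for alignment.

## Numerical choices

- Floats serialize at 6 decimals; screening RMSDs print at 3 decimals.
- Feature radii default to 1.0 Å (main) and 1.5 Å (projected); the default
  query's hydrophobe uses 1.5 Å to reflect its broader tolerance.
- RMSD threshold defaults to 1.0 Å over feature centers.
- Tie-breaks are lexicographic everywhere (mapping order, conformer index,
  molecule id, residue id/atom name), making runs bit-reproducible.
- Kabsch refuses < 3 pairs; α-carbon alignment additionally refuses
  collinear point sets (second singular value below 1e-8 of the first).
- Excluded-volume clash and keepout comparisons use strict/non-strict
  inequalities as documented above, with boundary cases pinned by tests.

## Problem sizes

The test suite and the acceptance script run the full 2387-compound planted
benchmark through molecule construction, RDKit perception and screening
(a few seconds on one CPU); the screening-engine guarantees are checked on
1000 random query/molecule instances against a no-prefilter exhaustive
permutation oracle, and planted-confusion recovery on 20 random
specifications with 24–300 compounds each. These sizes were chosen to
exercise every code path at full benchmark scale while keeping a complete
run interactive.

## Known limitations

- MOE's proprietary feature-typing, alignment and scoring schemes are not
  published; this package's SMARTS rules and thresholds are conventional
  stand-ins, so hit-for-hit agreement with MOE screens is not expected.
- Published figures give inter-feature distances only graphically, so the
  default query geometry is illustrative rather than a transcription.
- No tautomer/protonation enumeration, no conformer generation (libraries
  supply conformers), no aromatic-plane or charge features, no
  water-mediated or halogen bonds, and no scoring beyond feature RMSD.
- Partial matching exists (`required_feature_ids`) but is off by default;
  all features of a query must map.
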