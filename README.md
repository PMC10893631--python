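# ph4screen

Receptor-based 3D pharmacophore construction, pharmacophore virtual
screening, and active/decoy validation — built for multi-kinase inhibitor
discovery campaigns of the VEGFR-2 / FGFR-1 / BRAF kind, where a single
query model must capture the binding features shared by type II inhibitors
across several kinases.

## What it does

**Model construction** (`ph4screen.rbuilder`). Protein–ligand complexes are
rigidly superposed on paired α-carbons (closed-form Kabsch alignment),
ligand–protein interactions are detected per complex (hydrogen bonds by a
donor···acceptor distance + D–H···A angle rule; hydrophobic contacts by
proximity of a ligand hydrophobe centroid to apolar protein atoms), and
like-kind interaction points are single-linkage clustered across complexes.
Clusters common to enough complexes become pharmacophoric features —
hydrogen-bond acceptors (Acc), donors (Don) and hydrophobes (Hyd), with
projected site points encoding H-bond directionality. Excluded volumes are
placed on binding-site protein atoms to mark receptor-occupied space, and
named feature combinations are enumerated into candidate query models.

**Screening** (`ph4screen.matcher`). For each conformer, perceived features
are mapped onto the query in two stages: a distance prefilter enumerates
kind-compatible injective assignments whose inter-feature distances agree
within the summed tolerance radii, then each surviving assignment is rigidly
superposed onto the query feature centers by the Kabsch algorithm (proper
rotations only). The assignment of least RMSD wins; a conformer is a hit iff

    RMSD ≤ threshold   and   no atom enters an excluded volume.

**Validation** (`ph4screen.valmetrics`). Screens of labelled active/decoy
test sets are reduced to per-target confusion matrices, summed across
targets (TPt, FPt, TNt, FNt), and scored with the eight-metric suite

    Se = TP/(TP+FN)          Sp = TN/(TN+FP)       Ya = TP/(TP+FP)
    E  = Ya·N/A              Acc = (TP+TN)/N       DR = Se/Sp
    F1 = 2TP/(2TP+FP+FN)     MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with A actives, D decoys, N = A + D. All ratios are computed in exact
rational arithmetic and reported with half-up rounding (3 decimals; F1 and
MCC at 4). `back_solve_counts` inverts rounded (Se, Ya) pairs back to the
integer confusion matrix by exhaustive search, which lets a whole printed
metrics table be cross-validated for integer consistency.

**Synthetic benchmarks** (`ph4screen.synthdata`). Because real DUD-E /
DEKOIS-style test sets cannot be bundled, the package plants them: minimal
chemically valid fragments (carbonyl → Acc, hydroxyl → Don, propane → Hyd)
are assembled so that perception lands features exactly at prescribed
positions. Planted matchers carry bounded jitter under a random rigid motion
and are guaranteed hits; planted non-matchers provably fail the distance
prefilter. Screening such a library reproduces a prescribed confusion matrix
exactly, which makes the whole pipeline testable end to end.

## Worked example

Screen the default planted benchmark (three kinase test sets, 73 actives and
2314 decoys at a ≈30 decoys/actives ratio) against the bundled
seven-feature, 30-excluded-volume query:

```python
from ph4screen.matcher import screen_library
from ph4screen.synthdata import default_plant_spec, plant_matched_library
from ph4screen.valmetrics import (Label, TestSetLabel, aggregate_counts,
                                  compute_metrics, confusion_from_screen)

spec = default_plant_spec(seed=0)
records, labels = plant_matched_library(spec)
report = screen_library(records, spec.query)
print(f"{report.query_name}: {report.n_hits} hits of {report.n_screened} screened")

per_target = {}
for row in labels.itertuples(index=False):
    per_target.setdefault(row.target, []).append(
        TestSetLabel(row.compound_id, row.target, Label(row.label)))
counts = aggregate_counts(
    [confusion_from_screen(report, labs) for labs in per_target.values()])
print(f"TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
print(compute_metrics(counts).rounded())
```

prints

```
Ph4-4-like: 146 hits of 2387 screened
TP=55 FP=91 TN=2223 FN=18
{'se': 0.753, 'sp': 0.961, 'ya': 0.377, 'e': 12.318, 'acc': 0.954,
 'dr': 0.784, 'f1': 0.5023, 'mcc': 0.5131}
```

The screen retrieves 146 of 2387 compounds; 55 of the 73 actives are
recovered (Se 0.753) at a 12.3-fold enrichment over random picking, and the
suite summarises the model's balance between retrieving actives and
discarding decoys in a single MCC of 0.5131.

The same operations are available from the shell: `ph4 simulate library`,
`ph4 screen`, `ph4 validate metrics`, `ph4 validate rank`, `ph4 model
validate`, `ph4 build` (see `ph4 --help`).

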