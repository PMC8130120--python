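# dnahotspot

Prediction of hot spot residues at protein–DNA interfaces from structural
features. Given a PDB-format complex, the pipeline

1. parses the structure, classifies chains and defines two coordinate views:
   the bound complex and the unbound protein (DNA chains removed, coordinates
   frozen);
2. computes per-residue solvent-accessible surface area (Shrake–Rupley on a
   deterministic Fibonacci lattice) on both views and marks residues whose
   total ASA drops on binding as interface residues;
3. encodes every interface residue as 24 features: 12 ASA quantities (bound
   values, binding-induced change, relative change; total/side-chain ×
   absolute/relative), eigenvector centrality in the interface contact
   network, the backbone psi torsion, a half-sphere Cα–Cβ contact number,
   a hydrogen-bond donor count, and 8 interfacial-neighbor ratio features
   comparing each residue's ASA quantities to the mean over its interface
   neighbors within 6.5 Å (Cα–Cα);
4. selects features in two steps — SVM-RFE ranking with a cross-validated
   AUC stopping rule, then Pearson-correlation redundancy pruning at
   r > 0.65 — and
5. trains an RBF-kernel SVM with a grid search over C ∈ [0.1, 10] and
   γ ∈ [0.005, 0.5] under stratified tenfold cross-validation.

A synthetic-fixture generator (toy peptide + B-DNA complexes, labeled
feature tables with planted informative/correlated columns) makes every
stage testable without external data.

## CLI

```sh
# generate a toy complex and featurize it
dnahotspot fixtures complex --gap 3.5 --seed 1 -o toy.pdb
dnahotspot featurize toy.pdb --protein-chains A --dna-chains B,C -o features.tsv

# synthetic labeled table -> selection -> training -> prediction -> evaluation
dnahotspot fixtures table --n-positive 62 --n-negative 88 --informative 5 \
    --noise 15 --corr-pairs 4 -o table.tsv
dnahotspot select table.tsv -o selection.json
dnahotspot train table.tsv --features "$(python -c 'import json;print(",".join(json.load(open("selection.json"))["final_subset"]))')" -o model.joblib
dnahotspot predict model.joblib table.tsv -o predictions.tsv
dnahotspot evaluate predictions.tsv -o report.json

# evaluate a bare confusion matrix (TP,FP,TN,FN)
dnahotspot evaluate --counts 19,7,31,7 -o report.json
```

`featurize` expects a protein–DNA complex; chain roles are auto-classified
from residue names and can be overridden with `--protein-chains` /
`--dna-chains`. Feature tables are TSV with key columns
(pdb_id, chain, resnum, icode, resname), the 24 feature columns, and an
optional `label` column (1 = hot spot).

## Layout

- `src/dnahotspot/structure.py` — PDB parsing, chain classification,
  bound/unbound views, interface detection and neighbor lists
- `src/dnahotspot/sasa.py` — Shrake–Rupley SASA, per-residue aggregation,
  relative ASA against a reference max-ASA table
- `src/dnahotspot/features.py` — the 24-feature encoding
- `src/dnahotspot/selection.py` — SVM-RFE + correlation pruning
- `src/dnahotspot/model.py` — RBF-SVM grid search, persistence, prediction
- `src/dnahotspot/metrics.py` — confusion-matrix scalars, ROC, AUC
- `src/dnahotspot/synthetic.py` — fixture generators
- `src/dnahotspot/cli.py` — the `dnahotspot` command
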