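# bcrnet

B cell receptor (BCR) repertoire networks, clonal diversity indices, and
tumor-clone tracking for minimal residual disease (MRD).

After high-dose therapy with autologous stem cell rescue (HDT-ASCR), a
lymphoma patient's B cell compartment is ablated and then rebuilt. How fast
the repertoire re-diversifies — and whether the primary tumor's BCR clone
still lurks in peripheral blood — carries prognostic information. `bcrnet`
implements that analysis for kappa-chain CDR3 clonotype tables (AIRR- or
MiXCR-style exports), for researchers studying immune reconstitution and
relapse risk in B cell malignancies:

- **Clonal networks** — each vertex is a unique CDR3 nucleotide sequence,
  edges join sequences differing by a single nucleotide, and clones
  (clusters) are connected components: lineages related by chains of single
  point mutations. Neighbor search is an exact masked-key hash, near-linear
  in repertoire size.
- **Diversity** — Shannon index H = −Σ pᵢ ln pᵢ (SDI), Gini–Simpson
  D = 1 − Σ pᵢ², and the Gini inequality index
  G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄), at vertex and cluster level, normalized to the
  mean of a healthy-volunteer cohort. ΔSDI = normalized SDI(TP3) −
  normalized SDI(TP2) measures post-transplant recovery.
- **MRD tracking** — primary tumor clusters (≥ 5% of tumor BCR reads) are
  matched into peripheral repertoires by exact Levenshtein distance: LD 0 is
  MRD-positive, LD 1 marks related clones (ongoing clonal evolution), and
  spike-in networks visualize both against the blood repertoire.
- **Relapse discrimination** — Welch t-tests and empirical ROC with
  Youden-index cut-offs on any normalized measure, including ΔSDI.
- **Simulators** — a germinal-center co-culture model (two-phase growth,
  somatic hypermutation, replating, optional suppressive tumor compartment)
  and a patient-timeline generator with planted tumor clones, for
  end-to-end validation against known ground truth.

## Worked example

```python
import bcrnet as b

rep = b.Repertoire("toy", [b.Clonotype("AAA", 5),
                           b.Clonotype("AAT", 2),
                           b.Clonotype("GGG", 7)])
net = b.build_network(rep)
print("vertices:", net.n_vertices, "edges:", net.edges,
      "clusters:", b.cluster_abundances(net))

for level in ("vertex", "cluster"):
    p = b.diversity_profile(rep, net, level=level)
    print("%-7s SDI=%.4f  Gini-Simpson=%.4f  Gini=%.4f"
          % (level, p.shannon, p.gini_simpson, p.gini))
```

```
vertices: 3 edges: [(0, 1)] clusters: [7, 7]
vertex  SDI=0.9923  Gini-Simpson=0.6020  Gini=0.2381
cluster SDI=0.6931  Gini-Simpson=0.5000  Gini=0.0000
```

`AAA` and `AAT` differ by one nucleotide, so they form a single clone of 7
reads next to the unrelated `GGG` clone: cluster-level diversity collapses
to two equal clones (SDI = ln 2 ≈ 0.6931, Gini = 0 for perfect equality).

The same machinery scales to a full cohort. With the bundled synthetic
cohort (17 patients, 8 of whom relapse, and 12 healthy volunteers for
normalization):

```python
c = b.simulate_patient_cohort(seed=1)
report = b.cohort_pipeline(c.records, c.repertoires, c.healthy)
roc = report.roc[("shannon", "vertex", "delta_sdi")]
print("dSDI AUC=%.3f cutoff=%.3f sens=%.2f spec=%.2f"
      % (roc.auc, roc.cutoff, roc.sensitivity, roc.specificity))
```

```
dSDI AUC=0.986 cutoff=0.475 sens=0.89 spec=1.00
```

Patients whose normalized SDI rebounds by more than ≈ 0.47 of the healthy
mean between the post-chemotherapy nadir (TP2) and the 6–8-week
post-transplant sample (TP3) are almost all non-relapse cases.

Tumor tracking against the bundled kappa-chain tumor signatures:

```python
from bcrnet import datasets
sig = b.extract_primary_clusters(datasets.load_tumor_repertoires()["419"])
report = b.match_tumor_clones(sig, peripheral_repertoire)
for m in report.matches:
    print(m.tumor_sequence, "LD", m.distance, m.mrd_positive)
```

The command line mirrors these flows:

```sh
bcrnet simulate-cohort --seed 1 --out cohort/
bcrnet analyze-cohort --cohort cohort/cohort.tsv \
    --repertoire-dir cohort/patients --healthy-dir cohort/healthy \
    --signature-dir cohort/signatures --out results/
bcrnet analyze-sample --input sample.tsv --dialect mixcr --out sample_out/
bcrnet track-tumor --tumor tumor.tsv --peripheral blood_tp3.tsv --out mrd/
```

See `docs/methods.md` for the model details, parameter meanings, and the
limits of what the simulators emulate.

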