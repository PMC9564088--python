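# Methods

## Scope and model

`bcrnet` analyzes B cell receptor (BCR) immune repertoires at the level of
kappa-light-chain CDR3 nucleotide sequences. Its core objects and procedures
are:

**Clonal network.** Every unique CDR3 sequence is a vertex whose mass is the
number of identical reads. Edges join vertices that differ by a single
nucleotide; a *clone* (cluster) is a connected component — cells whose CDR3s
are identical or linked by chains of single point mutations, treated as one
somatic lineage. Two neighbor rules are offered because "single nucleotide
difference" is ambiguous between substitutions and edits:

- `hamming1` (default): equal length, Hamming distance exactly 1. Point
  mutations generated by somatic hypermutation (SHM) are substitutions, so
  this is the default.
- `levenshtein1`: Levenshtein distance exactly 1, i.e. the hamming1 pairs
  plus single-indel pairs.

Neighbor search is a position-masked key hash: for each sequence and each
position, the key is the sequence with that position wildcarded; two unique
equal-length sequences share a key iff they differ exactly at the masked
position. This is expected near-linear in the number of sequences and is
exactly equivalent to brute-force all-pairs distance computation (the test
suite keeps an independent brute-force oracle, and for `levenshtein1` an
independent dynamic-programming edit distance). Internally the buckets are
found by sorting byte-matrix rows with one column zeroed, which is just a
vectorized form of the same hash. Cluster ids are assigned in decreasing
aggregate-count order with lexicographic tie-breaks so all reports are
reproducible. Vertex identity deliberately ignores V/J gene calls: they are
carried as metadata, but the network is defined on the sequence alone.

**Diversity.** Three plug-in estimators over clone frequencies
p_i = x_i / Σx:

- Shannon diversity index (SDI): H = −Σ p_i ln p_i. Natural log by default;
  a `base` argument exists for comparability with log2/log10 conventions.
- Gini–Simpson: D = 1 − Σ p_i², the probability two random reads come from
  different clones.
- Gini index: G = Σ_{i,j} |x_i − x_j| / (2 n² x̄), clone-size inequality,
  computed through the exact sorted-rank identity.

Each is computed at *vertex* level (unique sequences) and *cluster* level
(network clones). No bias-corrected variants, Hill numbers or Chao-type
richness estimators are provided; the plug-in forms are the documented
choice. Patient values are **normalized by dividing by the arithmetic mean
of a healthy-volunteer cohort**, index-by-index and level-by-level. Division
(rather than z-scoring) is used because the downstream dichotomous cut-offs
are naturally expressed as fractions of healthy diversity, near 1. Repertoires
that are empty after chain filtering raise an error instead of contributing a
zero, which would silently skew cohort means.

**Trajectories.** Patients are sampled at four treatment timepoints around
high-dose therapy with autologous stem cell rescue (HDT-ASCR): TP1 before
conditioning, TP2 at the post-chemotherapy nadir, TP3 6–8 weeks after
transplant, TP4 at relapse. ΔSDI = normalized SDI(TP3) − normalized
SDI(TP2): the recovery of repertoire diversity after transplant. A missing
TP2 or TP3 yields a missing-data marker, and the patient is excluded from
ΔSDI group analyses with a warning.

**Tumor tracking (MRD).** From a tumor biopsy repertoire, the *primary
tumor cluster(s)* are the network clusters collectively holding ≥ 5% of
tumor reads (`threshold` configurable; clusters below threshold are retained
but flagged non-primary). Each primary sequence is searched against the
peripheral repertoire by exact Levenshtein distance; ties on distance are
broken lexicographically. MRD positivity requires an exact match (LD = 0);
LD values in 1..`related_max` (default 1) set a *related* flag — evidence of
clonal evolution — without flipping the MRD call. The tumor fraction counts
only exact matches to primary sequences. Edit distances are computed with
edlib's bit-vector algorithm, which is exact (no band limit is set); the
test suite verifies it against a quadratic DP oracle on random pairs and on
the published subclone pair. `spike_in_network` unions the primary tumor
sequences into the peripheral network (absent clones get a nominal count of
1) and labels tumor vertices `tumor_mrd` / `tumor_absent` for plotting with
the Fruchterman–Reingold layout.

**Group discrimination.** Relapse vs non-relapse comparisons use Welch's
unequal-variance t-test (group variances are not assumed equal at n ≤ 9 per
arm) and an empirical ROC. The ROC positive class is *non-relapse*, because
diversity recovers faster in patients who cleared their tumor; with
SDI-type scores the AUC is then ≥ 0.5 whenever that direction holds. AUC is
the trapezoidal area, identical to the Mann–Whitney rank statistic
(property-tested). The reported cut-off maximizes the Youden index
J = sensitivity + specificity − 1, with ties resolved toward higher
sensitivity and then lower threshold, and is reported as the midpoint
between the adjacent distinct scores it separates. No multiple-testing
correction is applied across measures and timepoints; the ROC/t-test grid is
exploratory and should be read as such. No confidence intervals are attached
to AUCs (point estimates only).

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes. They emulate the *shape* of real repertoire data, not its full
biology; passing tests demonstrates that the pipeline recovers planted
structure under the stated generative model, nothing more.

### Germinal-center co-culture (`simulate_coculture`)

A naive B cell pool (default 2000 clones, geometric clone sizes with mean 3,
CDR3 lengths uniform on 27–45 nt, total normalized to exactly 1e5 cells)
expands on a feeder layer:

| parameter | default | meaning |
|---|---|---|
| `growth_phase1` | 1.2/day | days 0–4, IL-4-only priming |
| `growth_phase2` | 2.0/day | days 4–14; makes cumulative fold 1.2⁴·2¹⁰ ≈ 2123 ≥ 2000 at day 14 |
| `growth_late` | 1.1/day | after day 14 |
| `shm_rate` | 0.02/cell/day | probability of emitting a 1-substitution daughter, from day 4 |
| `shm_window` | 8 units | maturation budget of SHM activity |
| `replate_start/every/size` | 8 / 4 / 1e5 | proportional downsampling to 1e5 cells |
| `tumor_seed` | 0 | tumor cells per 1e5 naive (1 → 0.001% day-0 fraction) |
| `tumor_growth` | 2.52/day | calibrated so the tumor fraction rises ~200-fold by day 14 |
| `s_max`, `K` | 0.5, 1e-5 | suppression: factor 1 − s_max·f_T/(f_T+K) |

Suppression multiplies the normal **growth increment** (g − 1) and the SHM
rate, not the factor g itself: a suppressed culture still grows
exponentially, just slower — multiplying g would make it collapse, which is
not what co-cultures show. The half-saturation K = 1e-5 makes even a
0.001% tumor seed produce a large effect, so the dose–response is steepest
between zero and the smallest seed; the mechanism behind such long-range
suppression (paracrine or otherwise) is not modeled, only its functional
form is declared. The tumor compartment emits no BCR reads by default,
modeling a lymphoma line without stable surface BCR expression.

SHM is gated by a *maturation integral*: maturity advances by the
suppression factor each day from day 4, and SHM is active while maturity <
`shm_window`. In an unsuppressed culture maturity hits 8 at day 12 — the
SHM-to-class-switch transition — so vertex-level SDI rises monotonically to
a day-12 plateau. Under suppression maturation is slower, the SHM window
stretches, and peak diversity shifts to day 14 or later while remaining
below the unsuppressed curve. This gating is a modeling device chosen to
reproduce that qualitative timing; it is not claimed as biology.

Two integration modes: `mean_field` propagates expected clone masses
deterministically (daughter vertices are spawned when the day's mutant mass
reaches `spawn_min` = 0.5 cells, and a fresh daughter sequence is preferred
so each SHM event adds a vertex adjacent to its parent; clones below
`prune_min` = 1e-3 cells are dropped at replating). `stochastic` uses
Poisson growth, binomial mutation counts, and multinomial replating.
Sampled repertoires (default days 0, 8, 10, 12, 14, 19 at 20 000 reads) are
multinomial draws from clone masses. Everything is bit-reproducible given
the config seed. The *cumulative fold-expansion* reported per day is the
running product of daily effective growth factors — growth net of
suppression but gross of replating removals, i.e. what a growth curve with
carried-over dilutions would show.

### Patient cohort (`simulate_patient_cohort`)

Seventeen patients (8 relapse / 9 non-relapse, order shuffled per seed) and
12 healthy volunteers. All repertoires draw clone sizes from a lognormal(0,
σ = 1.2) law scaled by 50, with uniform-random CDR3s (distinct subjects'
clones essentially never collide). Healthy volunteers have 5000 clones; TP1
is suppressed (800 clones); TP2 is near-ablated and sequenced at depth 200
reads from 40 clones — emulating samples whose entire mRNA yield barely
suffices for library preparation; TP4 (relapse only) has 600 clones.

TP3 is the single knob separating outcomes. A target normalized SDI is
drawn per patient — mean 1.0 (non-relapse) or 0.6 (relapse), sd 0.15 — and
realized through the novel-clone influx: for iid lognormal sizes,
H ≈ ln N − c where c is the evenness deficit of the size law, so the clone
count N for a target is solved from the *generated* healthy cohort's own
mean SDI and deficit. This self-calibration keeps the normalized scale
honest without hand-tuning. Whether a real diversity deficit reflects fewer
novel clones or skewed clone sizes is not distinguishable here; influx was
chosen as the simplest single mechanism.

Relapse patients carry a planted monoclonal tumor clone from TP1 onward at
a peripheral fraction log-uniform on [3e-5, 0.014] (the clinically observed
range), with a floor of one read so the clone is always detectable in
principle; each also gets a tumor biopsy repertoire (dominant clone 90%,
one Hamming-1 subclone 8%, one unrelated minor clone 2%) from which the
pipeline itself extracts the tumor signature. This enables strict
plant-and-recover checks: MRD must be called positive (LD 0) for every
relapse patient at every timepoint and never for non-relapse patients.

### What the generators do not emulate

Sequencing error, primer/V-gene amplification bias, UMI structure,
selection and affinity maturation within the GC, class-switch
recombination, shared/public clones between subjects, and realistic V/J
usage (V genes are attached only where tests need them). Results on
synthetic data therefore validate the *pipeline machinery* — network
construction, index arithmetic, normalization, matching, ROC — under known
ground truth, not the clinical effect sizes themselves.

## Numerical choices and degenerate inputs

- Tumor-signature fractions become pseudo-counts at scale 1e6, preserving
  printed ratios to ≤ 1e-6 relative error; fractions summing to more than
  1 + 1e-3 are rejected; zero fractions are dropped with a warning.
- Rows with any non-ACGT character are dropped (edges are defined on exact
  nucleotide identity, so ambiguity codes cannot be placed in the network).
- Empty repertoires: `build_network` returns an empty network;
  `diversity_profile` raises; ROC with a single class raises; Welch t with
  zero variance raises and suggests reporting exact equality.
- Sequences longer than 1000 nt are rejected as corrupt input.
- Cluster ids, closest-match ties, and ROC cut-off ties all have
  deterministic lexicographic/threshold tie-breaks.
- Optional multinomial rarefaction to a common depth exists but is off by
  default in every pipeline: at full depth it is the identity.

## Problem sizes

Defaults were chosen so a complete analysis is interactive on one CPU: the
full test suite runs in ~3 minutes and `scripts/acceptance.py` (which
generates and analyzes 20 full cohorts for the ΔSDI AUC) in ~2 minutes.

## Known limitations

- The hamming1/levenshtein1 choice changes cluster granularity for
  repertoires with many indel variants; both are exposed, only one default.
- Plug-in diversity estimators are depth-biased; cross-depth comparisons
  should use the rarefaction option explicitly.
- The suppression and SHM-gating functional forms are declared, not
  mechanistic; parameter values outside the calibrated ranges have no
  claimed meaning.
- MRD sensitivity is bounded by sequencing depth: a clone below ~1 read per
  sample depth cannot be detected, and the generator's one-read floor
  sidesteps rather than models this.
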