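# Methods

This note documents the statistical model behind `footprintnet`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical corner cases.

## Differential layer

Each feature (protein or phosphosite) is tested for a treated-vs-control
difference within one genotype context with a two-sample *t*-test on log2
intensities. The default flavor is the pooled-variance (Student) test;
Welch is available via `flavor="welch"`. The choice of the simplest
unmoderated test is deliberate: with three replicates per arm an
empirical-Bayes variance moderation would change every downstream number
while resting on assumptions the package cannot check, and the test
flavor is the single most downstream-visible knob, so it stays explicit
and configurable rather than hidden. No imputation is performed: a
feature needs at least two non-missing values per arm (complete-case per
feature), otherwise it is excluded and listed, because imputing
log-intensities without a stated missingness mechanism silently biases
fold changes.

Zero-variance features are resolved deterministically rather than left
NaN: no spread and no shift means no evidence against the null (t = 0,
p = 1); no spread with a shift is infinitely confident evidence
(t = ±inf, p = 0). The infinite case only arises in noise-free synthetic
data but must behave sanely because noise-free instances are the
package's strongest correctness probes.

Multiplicity is controlled with Benjamini–Hochberg across retained
features; significance means FDR < 0.1 for differential calls and
FDR < 0.05 for enrichment calls. Phospho matrices are filtered to class I
sites (localization probability ≥ 0.75) before testing, matching the
standard convention for confidently localized phosphosites.

Replicate QC computes pairwise Pearson correlations on pairwise-complete
values and warns for replicate pairs (same genotype and treatment) below
a configurable floor, default 0.75 — the low end of what a clean
(phospho)proteomic triplicate typically achieves; pairs with fewer than
two overlapping values are reported as undefined rather than silently
skipped.

Hierarchical clustering of significant features uses 1 − Pearson
distance on row-z-scored profiles with average linkage, cut into k = 4
clusters by default. Distance and linkage are the common proteomics
defaults and both are parameters. Features are processed in
lexicographic order and clusters renumbered by first appearance so the
assignment is reproducible; flat (zero-variance) profiles get z = 0 and
thus maximal distance 1 to everything, a deliberate "uninformative"
placement.

## Footprint activity inference

A regulator's regulon is a set of signed targets; the stored sign is the
expected direction of the target's change when the regulator is active.
This convention holds for phosphatases exactly as for kinases — the sign
already encodes the dephosphorylation direction, so no hidden class-based
sign flip exists anywhere downstream.

The footprint score of regulator R is

    score(R) = (1/n) Σᵢ sᵢ · tᵢ

over R's measured targets, where tᵢ is the target's t-statistic. The
statistic is linear by design (doubling every t doubles every score),
which makes it analyzable and lets tiny instances be checked against
exhaustive enumeration. Significance comes from a permutation null: the
same statistic on random draws of n measured features (without
replacement), two-sided p from the empirical distribution with the
+1/(B+1) correction, then BH across regulators. Each regulator gets an
independent null (sampled by vectorized rejection sampling when regulons
are small relative to the feature pool); sharing nulls between
same-shaped regulons would be faster but correlates their p-values and
visibly distorts the null calibration. An `exact=True` mode enumerates
all ordered arrangements instead, feasible only for toy problems, and is
what the enumeration oracle tests exercise. `n_perm` below 100 is
rejected outright because the resulting p-grid is too coarse to be
meaningful; the default is 1000. `min_targets` defaults to 3 — with
fewer measured targets the mean is dominated by single-site noise — but
is configurable down to 2 so that small phosphatase regulons survive in
sparse data.

Kinase and phosphatase regulons are evaluated against the phospho-layer
differential table, TF regulons against the proteome layer, mirroring
where each regulator's footprint physically appears.

Infinite t-statistics entering the footprint are clipped to
(max finite |t| + 1): they carry the strongest possible evidence but must
not turn scores or null moments into NaN/inf.

The phospho-score is the mean of (log2FC × annotated effect) over a
protein's measured regulatory sites, by default only significant ones —
an activating site going up or an inhibiting site going down both argue
for activation. It has no permutation p (typically 1–2 sites per
protein); it serves as orthogonal evidence. Combination policy: one
method's coverage is kept as-is; sign agreement upgrades to
`method="combined"` carrying the footprint score and p; sign conflicts
drop the protein and are logged. Dropping is the conservative resolution
— the package has no principled way to arbitrate between the two
evidence classes, and a wrong sign would poison the causal model built
next. Proteins of class "other" can only enter via the phospho-score,
since they have no regulon.

## Mechanistic models

The prior network is a signed directed multigraph; a duplicated
interaction with conflicting literature signs is kept as two parallel
edges, and a path commits to one of them. Phenotype nodes are sinks.

Model construction has two stages. First the *naive* network: the
induced subgraph on proteins with nonzero inferred sign, keeping an edge
(u, v, s) only when sign(u)·s = sign(v) — the interaction can explain the
observed activity pattern. Second, phenotype contextualization: simple
directed paths of at most `max_len` edges (default 4) are enumerated
from each scored protein through the full prior (unscored intermediates
allowed — the prior may route signal through proteins the data did not
score), and a path is kept iff the propagated sign matches every scored
node it passes and the source sign times the edge-sign product equals
the requested phenotype direction. The model is the union of kept paths
plus the naive edges among retained nodes. `max_len` = 4 keeps path
enumeration tractable at desk scale and reflects how shallow curated
signaling paths typically are; raising it can only add nodes
(monotonicity is a tested invariant). Self-loops are ignored during the
search: they only create trivial sign-flipping cycles.

A validator asserts every structural invariant of an emitted model —
phenotype is a sink, every scored-scored edge is sign-consistent, every
node lies on a kept path, every path is simple, respects scored signs
and matches the direction — and the pipeline refuses to write a model
that fails it. The phenotype direction is an explicit config input
(+1 for a damage-inducing treatment) rather than an inferred quantity.

Functional circuits restrict the model to paths whose *source* lies in a
chosen gene set while retaining all model edges among the surviving
nodes, so extracting with the full source set is the identity.

## Enrichment and phenotype arithmetic

ORA uses the one-sided hypergeometric upper tail on counts intersected
with a universe of *measured* features (never the whole genome — an
unmeasured gene had no chance to enter the query), BH adjustment across
sets, and reports an enrichment score of −log10(adjusted p); the
conventional reporting thresholds are adjusted p < 0.05 and score > 3
(i.e. adjusted p < 10⁻³). Kinase-substrate set enrichment is the same
machinery with each regulator's target-site set as a gene set, the
direction-restricted significant sites as the query, and all measured
class I sites as the universe.

The two phenotype formulas are exact arithmetic:
relative apoptosis = 100·(dead_treated − dead_control)/viable_control,
and Bliss excess = f_ab − (f_a + f_b − f_a·f_b), positive for synergy.
Bliss independence is used as the additivity null because it is the
standard parameter-free choice for kill fractions.

## Synthetic data: what it emulates, what it does not

The generator emulates the target study design: two genotype contexts ×
(control, treated) × n replicates (default 3); a random signed prior
(mean out-degree 3, 25% inhibitory edges, class proportions kinase 0.35
/ phosphatase 0.05 / TF 0.15 / other 0.45, echoing the realistic
dominance of kinases among regulon-bearing entities and the rarity of
phosphatases) with a single phenotype sink `DNA_damage`; globally unique
substrate sites per regulator (S/T/Y drawn 0.80/0.15/0.05); 0–2
regulatory self-sites per protein; and log2 baselines at 25 ± 2, the
scale of MS intensities.

The generative shift model is linear and additive: an active regulator
with signed activity a adds a·sign to each regulon target, a to its own
protein abundance, and a·effect to each of its own regulatory sites (the
last rule is what makes the phospho-score stream recoverable on
synthetic data: an activated kinase's activating site is itself
phosphorylated). Everything else has expectation zero, and every
measurement adds iid Gaussian noise (default sd 0.25 — a calibration
choice in the plausible range for replicate scatter of log2 MS data, not
a claim about any real dataset). A Bernoulli fraction of sites (default
0.1) receives a localization probability below 0.75 to exercise the
class I filter.

Deliberately **not** emulated: intensity-dependent missingness (MNAR),
batch effects, peptide-level quantification, shared substrates between
regulators, feedback dynamics, or nonlinear saturation. Passing the
recovery benchmarks therefore demonstrates correctness of the inference
machinery under the stated generative model — not performance on real
spectra, where missingness and regulon overlap will degrade both recall
and precision.

The reference benchmark (`standard_benchmark`) fixes the conditions used
throughout the tests and the acceptance script: 200-node prior, 20
regulon-bearing kinase/phosphatase regulators, 8 active at |activity|
1.5 with 5 substrate sites each, 3 replicates, noise sd 0.25. At these
settings a planted regulator's per-site t-statistic is ≈ 7, so footprint
inference is expected to recover essentially all active signs at
FDR < 0.1; with noise 0 recovery is exact by construction. The
calibration check uses a 2000-regulator, zero-active-regulator instance;
problem sizes were chosen so the whole suite runs comfortably on a
laptop-class single core.

## Determinism

All randomness flows from one root seed: the pipeline derives per-stage
seeds from it, generators take explicit seeds, and every writer emits
rows in lexicographic order, so identical config + inputs + seed
reproduce every TSV/JSON/SIF/GraphML byte for byte. Ties in clustering
and ordering are broken lexicographically by feature/node ID.

## Known limitations

- Identifier namespaces are opaque strings; consistency across matrices,
  regulons and network is required (and checked) but no gene-symbol /
  UniProt mapping is attempted.
- The phospho-score carries no p-value, so combined activities inherit
  the footprint p only.
- Path enumeration is exhaustive up to `max_len`; very dense priors with
  long limits will blow up combinatorially (no ILP-style pruning is
  implemented, by scope).
- "Other"-class proteins are scored only through regulatory sites; no
  network propagation of activity is attempted.
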