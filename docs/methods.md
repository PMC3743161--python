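# Methods

`binqsar` implements a binary (classification) QSAR workflow for
lipophilic GABA-uptake inhibitors of the tiagabine class: compounds are
labelled active/inactive on the pIC50 scale, described by 2D descriptors,
screened univariately, and classified by a Bayesian model over
decorrelated, smoothed class-conditional descriptor densities. This note
records the model, the conventions frozen where a published definition
does not exist, and what the synthetic data can and cannot show.

## Activity labelling

Activity is handled as pIC50 = −log10(IC50 [M]); the default decision
threshold is 7.0, i.e. 100 nM. A compound is *active* iff pIC50 ≥ 7.0 and
the measurement is not censored. "Larger-than" IC50 measurements are kept
with `censored=True` and the bound stored as the pIC50; they are inactive
at any threshold at or above the bound, and labelling at a threshold
*below* the bound raises an error rather than guessing — the data only
say the compound is weaker than the bound. Input IC50 columns in
nanomolar are converted with pIC50 = 9 − log10(IC50 [nM]); the nM
convention is an assumption documented in the CSV header contract.

## Descriptors

All descriptors are conformation-free (2D). Counts (`a_count`, `b_count`,
`b_single`) include implicit hydrogens as atoms/single bonds; aromatic
bonds count as bonds but not as single bonds. Rotatable bonds are acyclic
order-1 bonds between heavy atoms that each have ≥ 2 heavy neighbours;
`b_1rotN` additionally excludes amide C–N bonds (the classic
rotatable-*single*-bond rule), so `b_1rotN ≤ b_rotN`. Fractions divide by
the number of heavy–heavy bonds (0 when none). Rigid bonds
(`opr_brigid`) are non-terminal heavy–heavy bonds that are in a ring, of
order > 1, or amide C–N — one concrete reading of the rigid-bond concept,
flagged as an approximation. The Wiener polarity number is the count of
heavy-atom pairs at topological distance exactly 3 in the
hydrogen-suppressed graph; hydrogens never contribute.

PEOE partial charges (partial equalisation of orbital electronegativities)
are computed by RDKit's Gasteiger implementation on the hydrogen-explicit
molecule — damping 0.5 per iteration, iteration count configurable
(default 6). Charges sum to the molecular formal charge to 1e-6;
unparameterised elements raise an error naming the element.

The approximate van der Waals surface assigns every atom (hydrogens
included) the area of its vdW sphere minus the spherical caps buried by
bonded neighbours, with ideal bond lengths taken as the sum of covalent
radii clamped to the geometrically admissible range; `vdw_area` is the
sum of contributions. The 32 binned VSA descriptors sum these per-atom
contributions into bins of an atomic property:

* `SlogP_VSA0..9` — 10 bins over the Crippen atomic logP contribution
  (interior edges −0.4, −0.2, 0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4);
* `SMR_VSA0..7` — 8 bins over the Crippen molar-refractivity contribution
  (edges 0.11, 0.26, 0.35, 0.39, 0.44, 0.485, 0.56);
* `PEOE_VSA0..13` — 14 bins over the partial charge, edges −0.30 … +0.30
  in steps of 0.05 with open outer bins.

Because every atom lands in exactly one bin of each family, each family
sums to `vdw_area` exactly — a partition property the tests verify to
1e-6 relative on 500 random molecules. `PEOE_VSA_FPPOS` is the surface
fraction on atoms with charge ≥ +0.20. These definitions are
self-consistent and structurally faithful (names, counts, partitions);
no numeric parity with any proprietary descriptor implementation is
claimed or needed for the statistical conclusions.

Three indicator variables flag the amino-acid head group: R-nipecotic
acid, S-nipecotic acid (piperidine-3-carboxylic acid, CIP label at C3
deciding R vs S) and guvacine (the 1,2,5,6-tetrahydropyridine analogue).
The carboxylic acid (or carboxylate) must sit directly on the ring —
esters do not match. A nipecotic core with *unspecified* C3 stereo raises
an explicit error instead of silently scoring 0, because the R/S
distinction is exactly what the indicator encodes. At most one indicator
can be 1 (the guvacine C3 is sp2, the nipecotic C3 sp3).

The 16-descriptor physicochemical block has no canonical composition; a
documented default list of standard RDKit physicochemical descriptors is
shipped and the block is configurable. It participates in no headline
result.

## Contingency screening

Each descriptor is cut into equal-frequency bins (default 10; duplicate
quantile edges collapse) and crossed with the class label. Four
statistics are computed from the bin × class table: contingency
coefficient C = sqrt(χ²/(χ²+n)), Cramér's V = sqrt(χ²/(n·(min(r,c)−1))),
uncertainty coefficient U = I(X;Y)/H(Y), and R² — the squared Pearson
correlation of the *raw* values with the 0/1 label. The combined relative
importance is their unweighted mean; the combiner is pluggable because no
single convention exists. The default selection threshold is 0.2. No
Yates correction is applied (large-sample use). Note the chi-square-based
C and V have a small positive expectation under independence (≈ 0.09
each at n = 1000 with 10 bins), so null importances sit near 0.05, not 0.

## The binary QSAR classifier

Training columns are standardised (training statistics only; constant
and near-constant columns dropped with a warning), decorrelated by the
eigenvectors of the correlation matrix, and the component scores scaled
to unit variance (division by sqrt(eigenvalue)), so one bandwidth
heuristic serves all components. Components are dropped below an
eigenvalue-ratio condition limit (default 1e-6 of the largest) or beyond
an optional component limit.

For each retained component and class, the class-conditional density is

    f(u | class) = (1 − smooth) · KDE_class(u) + smooth · Uniform(S)

with Gaussian kernels at the class's training scores, Silverman bandwidth
h = 0.9·min(sd, iqr/1.34)·n^(−1/5) floored at 1e-3, and S the pooled
training-score range padded by three bandwidths, *shared between the
classes*. Sharing S is what makes `smooth` a clean bias-to-prior dial:
at smooth = 1 the densities cancel and the posterior equals the empirical
prior; at the default 0.01 the data dominate while the uniform floor
keeps every probability strictly inside (0, 1). The posterior

    Pr(active | x) = π₁ ∏ f_j(u_j|1) / (π₁ ∏ f_j(u_j|1) + π₀ ∏ f_j(u_j|0))

is evaluated in log space (stable to ≥ 500 columns). Component scores
outside S evaluate at the boundary, so extrapolated compounds degrade
gracefully toward the prior instead of being decided by kernel tails.
Classification is active iff the posterior ≥ the decision threshold
(default 0.5; ties classify active).

Defaults: smooth 0.01, condition limit 1e-6, no component limit,
threshold 0.5. The kernel-plus-uniform mixture is this package's frozen
reading of "binned Bayesian" class-conditional density estimation; it
reproduces the required limiting behaviours and is fully testable.

## Splitting

*Diversity split.* MACCS keys (166 public substructure bits) with
Tanimoto similarity |a∧b|/|a∨b| (1.0 for two empty vectors, a documented
convention). Clustering is sphere-exclusion (leader) clustering at a 0.75
similarity threshold: centers are picked in descending order of
unassigned-neighbour count (ties → lowest input index) and absorb all
unassigned neighbours — deterministic for a fixed input order. Each
cluster of ≥ 5 members sends max(1, round(0.1·size)) compounds (half-up)
to the test set, apportioned between the classes by largest remainder
(equal remainders favour the active class, which reproduces the
1 active + 1 inactive outcome for a 5:15 cluster of 20) and picked
lowest-index-first; smaller clusters go entirely to training.

*Random split.* Exactly 6 actives and 10 inactives (16 compounds, ~10%
of a 162-compound library) drawn uniformly without replacement,
reproducible from a seed; ten repeats with seeds 1–10 are the default
scheme, reported as mean ± SD. The test-set size is primary and the
training set is the complement (146 of 162).

## Validation

Metrics from the confusion matrix with active as the positive class:
A (overall accuracy), A1 (sensitivity), A0 (specificity), PPP/NPP
(predictive power) and MCC. Undefined ratios (zero denominator) are
reported as NaN and MCC is 0 by convention when any denominator factor
is 0 — needed for all-one-class predictions in permutation tests.
Percentages are full precision internally and rounded half-up to one
decimal only at the reporting layer. LOO cross-validation refits the
model n times, pooling the held-out predictions into one confusion
matrix (XA/XA0/XA1).

A known LOO artifact: with empirical class priors and no real signal,
removing a compound tips the fold prior *away* from that compound's
class, so the LOO null is pessimistically (negatively) biased — at n = 40
in one dimension a single permuted run can reach MCC = −1. The
permutation tests therefore bound the mean and the positive tail of the
null, not the per-run magnitude at small n; at n = 300 with ≥ 10
descriptors the likelihood term dominates the prior shift and |mean MCC|
stays below 0.1 over 50 permutations.

## Synthetic data

Two generators make the pipeline testable end to end without any
measured dataset.

*Descriptor tables* draw informative columns from N(effect, 1) for
actives vs N(0, 1) for inactives and noise columns from N(0, 1) for both;
defaults mirror a 57 active : 105 inactive library.

*Compound libraries* assemble tiagabine analogs from a scaffold
(R-nipecotic 0.45 / S-nipecotic 0.15 / guvacine 0.40 — S-configured
compounds are underrepresented, as in real collections of this series),
an N-linked aliphatic linker of 2–7 heavy atoms, and a diaryl tail
(plain methine, vinyl ether or oxime ether; 40% chance of an
ortho-methyl). Synthetic pIC50 = 6.0 + 0.8·[linker ∈ {4,5}] +
0.4·[ortho] + 0.5·[R-config] + 0.4·[polar head] + N(0, 0.3) — an additive
rule encoding the known qualitative SAR of the series (optimal linker
length, beneficial ortho substitution and linker polarity, R > guvacine >
S head-group order), with coefficients chosen so roughly 35% of a random
162-member library is active at 7.0. `benchmark_dataset` regenerates the
library with derived seeds until exactly 57 of 162 compounds are active
(rejection resampling keeps pIC50 consistent with structure, unlike label
flipping).

What passing tests on this fixture show: the descriptors carry the
encoded SAR, the screen ranks informative descriptors above noise, the
classifier recovers the signal (LOO MCC ≥ 0.4) and the splits behave as
specified. What they do not show: performance on measured inhibition
data, with its assay noise, activity cliffs, correlated scaffold series
and censoring patterns — the generator's additive, independent-feature
world is deliberately simpler than real SAR landscapes.

## Numerical choices and limitations

* Near-constant columns (std ≤ 1e-12 + 1e-9·|mean|) are treated as
  constant; they carry no signal and destabilise the correlation
  eigendecomposition.
* KDE bandwidth floor 1e-3 guards zero-spread class samples (e.g.
  duplicated scores); the uniform support padding (3 bandwidths) keeps
  boundary kernels essentially fully integrated, so each mixture
  integrates to 1 to ~1e-4 by quadrature.
* LOO folds of a 4-compound dataset contain 3 compounds; the fitting
  routine accepts this only for internal folds, the public minimum stays
  at 4.
* Model JSON is schema-versioned; round-trips reproduce probabilities
  bit-exactly.
* The univariate screen ignores descriptor redundancy by design
  (`b_rotN`/`b_1rotN` often tie); redundancy-aware selection is out of
  scope.
* Problem sizes in the test suite (500-molecule descriptor sweeps,
  200 random graphs, 50 × 300 LOO permutations, the 162-compound
  fixture) were chosen to estimate each property's statistic well inside
  its asserted bound.
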