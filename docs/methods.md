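# Methods notes

This note records the models, conventions and design choices behind
`cliffscout`, including every place where a convention had to be fixed
for reproducibility and where the design was genuinely open.

## Potency scale and curation

All potencies are handled as pKi = −log₁₀(Ki in mol/L); nanomolar input
is converted as pKi = 9 − log₁₀(Ki[nM]).  Equilibrium constants (Ki,
optionally Kd) are preferred over assay-dependent readouts; the allowed
measurement types are a curation parameter (default {Ki}).

Replicates for one compound/target are aggregated by the arithmetic
mean of pKi (equivalently the geometric mean of Ki).  Compounds whose
replicates span more than `spread_limit` (default 1.0 log unit) are
dropped — with literature-aggregated data, disagreement beyond one
order of magnitude usually indicates incompatible assays rather than
noise.  Both rules are deliberate package conventions: published
curation protocols for "high-confidence" activity data differ in
detail, so ours is explicit and configurable.  Every input record ends
up either in a class or in the curation log with a reason code
(`smiles_error`, `measurement_type`, `replicate_spread`,
`class_too_small`, `duplicate_id`, `no_usable_measurement`).

Structures are standardized to the largest organic fragment with
charges neutralized where unambiguous; pair matching requires a single
parent structure.  The default minimum class size is 100 compounds,
matching large-scale cliff surveys; desk-scale analyses and the test
suite lower it explicitly.

## Similarity criteria

*Fingerprints.*  MACCS structural keys (166 bits) and the
extended-connectivity fingerprint with bond diameter 4 (Morgan radius
2).  The circular fingerprint is kept as a sparse feature set; folding
to 2048 bits is available for interoperability but changes Tanimoto
values, so it is never the default.  Qualifying-pair thresholds are
Tc > 0.85 (MACCS) and Tc > 0.55 (ECFP4), applied strictly ("exceeding"
read literally); whether the boundary itself qualifies is convention —
we chose the strict reading and expose the thresholds.  Molecules with
empty fingerprints cannot be meaningfully compared and are excluded
from pairing with a warning.

*Matched pairs.*  Fragmentation severs acyclic single bonds between
heavy atoms: every single cut (k=1) and every simultaneous double cut
(k=2).  For k=1 the larger piece is the core; the swapped orientation
is also emitted whenever it passes the core/substituent size rule, so
equal-sized halves are not lost to an arbitrary orientation.  For k=2
exactly one piece carries both attachment points and is the core; its
two attachment labels are canonicalized by generating both numberings
and keeping the lexicographically smaller core SMILES, which prevents
site-swap duplicates of dual-site pairs.

Size restrictions confine pairs to recognizable analogs: exchanged
substituent ≤ 13 heavy atoms, core ≥ 2× the heavy atoms of the larger
exchanged substituent, exchanged substituent size difference ≤ 8.  The
exact numeric limits in the literature vary; these defaults are the
package's own and all three are configurable.  A pair is reported once
per site count with its largest-core representative.  Pair discovery
uses a hash index on canonical core SMILES (linear in fragmentations);
a quadratic brute-force all-pairs matcher is retained as an independent
oracle and the two are asserted equal in the test suite.

*Retrosynthetic rules.*  The RMMP rule set is stored as editable SMARTS
(atom maps 1/2 mark the cut bond): amide C–N, ester C–O, sulfonamide
S–N, aromatic C–O/N ether/amine, biaryl c–c, benzylic C(sp3)–c.
Published retrosynthetic fragmentation schemes are longer; this list
covers the bond classes that dominate analog series and can be replaced
wholesale from a YAML file.  Retrosynthetic cuts are a subset of
all-bond cuts by construction, which is what makes the G2 ⊆ G3
hierarchy provable.

*Hydrogen substituents.*  A cut exposing a bare hydrogen (substituent
`[H]`) makes H→CH₃ transformations detectable.  It is implemented but
off by default — enumerating one extra fragmentation per hydrogen-
bearing atom roughly doubles the index for a transformation class that
standard single-bond enumeration does not claim — and is switched on
per run (`PairConfig.include_hydrogen_substituents`).

*Special categories.*  Iso-cliff detection uses molecular-formula
equality plus a shared-core test (same hydrogen-capped core skeleton,
different attachment position, identical substituent) rather than
graph-edit distance — an implementation choice that reuses the
fragmentation machinery.  Chirality cliffs require identical
stereo-stripped structures, all stereocenters assigned, and exactly one
center of opposite configuration; unassigned centers disqualify a pair
as ambiguous.  Privileged-substructure flagging requires a supplied
SMARTS pattern to match **both** cliff compounds (the substructure as
shared context); no pattern catalog is built in.  Consensus cliffs are
the intersection of cliff sets by (target, unordered compound pair),
independent of the criterion that produced each set.

## Potency-difference thresholds

Constant mode: ΔpKi ≥ threshold with default 2.0 (100-fold).  The
comparison is inclusive (≥) throughout.

Class-dependent mode follows a two-step procedure.  First the class
potency distribution is categorized by its interquartile range — CAT1
(IQR < 1) classes lack the potency spread for meaningful cliffs and
are excluded; CAT2 (1 ≤ IQR < 2) and CAT3 (IQR ≥ 2) proceed.  Then the
threshold is the mean plus two standard deviations of the class's
single-site analog-pair |ΔpKi| distribution.  Conventions the source
procedure leaves open are fixed here: quartiles by linear interpolation
(the "type 7" estimator, numpy's default) and the sample (n−1) standard
deviation.  With fewer than `min_pairs` (default 10) analog pairs the
estimate is unstable and the profile falls back to the constant mode
with a logged warning.

Note that for a distribution truncated at zero the mean+2σ estimator
targets the truncated distribution's own moments: simulating
differences from a Normal(0.5, 0.45) truncated at 0 yields thresholds
concentrated near 1.34, slightly below the untruncated μ+2σ = 1.4.
The acceptance suite accounts for this explicitly.

## Generations and detection

- G1: fingerprint or MMP qualifying pairs, constant threshold.
- G2: retrosynthetic single-site pairs, class-dependent threshold;
  CAT1 classes return no cliffs (logged).
- G3: analog pairs with k ≤ 2 cuts under the same rule set and
  threshold profile as G2, so every G2 cliff is a G3 cliff; `n_sites`
  distinguishes ss- (1) from ds- (2) cliffs.

Each emitted cliff stores the potency-ordered pair, its criterion,
generation, site count, flags and (for substructure criteria) the
underlying matched pair, so downstream analyses never re-derive the
match.  Compounds appearing in several activity classes are analyzed
independently per class.

## Networks

Nodes are cliff-forming compounds, edges are cliffs; networks are
per-target unless explicitly unioned (edges then keep target labels).
Components with exactly one edge are isolated cliffs; two or more edges
make a coordinated cluster.  Hubs are nodes with degree ≥ `min_degree`
(default 3 — no canonical cutoff exists, so it is a parameter).  Node
roles (highly potent / weakly potent / both) derive from edge
orientation.  Exports: TSV edge list and GraphML with node (pKi, role)
and edge (ΔpKi, generation) attributes; no layout or interactive
visualization.

## Dual-site decomposition

For a ds-cliff with core C and exchanged substituents (h₁, h₂) on the
potent and (l₁, l₂) on the weak compound, the single-site analogs are
C(h₁, l₂) and C(l₁, h₂) — each introduces one substitution into the
weak compound's background.  They are located by reassembling the
fragment SMILES and matching canonical structures within the class;
absent analogs (or analogs without a potency) leave the effect
undetermined.  With δᵢ the signed pKi change of substitution i alone
and Δ the cliff's difference, the effect is classified with an
indifference band ε (default 0.3 pKi, a typical inter-assay noise
scale):

1. **redundant** — max(δ) ≥ threshold, |Δ − max(δ)| ≤ ε and the other
   δ within ±ε (one substitution accounts for the whole cliff);
2. **additive** — |δ₁ + δ₂ − Δ| ≤ ε;
3. **synergistic** — Δ > δ₁ + δ₂ + ε;
4. **compensatory** — Δ < max(δ) − ε;
5. otherwise undetermined.

The quantitative boundaries of these four categories are not fixed in
the literature; this ε-band formalization, the rule order, and the
requirement in rule 1 that the dominant substitution also account for
the total (without which a large-δ/inert-δ compensatory case would be
mislabeled redundant) are the package's own, and ε is fully
configurable.  On a noise-free additive potency model every complete
quartet classifies additive; the classification is symmetric under
site relabeling.

## Synthetic data generator

The generator emulates curated activity classes: analog series built
from shared scaffolds, clustered potencies, a few steep SAR jumps.
Potency follows `pKi = base + Σ contribution(substituentᵢ) +
interaction + N(0, noise_sd)`; an additive model was chosen because it
makes every planted ΔpKi analytic.  Key design points:

- **Bimodal contributions.**  Background substituents draw their
  contribution from a low (0–0.3) or high (1.5–1.8 pKi) cluster.  The
  resulting class IQR is ≈ 1.5 (CAT2, eligible for class-dependent
  analysis) while the largest background analog-pair difference is
  bounded at 1.8 — safely below the realized mean+2σ threshold
  (≈ 2.4–2.6).  A unimodal spread wide enough for CAT2 would
  necessarily push its own tail pairs over the mean+2σ line, making
  exact recovery impossible by construction.
- **Planted cliffs on dedicated scaffolds.**  Reserved cliff
  substituents contribute +5.0 (single-site) or +2.5 per site
  (dual-site) against low-cluster partners, so planted differences
  start at 4.4 pKi.  Scaffolds are mutually dissimilar ring/linker
  combinations and substituents are capped at 4 heavy atoms, so the
  core-dominance size restriction excludes any cross-scaffold match.
- **Quartets.**  For multi-site analysis, scaffolds carry complete
  four-compound structures sharing the high compound; an explicit
  pairwise `interaction_pki` term injects synergy or compensation.
- **Noise.**  Defaults are noise-free because the recovery guarantees
  are exact; `noise_sd` is available for robustness experiments.  The
  exact-recovery presets (including the 5% benchmark, where 39 planted
  pairs among C(40,2) = 780 qualifying pairs give exactly 5.0%) keep
  noise at zero since their documented guarantee is exactness and the
  designed margin between background (1.8) and threshold (2.0) cannot
  absorb measurement error.
- One seeded NumPy generator per run; identical configurations produce
  byte-identical output.

What passing these tests does **not** show: real compound classes have
correlated substituent effects, heteroscedastic assay noise, uneven
series sizes and scaffold hopping; the generator makes no claim of
structural realism (and none of sampling realistic chemistry).  The
planted-recovery results validate the machinery, not any statement
about cliff rates in real databases.

## Problem sizes and numerics

The shipped study conditions are desk-scale by design: 120-compound
recovery classes, a 200-molecule (≤ 15 heavy atoms) pair-finding oracle
comparison, 20 × 1000 simulated differences for threshold estimation.
Fragment SMILES are RDKit-canonical throughout; all set comparisons use
canonical forms, pair identities are unordered, and every ordering in
output tables is deterministic.  Degenerate inputs are defined
behavior: empty cliff lists give empty networks, classes with < 4
potencies raise on IQR estimation, zero qualifying pairs report missing
percentages, and two empty fingerprints raise rather than return 0/0.

## Known limitations

- Only 2D (molecular-graph) cliffs: no 3D/binding-mode, interaction or
  promiscuity cliffs, and no cliff prediction models.
- Analog pairs stop at two substitution sites (dual-site cliffs
  dominate multi-site cliffs in practice; triple cuts are out of scope).
- The retrosynthetic rule list is minimal; users with a preferred
  published rule set should supply it as SMARTS.
- Iso-cliff detection requires the shared substituent to be separable
  by a single cut, so ring-fused positional isomerism is not covered.
- Thresholds assume enough analog pairs per class; sparsely populated
  targets silently fall back to the constant criterion (logged).
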