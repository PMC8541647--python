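# Methods

## Scoring model

The unit of comparison is the monomer. Structure-side monomers are
`(a, m, e)` with residue `a ∈ Ā = A ∪ {⌀}`, methylation
`m ∈ {−1, +1}` and stereo `e ∈ {−1, 0, +1}`; gene-side monomers add a
specificity score `s ∈ [0..100]`. `⌀` pools all residues outside the
supported alphabet; because many distinct unsupported residues exist,
`⌀` never matches `⌀`.

A compound–cluster pair is scored as a log-odds ratio between the
probability that the cluster's assembly line synthesized the peptide as
laid out in a global alignment and the probability of the peptide under
a null "cluster" of undefined modules `M̄ = (0, ⌀, 0, 0)` of the same
length as the peptide. Aligned columns are independent and factor into
residue, methylation and stereo components.

Residue component: on a literal residue match,
`P = PmatchA(level(s))`; on a mismatch,
`P = (1 − PmatchA(level(s))) · PA(a_nrp) / (1 − PA(a_bgc))`, i.e. the
background frequency of the observed residue renormalized over the
residues other than the predicted one. `PmatchA` depends on the
specificity level only, not on the residue identity — a deliberate
simplification that keeps the parameter count proportional to the
number of levels rather than to `|Ā|²`. With `PmatchA(0) = 0` by
convention, the null residue term reduces to
`PA(a) / (1 − PA(⌀))`.

Modification components: equal non-zero flags cost `Pmatch(x)`,
opposite flags `Pmismatch(x)` (both keyed by the structure-side value
`x`), and an undefined gene-side flag falls back to the background
`PM(x)` / `PE(x)`. An undetermined structure-side stereo flag is
uninformative regardless of the prediction, so its probability is
defined as 1 and contributes exactly 0 to the log score.

Indels can only appear in the alternative hypothesis (the null is
defined gap-free at the peptide's length). An insertion — a peptide
monomer no module accounts for — costs
`Pinsertion · PA(a) · PM(m) · PE(e)` (with the `e = 0` convention
above), so its *net* contribution after null subtraction is the
monomer-independent constant `log(Pinsertion · (1 − PA(⌀)))`; this
algebraic identity is asserted numerically in the tests. A deletion — a
skipped module — costs a uniform `Pdeletion`.

The optimal global alignment is found with Needleman–Wunsch. The null
term does not depend on the alignment, so maximizing the summed column
log-probabilities maximizes the score. Logs are natural throughout; the
default reporting threshold (6.0) is calibrated in the same base. The
gap model is linear per column, exactly as the formulas imply — no
affine extension. Traceback ties prefer match/mismatch over deletion
over insertion, which is deterministic and biologically favors module
usage over gaps. All probabilities are clamped to ≥ 1e−9 before taking
logs so zero frequencies from small training sets cannot produce
infinite scores.

## Linearization of monomer graphs

Bond labels fall into a backbone class (amide, double-amide, and the
thiazole / oxazole / pyrimidine heterocycles — bonds core NRPS modules
create) and a tailoring class (everything else, unknown labels
included). Tailoring bonds are removed; each weakly connected backbone
component with at least `min_supported` (default 2) supported monomers
is traversed along directed Hamiltonian paths found by exhaustive
backtracking (node cap 20, per-component candidate cap 100 — monomer
graphs are small, so the exhaustive search is cheap). A simple directed
path therefore yields one candidate; a directed cycle yields one
candidate per ring-opening position. All found paths are retained
rather than one, since the best candidate is selected later by score.
Components that admit no Hamiltonian path are dropped with a warning
rather than failing the compound.

Edge direction is honored strictly (source→target); reversed traversal
is not attempted. If the backbone is acyclic and has at most three
retained components, all permutations of the components are emitted as
additional candidates (supporting non-collinear assembly lines) and
each component is always also emitted alone (supporting short iterative
products). A cyclic component among several suppresses the permutation
step but not the singletons.

## Assembly-line reconstruction

Each typical module (one A domain) becomes one monomer: the residue
with the highest mean of its Stachelhaus and SVM scores wins (first
listed wins ties), the specificity is that mean rounded half-up (for
cross-platform determinism), methylation follows the M domain, and the
stereo flag is D when the module has an E domain or the *next* module
has a dual C/E domain. Predicted residues outside the alphabet are
mapped through an optional synonym table, else the monomer is demoted
to the undefined monomer rather than inventing a residue.

Deficient modules generate strip variants: an A-less module may stutter
(reuse the previous typical module's A domain), giving variants where
that monomer occurs 1..3 times in total — the unexpanded strip counts
as the one-copy variant; a trailing sole-PCP module signals iterative
reuse of the whole gene, giving 1..3 whole-strip repeats. Multiple
deficient modules in one gene expand multiplicatively and
independently. Module order within a strip is never permuted.

Over-merged clusters are split first at inter-gene gaps larger than
10,000 nt (gap = next start − previous end − 1, 1-based inclusive
coordinates), then immediately before non-first CS-bearing genes and
after non-last TE-bearing genes; when a CS/TE cut fires, the uncut
piece is retained too, flagged, because an out-of-place CS/TE can also
mean a non-collinear assembly line. Genes on the minus strand are taken
in their annotated module order (annotation order = translation order);
no re-orientation is applied.

Strip ordering: a sequence of strips is consistent iff (i) any CS strip
is first, (ii) any TE strip is last, (iii) the first strip has no
N-terminal COM domain and (iv) the last has no C-terminal one. The
collinear order is assumed first; if it violates only (i)/(ii), the
single offending strip is stably moved to the front/back (both moves
applied when both fire); otherwise all consistent permutations are
enumerated, falling back to the collinear order with a warning when
none exists. Output is capped at 720 sequences (6! — the full
permutation budget of six strips); above that only the
collinear/repaired order is used, keeping runtime predictable.

## Parameter learning

All parameters are plug-in event frequencies. Backgrounds (`PA`, `PM`,
`PE`) come from a corpus of structure monomer sequences, with
unsupported residues pooled into `⌀` and undetermined stereo excluded
from the stereo denominator. Match/mismatch tables come from curated
alignments: `PmatchA(level)` is the fraction of matched residues among
non-indel columns at that level (level 0 forced to 0); methylation and
stereo tables are joint frequencies whose denominator is all non-indel
columns with a determined structure-side state, pooled over gene-side
states. The indel denominators are not uniquely determined by the
model, so the package normalizes insertions per structure monomer and
deletions per gene monomer, matching the roles the two probabilities
play in the two sums of the score. Bootstrap resampling (default 100
samples) draws whole alignments with replacement — preserving
within-cluster correlation — and aggregates by the mean (median
available).

## Reporting

Matches below the score threshold (default 6.0; the boundary is strict,
so a score equal to the threshold survives) are discarded and the rest
sorted score-descending with lexicographic tie-breaking on
(compound, genome, cluster) ids. The combined report applies reciprocal
filtering with `k_best = 1` by default (strict reciprocal best; a CLI
flag relaxes it), preventing a few promiscuous compounds or clusters
from dominating the list. The benchmark evaluator marks a cluster
correctly identified when its ground-truth compound ranks within 10,
uses the ground-truth score as the cluster representative when correct
(else the best hit's score), and reports the exact prefix formula
`FDR[i] = (i − Numcor[i]) / i`, with tied scores sharing the FDR of
their tie group.

## Synthetic fixtures

The generator emulates the statistical structure the scoring model
assumes, not real chemistry: residue sequences are drawn from the
background frequencies, clusters encode them across 1–3 genes with
specificity scores in [80..100] for the true residue plus a
lower-scoring decoy prediction, and perturbations inject mismatches,
indels, stutter modules, tailoring edges, cyclization, or gene
shuffling (with CS/TE kept on the true first/last genes so consistency
constraints can recover the order). Decoys are resampled from the same
background with matched length distribution, so fixture difficulty
scales with the alphabet's entropy. The training-set generator samples
columns directly from the generative model implied by the column
probabilities, which makes the frequency estimators consistent and
allows parameter-recovery tests. What passing these tests shows is that
the implementation is faithful to its own model; real monomer graphs
and miner outputs are noisier (ambiguous decompositions, wrong domain
calls, residues missing from the alphabet), so recovery rates on real
data will be lower.

## Defaults and problem sizes

The shipped alphabet has 58 residues (20 proteinogenic plus common
nonribosomal monomers); it is a config file users can replace, and the
shipped scoring parameters are documented placeholders meant to be
re-learned with the training module on curated data. Specificity levels
default to the cut points {[1,60], (60,70], (70,80], (80,90],
(90,100]}, five levels covering the upper range where substrate
predictions discriminate. The planted-recovery experiment in
`scripts/acceptance.py` uses 100 replicates of one planted pair
(length 8, mismatch rate 0.1, indel rates 0.05) against 20 decoys, and
the parameter-recovery experiment uses 200 synthetic alignments of 12
columns — sizes at which the binomial error of every estimated
frequency is comfortably below the 0.05 reporting tolerance while the
whole script runs in seconds.

## Known limitations

* Upstream chemistry is out of scope: SMILES decomposition,
  stereochemistry perception and polyketide-hybrid recognition must
  happen before the monomer-graph input is produced.
* COM-domain pairing partners are not predicted (only the
  first/last-position constraints are used).
* Reversed traversal of backbone edges is not attempted during
  linearization; a graph annotated with inverted bond directions will
  not linearize.
* `PmatchA` is residue-agnostic by design; promiscuous adenylation
  domains with residue-specific behavior are averaged over.
* The gap model is linear; long unannotated insertions are penalized
  proportionally to their length.
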