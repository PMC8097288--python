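# Methods

`rniikit` analyses a family of RNase II-type (Dis3L2/Ssd1-like) proteins
given a protein multiple sequence alignment and a phylogenetic tree whose
tips match the sequence ids. It computes three things: a per-sequence
feature table (active-site signature, NLS, Cbk1 kinase motifs), per-domain
conservation summaries (pairwise percent identity, consensus profiles),
and a parsimony count of independent active-site losses on the tree. A
simulator generates families with known ground truth for every stage.

## Coordinates and alignment handling

Residue positions and alignment columns are both 1-based with inclusive
ranges, matching the residue-range convention used for this family
(N-terminus 1–337, CSD1+2 338–659, RNII 689–1014 on the ScSsd1-like
reference). The only gap character is `-` (`.` is normalised on read);
ambiguity codes other than `X` are normalised to `X`. A `ColumnMap` built
from the reference row translates residue ranges to column ranges by gap
skipping; domain extraction keeps interior gap columns so that downstream
identity metrics can handle them explicitly.

Column trimming keeps exactly the columns whose non-gap fraction is
**greater than or equal to** the gap threshold (default 0.1), i.e. the
trimAl `-gt` convention with an inclusive boundary; the kept-column list
is emitted so trimmed coordinates can be mapped back. Whether domain
sub-alignments are trimmed before computing identity is a config switch
(`trim_domains`, default on), since either order is defensible.

## Motif definitions and feature calls

Motifs are ordered position classes (fixed residue, residue set in
brackets, wildcard `x`) with an optional side condition on wildcard
positions:

* Cbk1 phosphorylation consensus: `Hxxxx[ST]` requiring ≥1 K/R among the
  designated wildcards. "Central" mode (default) designates motif
  positions 3–4, consistent with NDR-kinase consensus placing the basic
  residue at −3 from the phosphosite; an "any" mode designates all four
  wildcards. The choice is exposed because the consensus is stated
  ambiguously in the literature.
* Cbk1 docking: `[YF]x[FP]`.
* RNII active-site block: `DxxxxxDxDD`, whose positions 1, 9, 10 are the
  magnesium-coordinating aspartates (D201/D209/D210 in E. coli RNase II
  numbering).

`X` never satisfies any position class, wildcards included — conservative
calling for ambiguous residues. Overlapping hits are all reported and all
counted; no overlap-collapsing rule is applied, which makes counts
reproducible without an arbitrary tie-break.

The active-site signature is called positionally, not by scanning: the
block's columns are located by anchoring on a declared active homolog
(which must itself match the motif at the declared position — a hard
error otherwise), and a row is "active" iff all three catalytic columns
hold `D`. A gap at a catalytic column is an inactive call. This is the
only way to call pseudonucleases, which do not match the motif at all.
Conservative substitutions at non-catalytic block positions (e.g. the
Dss1-like `DxxxxxELDD`) still count as active signatures.

The NLS is called by counting K/R in a configured reference window (a
CSD1 loop), positive at ≥ `min_basic` (default 4). The window coordinates
are configuration, not a claim about any particular published mapping;
the default threshold is deliberately strict and is recorded in the
resolved config of every run.

Cbk1 phosphorylation motifs are counted within the configured N-terminal
region only (windows must lie entirely inside it); the docking call is
positive on a hit anywhere in the sequence.

## Conservation metrics

Pairwise percent identity uses the co-ungapped denominator: matches /
columns where both rows are non-gap. This denominator is the least
distorted by lineage-specific insertions; it is recorded in output
metadata. `X` counts as a mismatch even against `X`; self-identity is
defined as 100 for any row with at least one residue in the domain. Pairs
with zero co-ungapped columns get NaN rather than a fabricated value.
Matrices are emitted in tree-tip order so heatmaps line up with the
phylogeny.

Consensus profiles are per-column residue frequencies over non-gap,
non-`X` characters; all-gap columns are excluded with a warning. The
signature-string rendering writes the top residue uppercase at ≥ 0.9
frequency, lowercase at ≥ 0.5, else `x` (thresholds configurable; ties
break alphabetically for determinism).

## Loss reconstruction

Tips are binarised on the active-site call. Two reconstructions:

* **Dollo parsimony** (default): loss is irreversible and the root is
  constrained active — the family's outgroup and early-diverging homologs
  carry intact signatures, so the ancestral state is active, and a
  degenerated catalytic site is not plausibly regained. The minimum
  solution is exactly one loss on the stem edge of each *maximal*
  all-inactive clade; the implementation counts those clades directly,
  and the test suite proves the equivalence against brute-force
  enumeration over all ancestral assignments. If every tip is inactive
  the single loss sits on the root's own edge. Polytomies are allowed;
  several all-inactive children of a polytomy count one loss each.
* **Fitch/Sankoff parsimony** as a sensitivity check: unconstrained
  minimum changes, one most-parsimonious assignment reported (ties broken
  toward active), with an `ambiguous` flag computed by an in/out dynamic
  program marking whether any node takes both states across
  most-parsimonious assignments. Fitch's minimum never exceeds Dollo's.

Outgroup rooting places the root on the edge separating a declared
outgroup from the ingroup, erroring with the conflicting tip list if the
outgroup is not monophyletic under any rooting. Loss counts are
conditional on the input topology; no bootstrap weighting is attempted,
and the ambiguity flag is the only confidence statement made.

## The simulator

The generator emulates the statistical structure of the real family, not
its taxon composition: ~100 sequences on a Yule tree with an outgroup
clade, a 1014-residue architecture (N-term 337 / CSD1+2 322 / linker 29 /
RNII 326), an active-site block inside RNII, a basic NLS window inside
CSD1, seven planted Cbk1 phosphorylation motifs and one docking motif in
the N-terminus, and irreversible active-site losses.

* **Trees**: pure-birth process starting from two lineages (no root stem),
  with one extra exponential interval after the last birth so terminal
  branches have positive length. This construction has closed forms
  E[depth] = (H_n − 1)/λ and E[total length] = (n − 1)/λ, which the tests
  check by Monte Carlo. Default n = 100 tips, λ = 1.
* **Losses**: per-edge probability 1 − exp(−rate·length) on still-active
  lineages. Default rate 0.04 ≈ 4 expected events on a 100-tip tree —
  the regime of repeated independent loss this family shows. At a loss
  event the three catalytic aspartates are substituted to random non-D
  residues and held fixed.
* **Substitutions**: per-site exponential waiting times, uniform
  replacement among the 19 alternatives. Default rates 0.4 (N-term and
  linker), 0.12 (RNII), 0.03 (CSD) per unit branch length: fast
  disordered N-terminus, moderately conserved catalytic domain, highly
  conserved CSDs. Planted-feature positions are invariant, so planted
  truth is exact where masked.
* **Background**: non-feature positions draw from the 20 amino acids
  minus {H, Y, F}, so the root contains no chance Cbk1 or docking motifs;
  substitution can still create them later. Consequently, at default
  rates the recovered feature table differs from planted truth only by
  *extra* phosphorylation hits in the diverged N-terminus — measured at
  roughly 5% of table cells (about 0.2–0.3 chance `Hxxxx[ST]`+basic
  windows per ~330-residue near-random region). This is real behaviour
  of degenerate short linear motifs in disordered sequence, not a
  scanner fault; boolean features remain exact. At zero substitution
  rates recovery is exact, cell for cell.
* **Indels**: off by default so coordinate truth is exact. Optionally,
  geometric-length deletions (mean 3) are placed in the N-terminal region
  only, skipping planted positions — enough to stress gap handling
  without corrupting truth. Insertions are not modelled.
* **Clade structure**: the smaller root-side is labelled `outgroup`, the
  ingroup's basal subtrees `cladeA`, `cladeB`, … Per-clade Cbk1 counts
  (0–7) and docking knockouts can be configured; knockouts substitute the
  motif's first residue at the affected tips and the truth table follows.

All randomness flows through a single `numpy.random.Generator` seeded
from the config; identical seeds give identical output on any platform.

What passing simulator-based tests does **not** show: performance on real
alignments with alignment error, heterogeneous site rates, compositional
bias, or uncertain topologies. The analysis stages are exercised on real
data only through the generic file interfaces.

## Reproduction scales and known limitations

`scripts/acceptance.py` recomputes every reported quantity from scratch:
parsimony-vs-enumeration agreement on all rooted binary shapes of 2–8
tips (exhaustive state patterns through 6 tips, sampled above), motif
scanner agreement on 10,000 random strings, Dollo recovery on 200
fifty-tip simulations with ~3 expected losses, feature recovery at zero
and default rates, and one full 100-tip pipeline run. These sizes keep a
complete run under a minute while estimating rates to a few percent.

On the Dollo-recovery conditions above, the exact-recovery rate is about
93–94%: in the remaining runs two independent losses land on edges that
jointly cover an entire subtree and merge into one inferred event. The
"never overcounts" guarantee holds in every run; the merge condition is
characterised exactly and tested. Users should read the Dollo count as a
lower bound on the number of independent losses — which is also the
correct reading for real data.

Other limitations: no substitution-matrix-weighted similarity or explicit
rate models; no ML ancestral reconstruction; no bootstrap support
handling; nucleotide alignments and Stockholm/Clustal dialects are out of
scope.
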