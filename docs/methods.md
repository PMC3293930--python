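# Methods

## The thermodynamic model

Folding of an RNA sequence x into a secondary structure s is scored by the
standard nearest-neighbor free energy ΔG°(s): a sum over base-pair stacks
and loops (hairpin, bulge, internal, multiloop), with terminal-AU
penalties at helix ends and dangling-end stabilization from unpaired
bases stacking onto helix terminal pairs. Each structure coexists in the
thermodynamic ensemble with Boltzmann probability
exp(−ΔG°(s)/RT)/Q, where Q = Σ_s exp(−ΔG°(s)/RT) is the partition
function over the folding space F(x). Abstract shapes pool structures by
their helix arrangement; the shape probability Prob(p) = Q_p/Q
(Q_p the restriction of Q to shape class p) is a robust summary of the
ensemble, and the MFE structure within a class is its representative
(shrep).

All four model variants share one folding space *filter set*: canonical
pairs only (G:C, C:G, A:U, U:A, G:U, U:G), hairpin loops of at least 3
nt, bulge/internal strands of at most 30 nt, and no lonely pairs (every
closed substructure starts with two stacked pairs). They differ only in
dangling ends:

* **NoDangle** ignores dangles entirely (d0).
* **OverDangle** adds both-side dangle terms to every helix end in the
  exterior loop and in multiloops, whether or not the neighboring base is
  free (d2). This over-counts stabilization (a crude proxy for coaxial
  stacking) but keeps the algebra strictly local.
* **MicroState** makes dangles part of the state: an unpaired base in the
  exterior loop or a multiloop that is adjacent to a helix end may stack
  onto the helix to its left (`d`) or right (`b`) or stay free, each
  choice a distinct *microstate* (d1). Hairpin-, bulge- and internal-loop
  strands never dangle — their terminal-mismatch contributions are part
  of the loop energies.
* **MacroState** keeps one state per classical structure and resolves
  dangles inside the evaluation algebra (details below).

## Energy core

Parameters are the Turner'99 37 °C free energies in integer
centi-kcal/mol (RT = 0.61633 kcal/mol at 310.15 K), read from the
parameter files distributed with ViennaRNA (`rna_turner1999.par`,
optionally `rna_turner2004.par`). Reading the installed files rather than
re-typing the published tables guarantees revision fidelity to the
reference implementation; `load_parameters` also accepts any v2.0
parameter file path. Conventions follow the RNAfold family: tabulated
tetraloop entries replace the whole hairpin term; size-3 hairpins take
terminal-AU instead of a mismatch; a length-1 bulge retains the
helix stack and no terminal-AU; internal loops use the 1x1/1x2/2x2
special tables, dedicated 1xn and 2x3 mismatch tables, and otherwise
length + Ninio asymmetry (coefficient 50, cap 300) + mismatches; loop
lengths beyond 30 extrapolate with 107.856·ln(n/30) centi-kcal; a
multiloop costs 340 + 40·(stems+1) with free unpaired bases; multiloop
closing pairs use the dangle tables of the reversed pair for their inner
dangles. The structure evaluator built on these functions agrees with
RNAeval in modes d0/d2/d1 on random structure corpora to the printed
0.01 kcal/mol resolution (this cross-check is part of the test suite);
co-optimality is detected exactly on the integer scale.

Temperature is fixed at 37 °C; enthalpy/entropy rescaling, salt
corrections and coaxial stacking are out of scope.

## Grammars and algebras

Each model is a tree grammar whose derivations are exactly the folding
space members, evaluated under pluggable algebras: minimum + backtrace of
all co-optimal candidates (MFE), integer sum (counting), Boltzmann-
weighted sum (partition function), per-shape map merge carrying mass,
best energy and best structure (shape analysis), and band-limited
candidate lists (suboptimal enumeration; local pruning at Δ above the
cell optimum is lossless because substituting the locally optimal
substructure only lowers the total). All analyses of a model therefore
share one folding space by construction. Grammar inventories are data
(`grammar_spec`): NoDangle/OverDangle share one grammar with 11
nonterminals and 12 functions; MicroState extends the helix-wrapper and
multiloop rules (18 functions); MacroState has 25 nonterminals and 32
functions.

The MacroState grammar distinguishes, for every helix, whether a single
unpaired base sits directly left/right of it (then up to four dangle
variants are minimized over locally, including the no-dangle option), and
uses dedicated productions (ambd, ambd', acomb and the mladl/mladr/...
multiloop variants) for the genuinely ambiguous case of one base shared
between two helix ends. Because its published production system is only
partially specified, the grammar here is reconstructed from its
documented nonterminal/function inventory and validated against the two
defining contracts, both under test: its folding space is *identical* to
NoDangle's on every sequence (exact count equality), and its MFE agrees
with MicroState's essentially always (the local dangle choice can in rare
cases miss the global optimum; the ordering E_MacroState ≥ E_MicroState
always holds).

### MacroState ensemble semantics

The MFE algebra resolves every dangle site at the per-structure optimum.
The ensemble algebras (partition function, shapes) assign each classical
structure a single Boltzmann weight at a *locally resolved* dangle
assignment: exterior-loop dangles at the per-structure optimum, but each
stem boundary inside a multiloop — an unpaired run between two stems, or
between the last stem and the closing pair — contributes at most one
stabilizing dangle (the best of none / the left stem's 3' dangle / the
right stem's 5' dangle), while the run following the closing pair keeps
its two boundary dangles independent. This is the behavior reconstructed
from the model's published extreme-shift example, which this
implementation reproduces to within 0.2 percentage points on all three
printed shape probabilities; the per-structure-optimal alternative
overshoots the multiloop shape's probability by 3.6 points there. The
resolution needs ensemble information a plain dynamic program does not
carry — the dangle energy of a base onto a neighboring helix depends on
that helix's far end, which varies within a DP cell — so the MacroState
ensemble recurrences classify cell values by the partner base and, where
a boundary decision is still pending, by the pending dangle energy of the
boundary stem (a handful of distinct integers per cell). The result is
exact for the stated semantics: tests verify Q and all per-shape masses
against brute-force enumeration, and `macrostate_ensemble_energy` exposes
the per-structure definition independently of the DP.

## Abstract shapes

`shape_of` maps a structure to its shape string at levels 1–5 by
compressing maximal stacks into helices and walking the loop tree:
level 1 keeps all unpaired regions; level 2 keeps only bulge and
internal-loop regions (matching the printed worked example exactly);
level 3 is level 2 without underscores; level 4 merges helices separated
by bulges only; level 5 also merges across internal loops, leaving pure
multiloop nesting. The fully unpaired structure maps to `_` at every
level, keeping shape spaces total. One caveat is inherent in these
definitions: level 3 renders bulge and internal-loop interruptions
identically while level 4 treats them differently, so level-4 shapes are
not a function of level-3 shapes; the coarsening property holds for all
other level pairs and is property-tested. Shape spaces shrink
monotonically with the level, and helix elongation never changes a
shape. Shape probabilities drop classes below a configurable cutoff
(default 1e-6, applied after normalization; 0 gives exact mass
conservation Σ_p Q_p = Q, which the oracle tests assert).

## Comparison statistics

SPS(A,B)(x) = ½ Σ_p |Prob_A(p) − Prob_B(p)| is the probability mass that
moves between shapes when switching models; it equals the total-variation
distance (cross-checked against 1 − Σ_p min) and is a metric
(property-tested). KL divergence is provided in both directions for
completeness (it is asymmetric, which is why it was rejected as the
comparison measure). The asymmetric base-pair distance removes from the
prediction P those extra pairs whose bases are unpaired in the reference
R and which cross no reference pair, then counts |R∖P| + |P^-c∖R|; no
slippage is forgiven. Corpus aggregation (`run_comparison`) uses the
unweighted mean SPS, chooses among co-optimal MFE structures the one
closest to the reference, and reports gold-shape ranks with lower
empirical quantiles (the 90% value r means the gold shape is within the
top r shapes in 90% of cases; a {1,1,2} rank list has median 1).

## Gold structures

From an annotated interaction list, only cis Watson-Crick pairs over
canonical base combinations are kept (stackings, non-canonical pairs and
backbone contacts dropped; positions with conflicting cWC partners are
dropped entirely). Crossings that a single pair deletion resolves are
resolved (smallest such pair, deterministically); anything more knotted
rejects the structure as a signaled, non-exception outcome. Lonely pairs
are removed to a fixpoint after all other filters, so the pipeline is
idempotent and its output is always a nested, lonely-pair-free canonical
structure. Inputs: a TSV pair list, or a permissive MC-Annotate-style
text reader behind a flag.

## Synthetic data and the oracle

Test corpora are uniformly random ACGU sequences from a seeded generator
(i.i.d. bases; frequency sanity is itself tested). Uniform random
sequences are the study condition for folding-space growth; they are
GC-balanced and unstructured compared to biological RNAs, so passing
oracle tests demonstrates algorithmic correctness of the recurrences, not
predictive accuracy on natural sequences. The brute-force oracle
enumerates the complete folding space by direct recursion over the
structural alternatives (no energy DP) and scores members exclusively
through the structure evaluator, giving an independent route to counts,
MFE, Q and shape masses; it is capped at 22 nt (18 for microstates).
Problem sizes in the default test run — ~200 oracle sequences up to
18 nt, 100 60-mers for the count identity, 100 replicates per point for
the 30–60 nt growth curve, a 500-sequence 30/35-mer corpus for the
MFE-agreement statistic — keep the whole suite at about half a minute
while exercising every recurrence branch; the growth experiment's
per-base factor lands at 1.392, inside the sanity band [1.35, 1.55]
bracketing the asymptotic 1.44358 (finite lengths bias the estimate
low).

Counting uses dedicated integer recurrences per grammar with an O(1)
internal-loop summation (row prefix sums), cross-checked against both the
generic walkers and the oracle; Python integers make overflow a
non-issue. Partition functions accumulate in double precision without
rescaling — adequate to ~1e-12 relative at the sequence lengths treated
here (tested at 1e-9); very long sequences would need log-space or
per-cell rescaling, which is out of scope.

## Known limitations

* Pseudoknots, G-quadruplexes, coaxial stacking and base-pair
  probability matrices are out of scope.
* MacroState MFE can, in rare constructed cases, report an energy above
  the true full-dangle MFE (the documented local-choice limitation).
* The MacroState ensemble dangle resolution is a reconstruction
  constrained by one published worked example plus the model's structural
  description; residuals of ~0.2 percentage points on that example
  presumably reflect remaining micro-differences from the original
  implementation.
* Suboptimal enumeration materializes every candidate; with large Δ or
  long sequences the output itself is exponential.
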