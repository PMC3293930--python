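# foldspace

Thermodynamic RNA secondary-structure prediction tools all refer to the same
nearest-neighbor energy model, but they implement it over subtly different
*folding spaces*: they differ in how dangling ends (unpaired bases stacking
onto helix terminal pairs) enter the energy, and in whether a structure with
several possible dangle assignments counts once or many times in Boltzmann
ensembles. `foldspace` implements four variants of the folding-space model
as explicit tree grammars over one shared Turner'99 energy core:

| Model      | Dangling ends | Folding space |
|------------|---------------|---------------|
| NoDangle   | none | classical structures |
| OverDangle | added on both sides of every helix, even onto paired bases | classical structures |
| MicroState | explicit: each legal dangle assignment is its own state | dangle-refined microstates (≈ 4^(n/15) more) |
| MacroState | resolved inside the evaluation algebra, one state per structure | classical structures |

NoDangle/OverDangle/MicroState correspond to the d0/d2/d1 dangle modes of
the RNAfold family; MacroState keeps the small classical space while
scoring dangles, at the price of a much richer grammar (25 nonterminals,
32 evaluation functions, vs 11 and 12 for NoDangle).

Every model supports, through one set of grammar recurrences with
pluggable evaluation algebras:

* **MFE folding** with *all* co-optimal structures (`fold_mfe`),
* exact **folding-space counting** (`count_structures`),
* complete **suboptimal enumeration** within an energy band
  (`enumerate_suboptimals`, with cross-model rescoring),
* the **partition function** Q = Σ exp(−ΔG/RT) (`partition_function`),
* **abstract shape probabilities** Prob(p) = Q_p/Q at abstraction levels
  1–5, with the minimum-energy representative (*shrep*) of every shape
  class (`shape_distribution`).

For comparing models and benchmarking against experimentally derived
reference ("gold") structures there are the shape probability shift
SPS(A,B) = ½ Σ_p |Prob_A(p) − Prob_B(p)|, an asymmetric base-pair distance
|R∖P| + |P^-c∖R| that forgives predicted extra pairs compatible with the
reference, gold-shape rank statistics, and the gold-structure derivation
pipeline (canonical cis-Watson-Crick filter, lonely-pair removal,
single-pair pseudoknot resolution).

Energy parameters are read from the ViennaRNA-distributed Turner'99
(default) or Turner 2004 parameter files, so the tables are bit-identical
to what RNAfold/RNAeval use; the structure evaluator agrees with RNAeval
to 0.01 kcal/mol in every dangle mode it supports.

## Worked example

The 43-nt sequence below is an extreme case where the choice of model
shifts about a third of the probability mass between shapes and reverses
the top two ranks. Level-5 shapes abstract a structure to its helix
nesting: `[][]` two consecutive helices, `[[][]]` a two-way multiloop.

```sh
$ foldspace shapes -s GACCAAAGCCUUUGUCCCACAAAUUGCGAUCGCGUCGCGGAGC \
    --model macrostate --level 5
[][]    0.5859  (((.((....)).))).......(((((((...)))))))... -6.00
[[][]]  0.2913  ..((......((((.....))))..(((((...)))))))... -5.80
[]      0.1227  .......................(((((((...)))))))... -5.90

$ foldspace shapes -s GACCAAAGCCUUUGUCCCACAAAUUGCGAUCGCGUCGCGGAGC \
    --model microstate --level 5
[[][]]  0.6342  ..((......((((.....))))..(((((...)))))))... -5.80
[][]    0.3258  (((.((....)).))).......(((((((...)))))))... -6.00
[]      0.0399  .......................(((((((...)))))))... -5.90
```

Columns: shape, probability, shrep, shrep energy (kcal/mol). Under
MacroState each classical structure contributes one Boltzmann weight and
the open two-helix arrangement dominates (59%); under MicroState the
multiloop shape's many dangle variants each count separately, pushing
`[[][]]` to 63% although the MFE structure (−6.00 kcal/mol, shape `[][]`)
is the same in both models:

```sh
$ foldspace fold -s GACCAAAGCCUUUGUCCCACAAAUUGCGAUCGCGUCGCGGAGC --model microstate
(((.((....)).)))d.....b(((((((...)))))))d.. (-6.00)
```

(`d`/`b` mark bases dangling onto the helix to their left/right.)

Other entry points: `foldspace count` (folding-space sizes; NoDangle,
OverDangle and MacroState agree exactly on every sequence), `foldspace
subopt --delta 2 [--rescore microstate]`, `foldspace compare --gold
corpus.txt`, `foldspace goldprep pairs.tsv -s SEQ`, and `foldspace growth`
(mean folding-space size over random sequences; the per-base growth
factor comes out near the asymptotic 1.44).

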