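# Methods

## Scope and model

`efeflux` analyses ethylene formation by the ethylene-forming enzyme (EFE) at
two levels: the enzyme's own reaction stoichiometry (dual-circuit scheme) and
its embedding in small central-carbon networks (elementary-flux-mode
analysis). Everything numeric is exact: stoichiometric coefficients, flux
vectors and yields are `fractions.Fraction`; floating point appears only in
LP cross-checks and report formatting.

### Dual-circuit EFE stoichiometry

The enzyme is modelled as two coupled catalytic cycles:

* main cycle: `akg + o2 -> ethylene + 3 co2` (arginine bound, not consumed);
* sub-cycle: `akg + arginine + o2 -> succinate + co2 + guanidine + p5c`.

At the canonical 2:1 main:sub ratio the composite is
`3 akg + arginine + 3 o2 -> 2 ethylene + succinate + 7 co2 + guanidine + p5c`,
with closed forms `akg:arginine = ratio + 1` and `ethylene:succinate = ratio`
for any cycle ratio. Two modelling conventions to be aware of:

* The commonly quoted overall equation is written without a leading
  coefficient on AKG; carbon balance forces 3 AKG per arginine and the
  package uses 3 throughout.
* Only the **total** of 3 O₂ per composite is experimentally constrained;
  the 1-O₂-per-cycle split is the simplest allocation consistent with that
  total and is an assumption of this model.
* Only C and N are balanced. The sub-cycle as written is not H/O-closed
  (water is omitted), so hydrogen/oxygen bookkeeping is out of scope.

The dual-circuit scheme itself remains debated; the package encodes it as
proposed and makes no mechanistic claim beyond stoichiometric consistency.

### Elementary flux modes

EFMs are computed by the classical tableau/double-description algorithm:
reversible reactions are split into forward/backward columns, metabolite
constraints are imposed one at a time by combining adjacent rays (adjacency
via the support-inclusion test), and the spurious forward+backward two-cycles
are removed on folding back. Modes are normalized to coprime integer fluxes;
a mode whose support is entirely reversible takes its first support entry
positive. Output order is lexicographic by support, so runs are diffable.
Enumeration aborts with an error if the intermediate tableau exceeds 10,000
rows — the intended scale is tens of reactions, not genome scale.

Elementarity of a given vector is certified independently by the rank test
(support submatrix nullspace dimension exactly 1). The test suite further
checks the enumerator against a literal brute-force enumeration over all
support subsets on ~100 random networks, and against an LP.

### The six substrate scenarios

The scenario networks are curated from canonical textbook stoichiometries
(glycolysis, non-oxidative pentose phosphate, anaplerotic C4 carboxylation,
Calvin–Benson–Bassham), lumped to the usual sugar-phosphate metabolites, with
`akg -> eth_e + 3 co2` as the lumped EFE step. The succinate-forming EFE side
reaction is excluded from all scenarios (contested stoichiometry), and O₂ is
not part of the scenario networks (it only enters the dual-circuit model).
The reaction tables ship as TSV inside the package
(`efeflux/data/scenario_*.tsv`) and are the single source of truth. The
maximum yields are invariant to carbon-conserving lumping choices.

Key conventions:

* **Yield denominator.** For scenarios with an organic substrate (B–F),
  yield = ethylene carbon / organic substrate carbon; CO₂ exchange shows up
  in the carbon balance but not the denominator. This is the only convention
  reproducing the glycolytic 1/3 (2 C ethylene per 6 C glucose, despite one
  anaplerotically fixed carbon). The autotrophic scenario A is scored on net
  CO₂ uptake instead, which makes its yield trivially 1 (ethylene is the
  only carbon product); the informative numbers for A are the gross flows
  and cofactor demands.
* **Cofactors are annotations, not species.** ATP/NADH/NADPH never constrain
  flux; they are summed per mode and reported per mole of ethylene. Negative
  balances are meaningful: the pathway needs external supply (e.g.
  photosynthetic light reactions). The scenario table's cofactor columns are
  therefore sign/ordering observables, not independently constrained values.
* **Gross CO₂ accounting** counts internal reactions only (exchanges
  excluded): on glucose the optimal mode releases 5 CO₂ (PDH 1, ICD 1,
  EFE 3) and fixes 1 (C4 route) per ethylene.
* **One-pass Rubisco (E, F) is structural.** Scenario E adds PRK, Rubisco,
  the reductive PGA→GAP step and the transketolase/SBPase regeneration
  reactions to the glucose core, but deliberately **no** FBP
  aldolase/FBPase. Without gluconeogenic hexose-phosphate formation the CBB
  loop cannot close on its own: erythrose-4-phosphate formation requires
  glucose-derived hexose-phosphate, so no purely autotrophic mode exists
  inside E, and the mixotrophic mode (2 Rubisco fixations + 1 anaplerotic
  fixation per ethylene, yield exactly 1/2) is genuinely elementary. Had the
  full CBB been included, that flux pattern would decompose into a
  glucose-only mode plus an embedded autotrophic mode and would not appear
  as an EFM at all. Scenario A, which *is* autotrophic, carries the full
  CBB including FBP aldolase/FBPase.
* **Scenario F reaches 2/5, not 1/2.** With xylose, the pentose skeleton
  feeds PRK directly (xylose C5 + CO₂ → 2 PGA, one Rubisco pass per
  ethylene), but reduced PGA cannot re-enter the pentose pool: the
  transketolase/transaldolase trio cannot net-convert GAP to pentose-P
  without a hexose-phosphate source (a short linear-algebra argument over
  the trio shows the conversion is infeasible). Granting F SBPase-route
  regeneration would embed the autotrophic cycle and, as above, destroy the
  elementarity of any higher-yield mixed mode. Under the one-pass
  convention the xylose shunt therefore tops out at 2/5 = 40%; the
  glucose/xylose asymmetry is a structural consequence of which substrate
  supplies the hexose backbone for RuBP regeneration.
* ATP details follow the simplest one-ATP-per-phosphorylation convention
  (uptake/phosphorylation lumped, −1 ATP); substrate uptake ratios in the
  mixed-sugar scenario D are unconstrained (the yield is ratio-invariant).

### LP cross-validation

`lp_max_yield` maximizes product carbon subject to S·v = 0, irreversibility,
and total substrate carbon uptake ≤ 1 carbon-mole (scipy `linprog`/HiGHS).
Since the optimum of a linear objective over the flux cone is attained on an
extreme ray, it must equal the maximum over EFM yields; the float optimum is
snapped to the nearest small rational before comparison. This is used purely
as an independent oracle, never as the implementation.

### Conservation and triad scanning

Column conservation is the frequency of the modal non-gap residue over
non-gap rows; gaps never count toward conservation. Triad candidates are
triples (His, Asp/Glu at reference position +2, downstream His) with all
three columns conserved at or above a threshold and the His–His spacing
inside a window of reference residues. Numbering is 1-based in the reference
sequence with gaps skipped, the convention in which the proposed Kudzu-EFE
triad reads His189/Asp191/His268 (spacing 79) and the petunia ACC oxidase
triad His177/Asp179/His234 (spacing 57); the default window 40..120 brackets
both. No quantitative conservation criterion is canonical in the literature,
so the threshold is an explicit parameter (default 1.0). The acidic column
counts D and E as one residue class.

### Synthetic fixtures

All tests run on generated data; no external sequences or models are
downloaded. The generators use an explicitly specified 64-bit LCG (Knuth
MMIX constants, top 32 bits used), so fixtures are byte-identical across
platforms for a given seed.

* Network fixtures: source→paths→sink constructions with known mode sets
  (k disjoint paths → k modes; k fronts × k backs through a shared
  intermediate → k² modes), and small random networks (≤ 8 reactions) whose
  reactions are built to be carbon-balanced by construction.
* Alignment fixtures: uniform substitution model, no indels (gap handling is
  tested with hand-written micro-fixtures); planted conserved columns are
  identical across rows; noisy columns are re-rolled until not accidentally
  100% conserved; the background alphabet excludes H, D and E so the planted
  triad is provably the only one present.

What passing these tests shows — and does not. They certify the algorithms
(enumeration = definition, LP = EFM max, planted signal recovered exactly);
they do not certify biological realism of any fixture. Real alignments have
indels, phylogenetic correlation and partial conservation, so real-data
triad scans should use thresholds < 1 and inspect ranked candidates rather
than expect a unique hit. Reproducing published conserved-residue counts on
real EFE/ACCO alignments requires downloading those sequences and is left as
an exercise.

## Problem sizes and determinism

The scenario networks span 11–20 reactions and enumerate in well under a
second each; the full test suite (including ~100 brute-force oracle
comparisons and 50 triad fixtures) runs in a few seconds. All analyses are
deterministic; the only randomness anywhere is the seeded LCG in the
synthetic generators.

## Known limitations

* Genome-scale enumeration is out of scope by design (tableau bound).
* H/O/charge balance, thermodynamics and kinetics are not modelled.
* Cofactor balances are unconstrained annotations; a host's actual
  P/O ratios, transhydrogenase activity, and maintenance costs will shift
  practical yields below these stoichiometric ceilings.
* The autotrophic yield convention (per net CO₂) makes scenario A's yield
  degenerate at 1; compare scenarios on gross flows and cofactor costs.
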