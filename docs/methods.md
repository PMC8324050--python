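# Methods

## The modeling problem

Bacteroids are growth-arrested: they do not optimize biomass. The natural
objective is nitrogenase flux, and the natural questions are about resource
allocation — how carbon, electrons and ATP are partitioned between nitrogen
fixation, storage-polymer synthesis and amino-acid secretion as oxygen
becomes scarce. Two complementary formalisms are implemented:

- **FBA-family LP analyses** answer "what is the best the network can do
  under these bounds, and how does the optimum respond to them" (optimum,
  flux ranges, duals, knock-out phenotypes, objective-free ensembles).
- **Elementary conversion modes** answer "what can the network do at all":
  the extreme rays of the cone of net external conversions reachable at
  steady state, with no objective assumed. Every steady-state behaviour is
  a nonnegative combination of ECMs.

## Conventions

- Boundary reactions (exchange `EX_`, demand `DM_`, sink `SK_`) are written
  `metabolite →`, so export is positive and uptake is negative; all metrics
  use absolute uptake values. An "uptake capacity" *u* enters the LP as
  lower bound −*u*.
- Stoichiometric coefficients are exact `Fraction`s end to end; floats
  appear only at the LP solver boundary. This is load-bearing for the
  conversion-cone enumeration, where rounding creates spurious rays.
- The LP layer balances **every** metabolite row (internal and external);
  boundary reactions are the only unbalanced columns. The
  `stoichiometric_matrix` operation exposes the internal-rows-only matrix
  used by the cone construction, where external metabolites accumulate the
  net conversion instead of being balanced.

## LP analyses

All programs are solved with HiGHS (`scipy.optimize.linprog`).

- **Taxicab minimization** (`solve_fba_l1`): after the FBA optimum Z* is
  found, fluxes are split into nonnegative forward/backward parts, the
  objective is pinned to Z* by an equality row, and Σ|vᵢ| is minimized.
  This removes thermodynamically infeasible internal cycles from the
  reported distribution; the objective agrees with plain FBA to better than
  1e−9 relative.
- **Loopless FVA** is CycleFreeFlux-style post-processing rather than a
  MILP: each extreme solution's boundary fluxes are held fixed, every other
  flux is confined between 0 and its extreme value, and Σ|v| is minimized;
  flux carried only by balanced cycles disappears. A MILP formulation would
  be exact but is far heavier, and cycle flux in these networks is removable
  by norm minimization.
- **FVA fraction of optimum** defaults to 0.99 in the oxygen-sweep
  scenario: at the strict optimum the flux polytope of this model collapses
  to a (near-)unique vertex and all ranges degenerate to points, so
  capability ranges are taken at 99% of the nitrogenase optimum.
- **Shadow prices** are the solver's bound duals on the boundary reaction of
  each external metabolite, with signs fixed so that a limiting uptake has
  π > 0 (marginal objective gain per unit of extra capacity) and a slack
  bound has π = 0. Degenerate optima have non-unique duals; an optional
  finite-difference cross-check flags metabolites where the basis dual
  disagrees with a central difference.
- **Phase planes** quantize each axis shadow price to {−, 0, +} with
  tolerance 1e−6 and label maximal 4-connected regions of identical
  signature; infeasible cells are labeled −1. Signature segmentation is a
  design choice: it makes "phase" mean exactly "constant marginal-value
  regime".
- **Gene deletion**: a reaction is disabled when its GPR evaluates false
  under the deletion; a gene is essential when the resulting maximum
  nitrogenase flux falls below 1e−6 flux units (an infeasible knock-out —
  e.g. one that makes a forced amino-acid demand unsatisfiable — also
  counts). The threshold quantifies "prevented flux"; results are
  insensitive to it over several orders of magnitude because knock-out
  optima here are either ~0 or O(0.1).
- **Ensemble FBA**: objective k draws a uniform number m of reactions
  without replacement and uniform(0, 1] weights. The draw stream is
  generated once per seed and reused across the sweep, so results are
  bitwise reproducible and sweep points see identical objectives.
  Infeasible/unbounded draws are skipped and counted, not resampled, to
  keep the stream seed-stable. The study-scale ensemble size is 50,000;
  tests and the acceptance script use a few hundred, which is enough for
  the qualitative orderings asserted (differences of several SDs).

## Conversion-mode enumeration

Reversible reactions are split into irreversible pairs; each listed
external metabolite contributes sign-restricted uptake and/or export
columns (inputs: uptake only; outputs: export only; free: both; hidden:
both but dropped from the bookkeeping — the cofactor-hiding device).
Unlisted external metabolites must balance internally, which cleanly
switches off whole branches (e.g. sugar catabolism in a
dicarboxylate-only survey). The double description then eliminates one
metabolite balance row at a time in greedy minimum |pos|·|neg| order with
integer, gcd-reduced arithmetic and the combinatorial adjacency test.
Rays activating both members of a split pair (or uptake and export of one
metabolite) are two-cycle artifacts and are discarded. Projected rays are
deduplicated exactly and pruned to the extreme rays of the conversion cone
by LP conic-membership tests; every returned conversion also has an LP
reachability certificate.

Note that extreme rays of a *projected* cone need not have pairwise
incomparable supports: a pure polymer-synthesis mode's support can be a
strict subset of a polymer-plus-N₂-fixation mode's support while both are
extreme. Elementarity is therefore verified as non-decomposability, not as
support minimality.

## Conversion metrics

- **Carbon cost** = 12.011·(C_in − C_out,credited) / 14.007·(N_out −
  N_in,organic) in g C per g N. Credited carbon outputs are secreted
  organic metabolites; CO₂ (waste) and storage polymers (retained in the
  cell, not delivered to the plant) are *not* credited, so polymer carbon
  counts toward the cost. N₂ is excluded from organic nitrogen input. Both
  the crediting set and the atomic masses are configurable. This reading
  is the one under which polymer-free modes sit near the theoretical
  fixation cost (≈2.5 g/g) while polymer modes are severalfold costlier.
- **Plausibility filter**: positive cost < 40 g C per g N, at most one
  amino-acid input (GABA counts as an amino acid), positive net nitrogen
  output. Rejections carry machine-readable reasons.
- **Spearman correlation** uses midranks; p-values are exact (full
  permutation distribution) for n ≤ 10 and t-approximated above.

## The synthetic core-bacteroid model

The generator emulates the pathway content of a curated core bacteroid
network with ~80 reactions: every metabolite carries a full C/H/N/O/P/S
formula, every internal reaction is exactly element-balanced (water and
protons are completed automatically after C/N/P/S are written by hand, so
the balance checks pass by construction, not by exemption), and the
network is free of orphans, dead ends and balanced cycles.

Key parameters (flux units are arbitrary; ratios are what matters):

| parameter | default | why |
|---|---|---|
| P/O (NADH) | 1.5 ATP per 2 e⁻ | textbook bacterial value; together with the FADH₂ value it makes dicarboxylate catabolism more oxygen-hungry per carbon than sugar catabolism |
| P/O (FADH₂) | 1.0 | enters at a later ETC coupling site |
| nitrogenase ATP / N₂ | 16 | textbook stoichiometry (8 e⁻ via reduced ferredoxin, H₂ evolved) |
| amino-acid demands | 0.01–0.05 | low-level protein synthesis in growth-arrested cells; alanine/aspartate upper bounds open (secreted) |
| carbon uptake | 4 | the standard scenario's dicarboxylate supply |
| oxygen ceiling | required argument | deliberately not defaulted: it is *the* controlled variable of every experiment |

Lumped steps use textbook net stoichiometries and are documented in the
generator source: glycolysis (G6P → 2 pyruvate, +3 ATP, +2 NADH),
gluconeogenesis (2 PEP → G6P, −2 ATP, −2 NADH), oxidative/non-oxidative
pentose-phosphate branches, arabinose → 2-oxoglutarate, PHB
(2 acetyl-CoA + NADH per C₄ monomer), glycogen (G6P + ATP per C₆ monomer),
palmitate (8 acetyl-CoA + 14 NADH + 7 ATP), and a phosphatidate-like
glycerolipid. NADPH is pooled with NADH; ferredoxin is a one-electron
carrier with an S₄ bookkeeping formula. Protons stay internal: with
neutral-species formulas the redox balance pins net proton exchange to
zero, so a proton boundary would be structurally dead.

Pyruvate carboxylase is included as the anaplerotic route: without it,
sugar carbon sources cannot replenish oxaloacetate and the
malate-vs-sucrose comparison is infeasible.

GPRs follow a seeded scheme (40% single gene, 30% two-gene complex, 30%
isozyme pair; transports single-gene; nitrogenase a fixed three-gene
complex; the ATP-maintenance pseudo-reaction has none). Mock experimental
essentiality calls flip exactly round((1 − agreement)·n_genes) seeded
random calls of the exhaustive-deletion ground truth, so the
essentiality-comparison machinery can be exercised at any chosen agreement
level.

### What the generator does and does not emulate

It reproduces the *qualitative* physiology: polymer synthesis as a
low-oxygen carbon/electron sink, alanine secretion under oxygen
limitation, the oxygen premium of ammonia assimilation via GS-GOGAT, the
per-carbon superiority of sugars over dicarboxylates, and the carbon-cost
separation between polymer-producing and polymer-free conversions. It does
**not** reproduce any organism's exact reaction list, gene ids, flux
values or phase boundaries; passing tests show the algorithms and the
qualitative orderings are right, not that the numbers transfer to a real
bacteroid. Two deviations from the corresponding curated-network results
are expected and documented: the malate × O₂ phase plane of this small
network has two shadow-price regimes (a richer network shows four), and at
the strict nitrogenase optimum the lipid-synthesis maximum does not rise
under oxygen limitation (palmitate synthesis pays the full 7 ATP/C16
carboxylation bill, so PHB dominates as a sink at the optimum); the lipid
shift appears in the objective-free ensemble, which is also where it is
observed in richer models.

## Numerical choices

- LP status is reported honestly (`optimal` / `infeasible` / `unbounded`);
  no fluxes are fabricated for failed solves.
- Balanced-cycle and blocked-reaction detection threshold: |flux| > 1e−6
  in model units.
- Shadow-price sign tolerance for phase signatures: 1e−6.
- Conversion rays are returned gcd-normalized with integer coefficients;
  `normalize_conversion` rescales per carbon input or per largest
  coefficient without changing any metric (all metrics are
  scale-invariant, which is tested).
- Double description intermediate ray count is capped (default 200,000);
  exceeding it raises with a suggestion to hide more metabolites rather
  than silently degrading.
- SBML round-trips recover exact rationals via
  `Fraction(float).limit_denominator(1e9)`, which is lossless for the
  coefficient denominators that occur here.

## Known limitations

- Loopless FVA by post-processing can, in adversarial networks with
  coupled cycles, keep flux that a MILP formulation would exclude; for the
  bundled models the two agree (the networks are cycle-free by
  construction, which the consistency check asserts).
- Dual-based shadow prices are basis-dependent at degenerate optima; the
  finite-difference flag identifies, but does not resolve, such cells.
- The ensemble skips infeasible draws rather than resampling; at extreme
  bounds where most draws fail, means are over few samples (the skipped
  count is reported).
- Enumeration scales to core-model size (tens of reactions after
  presolve), not genome scale; that is a scope choice, not an algorithmic
  accident.
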