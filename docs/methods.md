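# Methods

`discons` quantifies how well *intrinsic disorder* — not just sequence — is
conserved across homologues of RNA-binding proteins, and relates disorder to
the geometry of protein–RNA interfaces. This note documents the models and
the choices behind them.

## Conservation scoring

**Sequence conservation score (SCS).** For each alignment column *c* the
amino-acid distribution `p_c` over non-gap rows (unknown `X` residues carry no
evidence) is compared to a background distribution `q` by the Jensen–Shannon
divergence with mixing weight ½ and log base 2, so `D_c = JSD(p_c, q) ∈ [0,1]`.
Two corrections follow the Capra–Singh conservation-scoring conventions:

1. gap penalty: `D'_c = D_c · (1 − gap_fraction_c)`, applied *before*
   windowing (the order is a documented choice; the original tooling is
   ambiguous on this point);
2. window smoothing: `SCS_c = (1−w)·D'_c + w·mean(D' over a length-3 window
   centred on c)`, `w = 0.5`, window truncated at the alignment edges.

The default background is the BLOSUM62 marginal amino-acid frequency vector;
a uniform background is retained because the invariant-column score then has
the closed form `JSD(δ_r, U_20) = ½·[log₂(40/21) + (1/20)·log₂(2/21) + 19/20]
≈ 0.855`, used as an exact oracle in the tests. All-gap columns score 0 by
definition.

**Disorder conservation score (DCS).** Disorder is predicted per *ungapped*
sequence and mapped onto alignment columns. `DCS_c` is the fraction of
non-gap rows whose mapped score at *c* is ≥ 0.5. Gap rows are excluded from
the denominator: a gap carries no evidence about disorder.

**Classification.** Columns with ≥ 30% gaps stay `unclassified`. Otherwise:
`constrained` (SCS ≥ 0.5 and DCS ≥ 0.5), `flexible` (SCS < 0.5, DCS ≥ 0.5),
`non_conserved` (0 < DCS < 0.5), `structured` (DCS == 0, exactly — the
category means the *complete* absence of disorder evidence, so no epsilon is
applied). Scores are kept on [0,1]; the 0–9 scale seen in score-pair heat
maps is a display binning, `floor(10·score)` clipped to 9. Only a [0,1]
scale makes a 0.5 threshold meaningful, so the binned scale is derived, never
primary.

## Disorder prediction

The reference predictor reproduces the *shape* of IUPred's pairwise
interaction-energy estimation, not its published parameters (a stated
non-goal). For residue *k*,

    e_k = mean over residues i, 0 < |i−k| ≤ 50, of P[a_k, a_i]

with a symmetric 20×20 matrix `P` of *stabilizing* contact terms built from
the TOP-IDP order/disorder propensity scale `f = −TOP_IDP`:

    P[a,b] = (f_a + f_b)/2 + 0.4·max(0,f_a)·max(0,f_b) − 0.3·q_a·q_b

(hydrophobic pairs stabilize; like charges repel; opposite charges form salt
bridges; His counts as half-charged). Energies are smoothed by a ±10-residue
moving mean and mapped through a strictly decreasing logistic,
`score = 1/(1+exp(s·(e − e₀)))`. The transform parameters are calibrated
once, on 10 hydrophobic-core-like and 10 charge/Pro/Gly-rich synthetic
sequences (length 150, fixed seed), by placing `e₀` midway between the group
mean energies and choosing `s` so the group means map to scores 0.25 / 0.75 —
the groups therefore separate at 0.5. The fitted constants ship in the
package; `fit_transform()` reproduces them.

The window radius of 50 corresponds to long-disorder usage, appropriate for
whole-protein analysis. Unknown residues use the column-mean parameter row.
Any callable mapping a sequence to a per-residue [0,1] vector can be injected
in place of the reference predictor; a windowed TOP-IDP propensity predictor
ships as a deliberately trivial fallback.

**Known limitation.** Because the energy model is composition-based and
coarsely calibrated, absolute disorder contents of real proteins can deviate
substantially from IUPred's. On the bundled Levivirus coat-protein sequence
the predictor yields a score plateau of 0.30–0.48 and a disorder fraction of
0, where IUPred reports ≈ 24%. Rank ordering (disordered vs ordered
compositions, IDR-bearing vs compact synthetic sequences) is reliable;
absolute percentages on natural sequences are not.

## Interface geometry

**Interface residues.** A protein residue is an interface residue when it
forms ≥ 5 heavy-atom pairs within 5.0 Å (inclusive — the boundary must be
fixed for exact tests) of the nucleic chain. The implementation uses a k-d
tree over partner atoms; the test suite asserts exact equality with an
all-pairs distance-matrix oracle, so the spatial index is purely an
optimization.

**Partners.** Chain B is a partner of chain A when ≥ 5 residues of *A* each
have ≥ 1 atom within 5 Å of B. The residue count is taken on the query chain
(the relation could in principle be asymmetric in rare constructions; the
underlying atom-distance relation is symmetric and is what the tests assert).
Only the first model of multi-model entries is ever loaded.

**Surface areas.** Solvent-accessible surface areas use an in-package
Shrake–Rupley implementation: probe 1.4 Å, 960 deterministic
Fibonacci-lattice sphere points per atom (no RNG, so outputs are
byte-reproducible), Bondi van der Waals radii by element (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å; default 1.70), hydrogens excluded. The buried
interface area of a chain is `(SASA_chain + SASA_complement − SASA_complex)/2`;
per-residue normalizations divide by the chain's residue count. At 960
points the two-sphere toy agrees with the closed-form buried-cap area and
with a 10×-density run to well under 2%.

**Accessibility plot.** Chains are placed on the per-residue accessible
surface area vs per-residue interface area plot; the published constant
threshold of 80 Å²/residue is interpreted as the level set
`asa_per_residue + interface_per_residue = 80` (the simplest line consistent
with "lower left … below"), with the disordered/folding-upon-binding side
inclusive at the boundary.

**Secondary structure.** A DSSP-style assignment: amide hydrogens are
rebuilt 1.01 Å from N opposite the preceding carbonyl, hydrogen-bond energies
use the Kabsch–Sander electrostatic model (`E = 0.084·(1/r_ON + 1/r_CH −
1/r_OH − 1/r_CN)·332` kcal/mol, bond if `E < −0.5`), two consecutive 4-turns
make an α-helix, two consecutive 3-turns a 3₁₀-helix, parallel/antiparallel
bridge patterns make strands, remaining hydrogen-bonded turns are `turn`, and
everything else (including residues with incomplete backbones and prolines as
donors) is `unclassified`. π-helices and β-bulges are deliberately out of
scope. Helices and strands together count as "regular" structure; fractions
over disordered residues are reported as missing when a chain has no residue
scoring ≥ 0.5.

## Statistics

Welch *t* and two-sample Kolmogorov–Smirnov tests, Pearson and Kendall
correlations are delegated to scipy behind the module surface; Kendall uses
the tie-corrected tau-b variant because composition data produce ties.
Reported p-values are floored at 2.2e-16 (the conventional lowest printed
precision), with raw values retained. Per-amino-acid conservation in
disordered columns (DCS ≥ 0.5 by default) compares each residue's SCS sample
against the pooled occurrences of all other residues by Welch *t*, with
Benjamini–Hochberg correction across the 20 tests at α = 0.05 (the correction
is a documented choice; the analysis convention leaves it open). Residues
with fewer than two occurrences are reported untested. Zero-variance inputs
make correlations undefined and they are reported as missing, not zero.
Composition enrichment is `100·(f_target − f_background)/f_background` per
amino acid, undefined where the background frequency is zero.

## Synthetic data: what it emulates and what it does not

The generators exist so that every stage is testable offline with exact,
planted truth; they are pure functions of (spec, seed).

- **MSAs**: built column-wise per block. Constrained blocks plant one
  invariant low-background-frequency residue (W/C/M/H) per column, giving a
  JSD high enough to survive the gap penalty and windowing; flexible,
  non-conserved and structured blocks use *balanced* uniform columns (every
  amino acid equally often, shuffled) so the low-SCS guarantee is
  deterministic rather than merely probable. Disorder scores are planted
  directly (0.9/0.1 patterns giving DCS 1, 1, 0.3, 0 respectively), which
  isolates the conservation logic from predictor fidelity. Gaps are placed
  at exact per-column counts — `floor(rate·n_rows)` below the 30% filter,
  `ceil` at or above — so the classified/unclassified truth is part of the
  construction rather than a sampling outcome.
- **Complexes**: unphysical pseudo-atom lattices. Each planted interface
  residue gets its contact atoms within 4.5 Å (not 5.0, to keep clear of the
  floating-point boundary) of exactly one RNA phosphate and > 5 Å from every
  other RNA atom, so its atom-pair count is exact; non-interface residues
  stay > 8 Å from the RNA. RNA residues carry O2′ so chain typing works on
  round-trip through PDB files.
- **Sequence sets** place one contiguous disordered-composition segment of
  the target size in an otherwise core-like sequence; the dataset generator
  couples planted interface size to disorder content and draws interface
  residues from an Arg/Lys-rich composition.

Passing tests on these inputs demonstrates that the *machinery* (scoring,
classification, geometry, statistics) is correct and self-consistent. It
does not demonstrate predictor fidelity on natural sequences, realistic
interface geometry, or the database-scale effect sizes of the original
analysis, all of which depend on 2015 snapshots of Pfam/SwissProt/PDB that
are intentionally not reproduced.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use desk-scale runs chosen to keep
full verification under a minute apiece: 100 seeded alignments
(4 × 25 columns, 20 rows) for category recovery, 50 seeded complexes
(≤ 2,000 atoms) for interface-oracle equivalence, 100 seeded datasets for
statistics parity, and 30 complexes (100-residue chains) for the dataset-level
enrichment and correlation directions. All randomness flows from explicit
seeds; SASA, file outputs and the CLI are deterministic by construction
(fixed float formats, fixed orderings, deterministic sphere points).

## Known limitations

- The disorder predictor shares IUPred's architecture but not its parameters;
  absolute disorder percentages on natural proteins are approximate (see
  above).
- The redundancy filter is a greedy stand-in for CD-HIT: identity is
  match-count under a match=1/mismatch=0/gap=0 global alignment divided by the
  shorter length, clustering is single-pass greedy by descending length. It
  is deterministic and testable but not speed- or recall-equivalent to CD-HIT.
- Heteroatoms, ligands, waters, hydrogens and alternate conformations beyond
  the highest-occupancy one are excluded everywhere; chains mixing amino
  acids and nucleotides are flagged `other` and skipped by the geometry.
- Homolog search, alignment construction (PSI-BLAST/MAFFT), Pfam domain
  extraction, GO retrieval and conformational-energy calculation are out of
  scope; alignments and per-chain energies enter as files.
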