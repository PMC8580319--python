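# Methods

## The classification model

`acsarch` treats "genuine ACS" as a conjunction of sequence features:

```
predicted_ACS  ⇔  (ACS motifs 1–9 all present)
               ∧  (their best hits at strictly increasing, disjoint positions)
               ∧  (Q98-equivalent glutamine present)
               ∧  (N217-equivalent asparagine present)
```

The N217 conjunct is part of the predicate by default (`strict_n217=True`)
because the one known protein that satisfies motifs+Q98 yet lacks activity
is explained exactly by the missing PLP-contacting asparagine; setting
`strict_n217=False` restores the two-level reading in which such sequences
are flagged with an exception note instead of vetoed. AAT-motif presence
is reported but never vetoes: no positive rule for aminotransferase or
Cβ-S lyase activity is defined, and the lyase column of the evidence table
is always "ND".

## Motif scanning and exact p-values

Motifs are ungapped PWMs over the 20 standard amino acids. Window scores
are log-odds in bits against a background composition. Position p-values
are exact: per-column scores are quantized to integers (1000 bins per bit,
`floor` rounding so p-values are conservative) and the null score
distribution is built by column-wise convolution over the background. The
sequence-level best-hit p-value is `1 − (1 − p_min)^W` over the `W`
scorable windows; overlapping-window dependence and the conservative
quantization make it stochastically ≥ Uniform(0,1) under the null, which
the test suite verifies by a one-sided KS check at n = 2000.

Ambiguous letters (X/B/Z/J/U/O) contribute zero log-odds in scanning, are
excluded from counting when building models, and windows more than 50%
ambiguous are skipped. Presence threshold: position p ≤ 1e-4 (a
conventional motif-search position-p cutoff; the underlying studies do not
state one), exposed as config. Pseudocount: 0.375 total pseudo-observations
spread proportionally to the background (a standard MEME-style choice).

## Motif discovery

Discovery is greedy sequential EM under the ZOOPS occurrence model (zero
or one occurrence per sequence; OOPS available): per candidate width,
`n_restarts` EM runs are seeded from randomly chosen subsequence windows
(deterministic given the seed); the best motif by log-likelihood ratio is
kept if its LLR exceeds `log(#possible alignments)` — an E-value-like
floor that returns zero motifs on degenerate input — its occurrences are
probabilistically erased, and the process repeats up to `max_motifs`.
After convergence the occurrence register is refined by trying rigid
shifts of all occurrences (iterated; EM is prone to phase-shifted local
optima) and the final model is rebuilt from the hard occurrences.
Defaults mirror the conventional discovery setup (widths 6–50, 25 motifs,
20 restarts); the tests and the acceptance script run discovery at the
planted width with ~5 restarts, which is ample at the conservation levels
they use and keeps runtimes in seconds.

## Residue correspondence

Key-residue status is read off a global affine-gap alignment (BLOSUM62,
gap of length k costing 11 + k, end gaps penalized) between the query and
the AtACS7 reference, whose numbering counts the initiator Met as residue
1. The alignment engine is Biopython's `PairwiseAligner`; when co-optimal
alignments exist the engine's deterministic first traceback defines the
correspondence (the package treats this order as its tie-break
convention). The status of a key residue is `match`, `mismatch(letter)`,
or `deleted`. Status can be sensitive to alignment parameters for distant
homologs; parameters are therefore explicit configuration, not constants.

The packaged reference (`data/atacs7_synthetic.fasta`) is a synthetic
stand-in: a deterministic protein-like sequence with Q at 98 and N at 217.
It exercises all numbering logic but is not the database AtACS7 sequence;
real analyses should pass the database sequence explicitly.

## Phylogeny

The progressive aligner is deliberately simple and documented as such: a
UPGMA guide tree over pairwise-alignment p-distances, exact pairwise
alignment for cherry merges, and an affine-gap expected-score (Gotoh)
profile–profile DP for internal merges. Distances are pairwise-deletion
p-distance or Poisson-corrected `d = −ln(1 − p)`; saturation (p → 1) is an
explicit error unless clamping is requested (the bootstrap clamps, since
resampled replicates may saturate transiently). Neighbor joining is the
Saitou–Nei algorithm with the standard Q-criterion, ties broken toward the
lexicographically smallest label pair, and negative branch estimates
clamped to zero with the original value recorded. Bootstrap replicates
resample columns with a counter-based Philox stream keyed by (seed,
replicate), so any replicate is reproducible in isolation; supports are
percentages of replicates containing each internal bipartition of the
full-data tree. Because the aligner is a stand-in for production MSA
tools, tree claims are validated as topological properties (monophyly,
supports), not branch-length matches.

## Structures

PDB/mmCIF parsing is backed by gemmi. Altlocs resolve to the highest
occupancy conformer (ties → 'A'); waters are dropped; non-polymer residues
(e.g. the PLP–aminoethoxyvinylglycine adduct PPG) are collected as
ligands. Superposition is single-pass least squares (Kabsch via SVD,
reflections excluded) — no outlier-rejection cycles, so the RMSD
denominator is exactly the paired-atom count. Residue pairing is by
residue number within one entry and by sequence alignment across
proteins; the active-site report lists protein residues with any
non-hydrogen atom within 4.0 Å (configurable) of any ligand atom, flagging
residues contributed by the partner subunit. Region comparisons support
Cα or side-chain atom policies and an optional frozen-frame RMSD (no
re-fit), since published active-site comparisons do not always state the
reference frame; both variants are exposed.

## The synthetic generator

The generator emulates the validation design the rule was built against: a
protein family of ~420–480-residue sequences over a uniform background
(a plant-proteome-like composition is provided as a preset), with nine
planted ungapped motifs (widths 14–24) in fixed order, spacers geometric
with mean 25. Motif consensus strings are drawn per seed, so nothing
depends on external motif tables. One family-wide spacer layout is drawn
and each sequence jitters it by ±3 per spacer — homologs share
architecture spacing up to small indels, which is what makes global
alignment meaningful; spacer *letters* are iid background. At each
non-key motif column the consensus letter appears with probability c
(default 0.9) and otherwise a background letter is drawn (so the expected
per-column identity is c + (1 − c)·bg(consensus)); the Q and N key
residues are planted deterministically since they define the labels.

Negative classes: four *point ablations* (missing motif k, scrambled
order, Q98→A, N217→A) deviate in exactly one conjunct; two *evolutionary
controls* (seven-C-terminal-motif-only, emulating the moss Cβ-S lyase
pattern, and an AAT-motif aminotransferase control) additionally carry
their own consensus diverged from the family consensus at rate 0.3,
standing in for anciently diverged homologs — without this the phylogeny
would have no signal separating the positive clade, because the motifs the
controls lack are gapped out of pairwise-deletion distances rather than
counted as differences.

What passing tests on this generator do *not* show about real data:
spacers carry no homologous signal (real inter-motif regions do), there
are no indel processes inside motifs, no site-rate heterogeneity, and
motif consensus strings are random rather than biochemically constrained.
Results on the generator validate the pipeline's logic and calibration,
not the biological discriminability of real families.

Coordinate perturbations for superposition fixtures displace a base
configuration along a random field orthogonalized against the six
rigid-body modes, with the amplitude solved by secant iteration on the
actually computed Kabsch RMSD until the target is met within 1e-9.

## Numerical choices and problem sizes

- Score quantization: 1000 bins/bit, floor rounding (conservative
  p-values); the exact-PMF test alphabet is 4 letters so enumeration is
  feasible at widths 2–4.
- Architecture tie-break: equal-p hits resolve to the smaller start;
  retained hits must be pairwise disjoint intervals.
- Internal coordinates are 0-based half-open; all user-facing reports are
  1-based inclusive, matching crystal-structure residue numbering.
- Benchmark sizes: 100 sequences (50 positives / 50 negatives) for
  classification accuracy; 12 taxa × 20 seeds for the monophyly study;
  100 random additive matrices (≤ 6 taxa) for NJ consistency; 200
  bootstrap replicates for support estimates; 30–50 random ≤10-point
  instances for the superposition oracle. These sizes were chosen so the
  whole validation runs in about a minute while keeping Monte-Carlo error
  well inside the asserted margins.

## Known limitations

- The progressive aligner is not a substitute for a production MSA tool
  on real, indel-rich families; use it for the synthetic benchmark and
  topology-level claims.
- Discovery E-values are an LLR-with-penalty criterion, not a calibrated
  E-value; no attempt is made to reproduce any specific discovery
  program's numbers.
- The decision rule is a conjunction of presence calls; it does not
  predict quantitative activity levels.
- Reproducing the published crystal-structure RMSD comparisons requires
  the deposited coordinates (7DLW, 7DLY, 1M7Y) on local disk; they are
  not bundled.
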