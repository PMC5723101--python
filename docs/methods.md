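# Methods

## The potential

`pairpot` builds distance-dependent atom-pair statistical potentials for
protein structures. Atoms are described residue-specifically: enumerating the
canonical heavy atoms of the 20 standard amino acids gives 167 atom types,
and because a protein chain has distinct N and C termini, ordered pairs
(i, j) and (j, i) are kept separate — 167² = 27,889 pair types. For each
ordered pair the distances of qualifying atom pairs in a training set of
experimental structures are histogrammed, and the energy of pair type (i, j)
at distance bin r is the inverse-Boltzmann log-ratio

    u_ij(r) = −kT · ln[ f_obs_ij(r) / f_ref_ij(r) ],

with kT ≡ 1: every downstream measure (native recognition, Z-score, the
energy/TM-score correlation) is invariant to a positive energy scale, so
absolute units are never needed.

Two statistical parameters control which pairs are counted and scored:

- **distance cutoff** (Å): pairs at or beyond it are ignored. Distances are
  binned into a first bin [0, 3.0) Å followed by 0.5 Å bins up to the cutoff
  (half-open bins, so the bins partition [0, cutoff)); a 5 Å cutoff gives 5
  bins, a 22 Å cutoff gives 39.
- **residue interval** s: only pairs whose residues are ≥ s apart in
  sequence qualify; s = 0 admits intra-residue pairs. Intervals are computed
  from 0-based positional indices of the continuous chain, which coincide
  with author numbering on the sequence-continuous chains the framework
  accepts.

Each unordered geometric pair increments exactly one ordered cell — the atom
in the N-terminally earlier residue first, canonical atom order breaking the
tie within a residue — so total counts remain interpretable as numbers of
geometric pairs (a both-cells convention would double them).

The construction interval and the **application interval** are decoupled:
a table built at interval s_c can be applied at any s_a, simply restricting
the scored pair set. This is deliberate and first-class; applying a table at
a lower interval than it was built with often changes performance
substantially, and the evaluation module sweeps all 16 intervals on request.

The default parameter grid is 6 reference states × 18 cutoffs (5–22 Å) ×
16 intervals (0–15) = 1728 potentials, 288 per reference state.

## Reference states

The denominator f_ref is the expected pair-distance distribution absent
specific interactions. Six classic models are implemented:

| kind | reference distribution |
|---|---|
| `ave` | pooled distance distribution over all pair types, shared by every pair |
| `kbp` | quasi-chemical: expected counts χ_i·χ_j·N_tot(r), with χ the mole fractions of the atom types over the whole training set |
| `dfire` | finite ideal gas: bin probability grows as r^α with α < 2 (default 1.61; α = 2 would be the unconfined ideal gas) |
| `dope` | spherical non-interacting: two points uniform in a ball whose radius is set per training structure |
| `rw` | ideal random-walk (Gaussian) chain of rigid step length L (default 3.8 Å, the Cα–Cα virtual bond) |
| `srs` | atom-shuffled: atom identities permuted uniformly over each structure's fixed atomic positions, pairs recounted |

Notes on the individual models:

- **kbp** admits two algebraic forms. The per-pair normalized form collapses
  onto the pooled distribution; the energy therefore uses the un-normalized
  expected-count (quasi-chemical) form
  u = −ln[(N_ij(r)+pc) / (χ_i χ_j (N_tot(r)+pc·167²))], and the reference
  object retains χ and N_tot to make that possible.
- **dfire**'s bin mass is the exact integral (hi^(α+1) − lo^(α+1))/(α+1)
  over each bin rather than a midpoint value — the 3 Å-wide first bin makes
  the midpoint rule ~15% biased there. `fit_alpha` estimates α from the
  pooled counts by a log-log least-squares slope over the uniform-width bins
  (the first bin is excluded: different width, hard-core effects), clamped
  to (0, 2).
- **dope**'s per-structure sphere radius is R_s = √(5/3)·R_g, exact for a
  uniform ball; per-structure bin masses come from the closed-form CDF of
  the uniform-ball pair-distance density
  p(r|R) = (3r²/R³)(1 − 3r/(4R) + r³/(16R³)), and structures are mixed with
  pair-count weights n(n−1)/2.
- **rw** conditions on sequence separation: the Gaussian-chain density
  P_n(r) = 4πr²(3/(2πnL²))^{3/2}·exp(−3r²/(2nL²)) is mixed over the training
  set's separation profile (the histogram records pair counts per
  separation), with same-residue pairs folded into the one-step term, and
  renormalized over the bins below the cutoff. Bin masses use the erf-based
  closed-form CDF.
- **srs** draws one uniform permutation of type ids per structure and round
  from a seeded generator; identical seeds give bit-identical references.
  A hook for injecting the permutation exists so the degenerate identity
  shuffle (which must reproduce the observed distribution exactly) is
  testable.

Closed-form CDFs were preferred over adaptive quadrature for the dope and rw
bin integrals because they are exact, faster, and easier to test — the test
suite still cross-checks them against numerical quadrature.

## Numerical choices

- **Pseudocount**: 1.0 per (pair, bin) cell by default, applied identically
  to the observed distribution and to the count-based references (ave, kbp,
  srs). This guarantees finite energies on sparse data and the identity law
  "identical counts ⇒ zero energy". Analytic references take no pseudocount;
  their bin masses are floored at 1e-12 before normalization (relevant only
  for dope when the cutoff exceeds a small training structure's sphere
  diameter).
- **Bin boundaries**: half-open [lo, hi); a distance exactly at the cutoff
  is excluded. Distances below 3 Å land in bin 0, not discarded.
- **Altloc policy**: highest occupancy wins, ties prefer altloc 'A'.
  Nonstandard residues (including MSE) and OXT are skipped, not remapped.
- **Z-score** uses the population (divide-by-n) standard deviation; at the
  decoy-set sizes of interest the sample/population distinction is
  negligible.
- **R1-num tie rule**: the native must be *strictly* lowest; ties count as
  failure (conservative; ties are essentially impossible with float
  energies).
- Sets with undefined Z or PCC (fewer than 2 decoys, zero variance) are
  dropped from aggregate means with a logged count, never imputed.

## TM-score

Decoys are trimmed to the native sequence before scoring, so CA
correspondence is positional and no alignment search is needed. The score is

    TM = max over superpositions of (1/L)·Σ_i 1/(1 + (d_i/d0)²),
    d0 = 1.24·(L−15)^(1/3) − 1.8, clamped at 0.5 Å,

maximized by the standard iterative scheme: Kabsch superpositions seeded
from contiguous fragments (lengths L, L/2, L/4, every start position), then
alternating inlier selection at distance d0 and re-superposition until the
inlier set repeats (cap 200 iterations; if fewer than 3 inliers remain, the
3 closest residues are used). The native's length sets d0, so the score is
asymmetric in its arguments. The implementation is deterministic; users who
need bit-compatibility with the published TM-score program can supply
precomputed two-column score tables instead.

## Synthetic data

The generator emulates the two inputs the framework needs — a training
corpus and decoy sets — without downloads:

- **Structures** are ideal α-helices built by natural-extension-reference-
  frame placement from standard bond lengths/angles and helical dihedrals
  (φ = −57°, ψ = −47°, ω = 180°), giving ~1.5 Å rise and ~100° twist per
  residue, with CB at ideal tetrahedral geometry (optionally OG/CG1/CG2 for
  SER/VAL to exercise more atom types). Sequences are uniform over the 20
  residues. Coordinates are rounded to 0.001 Å so written PDB files re-read
  bit-identically.
- **Decoy sets** take a clean helix as native and add i.i.d. Gaussian
  coordinate noise per decoy, with σ cycled through a ladder (default
  {1, 2, 4} Å). Noise preserves sequence identity, so TM-scores need no
  alignment.

What this does *not* emulate: real decoys are physically plausible
alternative folds with native-like local geometry, real training sets have
diverse secondary structure and packing, and real chains are far longer.
Passing the synthetic benchmark therefore demonstrates that the machinery is
correct and that the potentials rank graded distortions sensibly — not that
any particular reference state or parameter choice is optimal on real decoy
sets.

### Benchmark conditions

The end-to-end benchmark (tests and `scripts/acceptance.py`) trains ave and
dfire potentials at cutoff 8 Å, interval 3 on 50 synthetic structures of
15–40 residues, and evaluates them on 10 decoy sets of 30 residues with 20
decoys each over the {1, 2, 4} Å ladder. These sizes keep the whole pipeline
(including ~200 TM-score computations) at a few seconds while leaving the
expected outcomes — near-perfect native recognition, strongly negative
mean energy/TM correlation, and no worse recognition at application interval
0 than at 10 — far from their thresholds.

## Known limitations

- Single chain per model; inter-chain pairs and ligands are never counted.
- First MODEL only for multi-model (NMR) files; no mmCIF.
- No spline smoothing between bins and no per-atom energy decomposition.
- The rw reference mixes over separations with training-set weights; other
  published random-walk references average differently, so absolute energies
  (never the rank-based measures) may differ from theirs.
- The srs reference shuffles identities across the whole structure, not
  within residues.
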