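# Methods

This note documents the model, its parameters, the numerical choices, and
what the synthetic fixtures do and do not establish.

## Scoring terms

All statistical tables are derived from a user-supplied reference set of
(structure, native sequence) pairs by log-odds counting with +1
pseudocounts. Pseudocounts are used everywhere so that small reference
sets — including the synthetic test libraries — can never produce
infinite energies.

**Burial.** A residue's burial is the number of other residues whose Cβ
lies within 14 Å of its Cβ (glycine uses Cα). The counts are discretized
into 7 states; the state boundaries are the equal-frequency (7-quantile)
boundaries of the pooled neighbour counts of the reference set, made
strictly increasing by an ε bump when quantiles coincide on small sets.
The energy is E(s,a) = −ln[(N(s,a)+1)/(N(s)·f(a)+1)], with f(a) the
reference set's amino-acid frequency. The alphabet's three defining
choices (Cβ atoms, 14 Å, 7 states) are fixed; the boundaries and table are
derived quantities, so they adapt to whatever reference set the user
supplies.

**Secondary structure.** The same log-odds construction over the 7 STRIDE
states {H,G,I,E,B,T,C}. STRIDE's lower-case bridge code `b` maps to B;
any unknown code maps to coil.

**Contacts.** A distance-dependent pairwise potential with the DFIRE
distance-scaled ideal-gas reference state:
E(a,b,r_k) = −ln[N(a,b,r_k) / ((r_k/r_ref)^α · N(a,b,r_ref))], α = 1.61,
bins of 0.5 Å up to the 14.5 Å reference distance (29 bins; bin midpoints
as r_k; the last bin is the reference, where the energy is 0 by
construction, and E ≡ 0 beyond it). Counts are symmetrized in (a,b).
Pairs require sequence separation |i−j| ≥ 2: nearest-neighbour backbone
contacts are geometry, not sequence signal. Two flavours are kept
separately — Cα atoms and side-chain centroids (unweighted mean of the
side-chain heavy atoms from Cβ outward; a mass-weighted variant would be a
one-line change in `structio.read_structure`).

**Length independence.** Raw contact energies grow with chain length. At
model-build time the mean random-sequence energy is regressed linearly on
L over the reference structures (requires ≥3 distinct lengths) and the
fitted trend is subtracted. The coefficients are fitted, not hard-coded,
because they depend on the derived tables.

**Profile.** The target is aligned against every library structure with a
TM-align-style heuristic: seed alignments from gapless threading (top
offsets ranked by TM-sum after one superposition) and from matching
secondary-structure elements in order, each refined by alternating Kabsch
superposition on the current pairs with semi-global dynamic programming on
the proximity matrix 1/(1+(d_ij/d0)²), gap penalty −0.6, until the pair
set is stable (≤30 iterations). The TM-score itself is maximized over
superpositions by the standard fragment-seeding/close-pair-iteration
search, with d0 = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å and L the target
length. Analogs at TM-score ≥ 0.4 (inclusive) contribute aligned residues
to an L×7 count matrix over the reduced classes (negative {D,E}, positive
{K,R}, aromatic {F,W,Y}, histidine {H}, hydrophobic {A,V,L,I,M,P}, small
polar {G,S,T,C}, large polar {N,Q}); rows are normalized with +0.5
pseudocounts per class. The target's own sequence is never added to its
profile, to avoid trivial self-bias. The background is the class
distribution implied by the amino-acid frequency table, so an
uninformative profile scores exactly 0 for every sequence. Profiles
computed by external aligners can be imported as TSV.

**Anti-grouping.** Per residue class c, O_c counts near-neighbour
position pairs (window k = 1, i.e. adjacency; wider windows available)
whose members both belong to c. Under random permutation of the fixed
composition, E_c = n_c(n_c−1)/L and V_c follows from exact combinatorics
of the pair-pair overlap structure (pairs sharing an index vs disjoint),
so no Monte Carlo is needed at any composition; compositions whose count
is deterministic (V_c = 0) contribute nothing. The penalty is
Σ_c max(0, (O_c−E_c)/√V_c) — one-sided, because only excess clustering is
an optimization artifact; dispersion below expectation is harmless. The
statistic is applied over the whole chain by default (a per-segment
variant can be composed by the caller by slicing sequences).

## Combination and calibration

Terms live on incompatible scales, so each is z-normalized against
n_random (default 200, minimum 30) random sequences drawn from the
background amino-acid table *for the specific target structure*, and
oriented so larger = more native-like (energies and the clustering
penalty flip sign; the profile log-ratio does not). The combined score is
fitness = 1 + Σ w_t z_t with w on the probability simplex, which anchors
the expected random-sequence fitness at 1.0 for every target and makes
fitness comparable across targets. Per-structure calibration also makes
the fitness invariant to adding any constant to a raw table.

Weights are optimized on cases of (structure, native, decoys) — decoys
half shuffled natives, half random background sequences — by maximizing
the mean over cases of (f_native − mean f_decoy)/sd f_decoy with projected
coordinate ascent from the uniform start over a fixed step schedule
(0.2 … 0.01). The objective is scale-free in w, deterministic, and returns
uniform weights with a warning when no move improves it. Uncalibrated
models default to uniform weights.

## Optimizer

Geometric cooling: T ← T/MU_T from T_INITIAL = 5000 down to
T_MIN = 0.005 with MU_T = 1.002 gives 6,915 temperature levels;
ITERS_FIXED_T = 2000 Metropolis iterations run at each level, for
13,830,000 iterations per default run. N_TRIES = 200 is retained in the
schedule for fidelity to the stock parameter set but does not multiply
the iteration count: the level × iterations product is the documented
per-run workload, and treating N_TRIES as a further multiplier would give
~2.8×10⁹ iterations, contradicting it.

Moves are single-point substitutions: position uniform, replacement drawn
from the background table conditioned on differing from the current
residue. Acceptance is Metropolis on Δfitness (maximization):
always if Δ ≥ 0, else with probability exp(Δ/(kT)). A single MT19937
stream, seeded with the generator's classic `init_genrand` recurrence
(default seed 5489, the reference implementation's default), drives the
start sequence, every proposal and every acceptance draw; the raw stream
is bit-identical to the reference implementation, so runs reproduce
exactly across platforms and one run per start suffices.

The inner loop uses incremental evaluation: per-position burial/SS/profile
deltas are table lookups, contact deltas sum over the precomputed
neighbour list of the mutated position, and the clustering term updates
O/E/V for the two affected classes from a precomputed moments table in
O(window). Accumulated raws are refreshed by a full recomputation at each
temperature level, bounding float drift; incremental and full evaluation
agree to 1e-9 (tested property). The returned sequence is the best seen
at any point, not the final state.

## Synthetic fixtures

The fixture generator produces ideal α-helices (rise 1.5 Å, radius
2.3 Å, 100°/residue), antiparallel strand pairs (4.8 Å apart, 3.3 Å
rise, two-residue turn), jittered copies (isotropic σ = 0.3 Å), mixed
libraries of both, and "homolog" families (jittered structures carrying
point-mutated copies of the native sequence, default 30% mutated).
Native sequences are drawn from the bundled UniProtKB/Swiss-Prot
amino-acid composition (release 2013_04 statistics; user-overridable,
since composition drifts slightly between releases), biased toward
A/L/E/K on helices and V/I/T/Y on strands. Side-chain centroids sit
0.8–2.5 Å beyond Cβ along the outward axis, scaled by residue size.

These fixtures exercise distance binning, burial counting, alignment,
profile accumulation and the optimizer exactly; they are *not* physically
realistic decoys. Passing tests therefore establish the correctness of
the machinery (tables equal brute-force recounts, the annealer finds
enumerable optima, profiles recover planted signal), and the qualitative
regressions (native beats shuffled, identity rises under an informative
profile, the anti-grouping term suppresses runs), but say nothing about
design quality on real folds, which depends on reference libraries of
real structures.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at desk scale chosen for tight sampling error at
interactive runtimes: the fitness anchor uses a 60-residue helix, a
10-structure library, and 200+200 random sequences; the exhaustive
annealing check enumerates all 3¹⁰ sequences of a 10-residue target over
a 3-letter alphabet and runs 20 independent annealer seeds; discrimination
and suppression regressions use 30 and 4 fixture cases respectively.

## Known limitations

- The aligner is a TM-align-style heuristic, not a port of a fragment
  library aligner; on hard topologies it can undershoot the best
  attainable TM-score (any external aligner's profiles can be imported
  instead).
- Single-chain, single-conformer inputs only; the first MODEL of
  multi-model files is used; mmCIF is not read.
- STRIDE itself is not run; assignments are read from its output format
  (fixtures carry their own labels).
- The default full schedule in pure Python takes hours for real-protein
  lengths; the engine is intended to be driven with custom schedules where
  wall-clock matters.
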