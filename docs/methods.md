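# Methods

This note records the model as implemented, the defaults and why they hold,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Coarse-graining and interface definition

Each amino acid is reduced to its Cα coordinate; each nucleotide to either
its base C5 atom or its backbone phosphate P. The representative DNA atom
kind is chosen per complex by counting DNA-atom/Cα pairs within 8, 9 and
10 Å and summing the three counts; the kind with the larger sum wins. The
rationale is that atoms sitting closer to the protein carry more
information about the interaction, and the three-shell sum makes the vote
robust to the exact cutoff. Ties prefer C5 (base atoms carry base identity)
and are logged. Pair counting, rather than counting unique DNA atoms per
shell, is used; the two differ only in degenerate geometries.

Interface membership is a hard 8 Å cutoff on representative atoms: a bead
is at the interface if any cross-molecule bead lies within 8 Å. The soft
switching weight Θ is applied *on top of* interface pairs, so a pair at
7.9 Å contributes ≈0.51 and one at 8.1 Å contributes nothing. Altlocs take
the first location; insertion codes are kept in residue labels; waters and
unmapped hetero residues are ignored; modified residues resolve through a
user-extensible table (5-methyl-cytosine → DC ships by default). All
protein chains are pooled, so homodimers contribute both protomers'
interface residues.

## Energy model and training

Binding energy is linear in the 20×4 contact-count features:
E = Σ γ(a,n)·φ(a,n), φ(a,n) = Σ_pairs Θ(r_ij). The switching function

    Θ(r) = ½·tanh(κ(r − r_min))·tanh(κ(r_max − r)) + ½,
    κ = 0.7 Å⁻¹, r_min = −8 Å, r_max = 8 Å,

is strictly decreasing on r ≥ 0, equals ½ at 8 Å and saturates to ~1 at
contact. The feature space is exactly 20×4 = 80; the flattened dimension is
a single module constant (`alphabets.N_FEATURES`) should a larger padded
variant ever be needed.

Training maximizes δE/ΔE, the native-vs-decoy energy gap over the decoy
energy spread. Decoys randomize interface positions i.i.d. uniformly over
the residue alphabet — DNA (1000 sequences) and protein (10,000 sequences)
in separate sets, never jointly; a composition-preserving shuffle mode
exists for users who want to control composition effects. Both decoy sets
are pooled into one A vector and one B covariance (the per-set option
remains available); with multiple training complexes, φ vectors from all
complexes would be pooled the same way.

The closed-form maximizer γ ∝ B⁻¹A is computed through the
eigendecomposition of B with trailing-eigenvalue replacement: eigenvalues
beyond the leading `n_modes` are replaced by the `n_modes`-th before
inversion. The default `n_modes=None` uses min(70, rank B) — 70 retained
modes is a good ceiling for an 80-dimensional feature space, but a decoy
set of low diversity can have rank below 70, and inverting at a
numerically zero eigenvalue would be meaningless; an explicitly requested
`n_modes` beyond the rank raises "insufficient decoy diversity".
Eigenvalues below 1e−12 of the largest count as zero. The Lagrange
multiplier of the constrained formulation is eliminated analytically and
never represented.

Gap training leaves the energy scale undetermined, so γ is normalized to
unit Euclidean norm with sign fixed by δE = Aᵀγ > 0 (decoys above natives);
all predicted energies are reduced units, and only rankings, ratios, and
correlations are meaningful. Affinities map to energies via
ΔΔG = RT·ln(ΔKd) with R = 1.98720425e−3 kcal/(mol·K) and T = 298.15 K by
default.

When quantitative affinity tables exist, `fit_gamma_selex` solves the ridge
problem γ̂ = argmin ‖Φγ − ΔΔG‖² + α‖γ‖² (α = 0.01 default) in closed form
(scikit-learn's Cholesky ridge, no intercept). The pseudo-inverse relation
γ = φ⁻¹ΔΔG is exactly this solve in the α → 0 limit; the regularizer
handles the rank deficiency that threaded features always have (a threaded
DNA target only varies the columns touched by the threading strand).

## Threading and strand selection

Threading substitutes target residue identities into the fixed structure;
distances never change, so predictions assume the target shares the
training complex's interface geometry — the method's central approximation
and its main known limitation. A 5'→3' DNA target is assigned to the
structural strand with higher full-strand sequence identity (ties:
forward, with a warning); the partner strand keeps its native sequence.
When orientation is unknown, both threadings are scored and the lower
(stronger) energy is reported, on the grounds that strong binders dominate
experimental signals.

## Genome scanning

An L-bp region yields exactly L − w + 1 window scores, w being the length
of the structure's threading strand. Each window is threaded under the
same strand-identity rule (applied per window when both strands span w);
windows containing N are reported missing rather than zero-filled, so
ambiguity cannot fake a strong call. Z-normalization uses 1000 randomized
decoy windows generated once per scan — not per position — with the decoy
seed recorded in the track metadata. The windowed average is centered and
truncated at the edges, with missing scores excluded from the mean; sites
are maximal runs of windowed Z below −0.75 (0-based half-open intervals,
BED convention). A `--both-strands` mode scores each window's reverse
complement too and keeps the per-position minimum. Proteins represented by
several partial structures are scanned per template; no fusion rule is
invented.

## Exported pair potential

The learned matrix enters simulations as W = γ / Σ|γ| (signs preserved,
Σ|W| = 1), attached to a tanh well between each amino acid and the DNA
phosphate site, V_PD(r) = (W/2)(1 + tanh(η(r₀ − r))), r₀ = 8 Å,
η = 0.7 Å⁻¹; η is a scalar steepness and W the 20×4 matrix. Companion
terms: Debye-Hückel screened Coulomb with ε = 78.0 (Coulomb constant
332.0636 kcal·Å/(mol·e²), charges in elementary units) and an excluded
volume wall 4ε(σ/r)¹² with σ = 4.0 Å. Because gap training fixes no
absolute scale, the kcal/mol prefactor multiplying W is a required user
input. Tables are (r, E, −dE/dr) with analytic forces — finite differences
of the energy column reproduce the force column to the truncation order of
the grid — and a self-describing header; the attachment site and all
parameters are recorded. Grids must exclude r = 0, where the Coulomb and
excluded terms diverge.

## Synthetic scenarios: what they emulate and what they don't

`synthfix` builds toy complexes with an exactly controlled contact count: DNA
beads on a 12 Å-spaced line, contacting protein beads placed 4.5-7.5 Å from
one DNA bead or near the midpoint of an adjacent pair (two contacts), all
offsets in the half-space away from the P pseudo-atoms so the
representative-atom vote resolves to C5; spectator beads are parked outside
every counting shell. Written as minimal PDB ATOM records (coordinates
pre-rounded to the format's 3 decimals), these fixtures round-trip through
any standard parser.

The planted-parameter scenario draws a unit-norm random γ*, then samples
"evolved" sequences from per-position conditional Boltzmann distributions
under γ*: DNA varied with protein fixed, and protein varied with DNA fixed,
mirroring the two decoy ensembles. The selection strength β = 2 (reduced
energy units) sits where selection is strong enough for the strong-binder
ensemble to be clearly displaced from the decoy mean yet soft enough to
retain graded preferences; in the linear-response regime
A ≈ β·B·γ*, which makes γ ∝ B⁻¹A a consistent estimator of the planted
matrix. Strong sets default to 200 DNA-varied plus 2000 protein-varied
sequences, matching the 1:10 decoy ratio so the pooled means weight the two
ensembles consistently. A single deterministic minimum-energy native, by
contrast, carries only which letter is best per position, not by how much,
and recovers the planted direction poorly — this is why the scenario models
evolution as a Boltzmann ensemble rather than as outright minimization.

The standard benchmark sizes are 30 protein beads, 16 nucleotides and 40
contacts for parameter recovery, and an 8-nucleotide strand for genome
scans (the planted motif is then the exhaustive argmin over all 4⁸ = 65,536
8-mers; for longer strands a per-position greedy argmin is exact because
threading energies are additive over window positions). Genome benchmarks
plant 20 motif copies in 100 kb of uniform-background sequence (a GC-content
knob exists because real genomes are skewed). Truth intervals record the
single scan position of each insertion, and the benchmark evaluates the
unaveraged Z track (window 1): an isolated w-mer shifts a 500 bp window
mean by only ~Z_min/500, so wide averaging — appropriate for ChIP-seq-style
peaks hundreds of bp wide — is not a meaningful readout for isolated
planted motifs.

These scenarios reproduce the *contact-count statistics* the model
consumes, and nothing else: no real interface geometry, no base-pair
complementarity constraint between synthetic strands, no correlated decoy
structure, no experimental noise model beyond optional Gaussian noise on
ΔΔG. Passing them demonstrates internal consistency of featurization,
optimization and scanning — not predictive accuracy on real structures,
which depends on how far a real target's geometry departs from the training
complex.

## Numerical conventions

Amino-acid rows are ordered alphabetically by one-letter code
(ACDEFGHIKLMNPQRSTVWY); nucleotide columns are DA, DT, DC, DG. Energies:
lower = stronger binding throughout; classification metrics therefore score
negated energies with "strong binder" as the positive class, and ROC AUC
uses midrank tie handling. The balanced PR AUC subsamples the majority
class to the minority size and averages over 20 seeded subsamples — an
interpretation, since balanced PR metrics have no single standard
definition. Correlation of constant vectors is reported as NaN rather than
raised. All randomness flows through named `numpy.random.default_rng`
generators; decoy sets, scenarios and tracks record their seeds.
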