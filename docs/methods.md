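# Methods

This note records the models implemented in `idpbench`, the choices made
where the underlying physics or conventions left room, and what the
synthetic test systems do and do not demonstrate.

## The bead-necklace model

Each residue of an intrinsically disordered protein (IDP) is a hard
sphere of radius 2 Å carrying a fixed integer charge in {−1, 0, +1}.
Consecutive beads are joined by harmonic bonds,

    U_bond(r) = (k/2)(r − r0)²,   r0 = 4.1 Å,  k = 0.4 N/m,

with the force constant converted to kT/Å² at the configured temperature
(0.4 N/m ≈ 0.972 kT/Å² at 298 K). Non-bonded pairs interact through an
extended Debye–Hückel potential that accounts for finite particle size,

    u_el(r) = λB z_i z_j exp(−κ(r − a_i − a_j)) / [ r (1+κa_i)(1+κa_j) ],

in kT, with λB = e²/(4πε₀ε_r kB T) the Bjerrum length (7.15 Å at 298 K,
ε_r = 78.4) and κ² = 8π λB n_salt the square inverse Debye length of the
1:1 background salt (1/κ ≈ 7.9 Å at 150 mM). Chain beads additionally
share a uniform soft attraction

    u_sr(r) = −ε (σ_c / r)⁶,   σ_c = 4 Å,  ε = 0.6 kT,

which equals −0.6 kT at closest contact. The published description of
the model fixes only the contact depth, not the functional form; the
r⁻⁶ dispersion form used here is the conventional choice in this model
family and is confined to one routine should another form be wanted.
Counterions — one per charged bead, opposite in sign, hard spheres of
radius 2 Å — are explicit and feel electrostatics and hard core only;
the short-range attraction is a residue–residue term. Added salt is
implicit (through κ) while counterions are explicit; the system is
exactly electroneutral by construction.

Degenerate inputs are rejected at construction: chains shorter than two
beads, boxes smaller than the contour length, negative salt, zero weight
on the single-particle move.

## Monte Carlo sampling

Canonical-ensemble Metropolis sampling in a cubic box with periodic
boundaries; the minimum image convention truncates the screened Coulomb
interaction. Coordinates are kept unwrapped — periodicity enters only
through minimum-image pair distances — so bonds and Rg need no
unwrapping logic.

Move classes and their relative weights:

| move | weight | amplitude (default) |
|---|---|---|
| single-particle translation (bead or counterion) | 17 | bead 1.5 Å, ion 5 Å |
| pivot rotation of the shorter chain segment | 1 | angle ≤ π/2 |
| rigid chain translation | 1 | 2 Å |
| slithering (reptation) | 1 | bond from Boltzmann density |

The single-particle class covers every mobile particle, so with the
17:1:1:1 class weights each particle is attempted with equal frequency
within the class. One cycle is defined as one attempted move per mobile
particle (a sweep). Displacement amplitudes are not part of the model
definition; the defaults above give roughly 35–60% acceptance for the
systems in the test suite and are configurable. Chains shorter than
three beads drop the pivot and slither classes (their weight is
renormalized away).

The slithering move deletes one end bead and regrows it past the
opposite end. The regrown bond length is drawn from the exact radial
bond density p(r) ∝ r² exp(−βk(r−r0)²/2) by inverse-CDF lookup, and the
corresponding bond-energy factor is divided out of the Metropolis
ratio. Regrowing at a fixed length r0 instead — a tempting shortcut —
is *irreversible* (the reverse move can never recreate a bond of length
≠ r0), violates detailed balance, and measurably compresses the bond
distribution; the ideal-chain validation below detects exactly this.
Charges are attached to residue indices, so slithering relabels
geometry, never the charge sequence.

Incremental energies: single-particle moves recompute one row of the
pair sum; pivot moves recompute segment-versus-rest cross terms only
(distances to the pivot bead are invariant under rotation about it);
rigid chain translations recompute chain–ion terms only (minimum-image
internal distances are translation invariant); slithering recomputes
the chain's full energy. A running total is updated from accepted
increments; the suite verifies the increments against full
recomputation to 1e−8 kT and the accumulated ledger against a fresh
summation to 1e−6 kT after hundreds of cycles.

The initial configuration is a self-avoiding random walk with bond
length r0 plus uniformly inserted counterions, with bounded retries and
a clear error suggesting a larger box on failure. The default box is
1.1× the contour length (N−1)·r0, with a floor of six bond lengths so
that very short chains (dimers, trimers) still fit comfortably. Runs are bit-reproducible given the
seed: one named PCG64 generator drives every stochastic choice.

## Validation against exact references

* **Ideal-chain limit.** With charges off, attraction off and the hard
  core shrunk to 0.01 Å, the chain is a phantom harmonic chain whose
  ⟨Ree²⟩ = (N−1)⟨b²⟩ with ⟨b²⟩ computed by quadrature of the radial
  bond density — an oracle entirely independent of the sampler. The
  suite also draws phantom chains directly (inverse-CDF bond lengths,
  uniform directions) and checks the same identity, plus a
  Kolmogorov–Smirnov test of the single-bond distribution.
* **Metropolis rule.** The acceptance frequency at ΔU = 1 kT is checked
  against exp(−1) within binomial 3σ over 1e5 trials.
* **Hard core.** Every sampled frame in every suite trajectory is
  checked for minimum-image pair distances ≥ 4 Å.
* **Salt screening.** A synthetic 50-mer with FCR = NCPR = 0.5 is
  simulated at 0 and 150 mM: the unscreened polyelectrolyte must be
  significantly more expanded (the benchmark set's Prothymosin α shows
  the same pattern, 72.3 → 44.6 Å). Suite-scale runs (2 replicates ×
  1500+5000 cycles per condition) give ≈34 vs ≈25 Å with pooled block
  errors of a few tenths of an Å.
* **Full protein.** Histatin 5 (24 residues, net +5 at pH 7, 150 mM) at
  2000+15000 cycles gives mean Rg 13.0 ± 0.14 Å against the 13.8 Å
  reference — inside the 5% model band plus sampling error. Longer
  production runs move the estimate little; the residual few-percent
  compression is within the model's own accuracy for its training
  peptide. Larger proteins (e.g. the 111-residue Prothymosin α with ~60
  counterions) need cycle counts far beyond what a test suite should
  spend and are left to explicit campaigns via the CLI.

## Charge assignment

The reference workflow assigns fixed bead charges from a short
constant-pH titration simulation. Because the endpoint is constrained
to {−1, 0, +1} anyway, `idpbench` replaces the stochastic titration
with deterministic Henderson–Hasselbalch rounding against the
Nozaki–Tanford intrinsic pKa table (D 4.0, E 4.4, H 6.3, C 9.5, Y 9.6,
K 10.4, R 12.0; N-terminus 7.5, C-terminus 3.8 — shipped as editable
YAML): a group whose mean charge at the given pH rounds away from zero
gets the full charge of its (de)protonated form. This is reproducible
and dependency-free and converges to the same fixed charges whenever
pKa values are more than ~0.3 units from the pH. His is therefore
neutral at pH 7 and +1 at pH 5; default pH is 7.

Termini: the published model description is ambiguous between counting
the termini as extra beads and merging their charges onto the terminal
residues. Both modes are provided. The default, `merged`, adds +1/−1 to
the first/last residue bead and clamps to {−1, 0, +1} with a warning
when the terminal residue is already charged — note this loses one unit
of net charge in that case (e.g. poly-Lys); `extra_beads` appends two
dedicated ±1 beads and preserves the exact net charge.

Descriptors follow the CIDER conventions: FCR = f₊+f₋ and
NCPR = |f₊−f₋| over side chains only (termini excluded), unweighted
mean Kyte–Doolittle hydropathy, proline fraction. Disorder scores are
accepted as external inputs, never computed.

## Benchmark dataset and statistics

The packaged fixture transcribes the 24-protein compilation of Baul et
al. as used for cross-model comparison: SAXS-derived experimental Rg
(uncertainty kept as *missing* when unreported, never zero) and four
model columns (scaling law, SOP-IDP, bead-necklace, Martini 2 with the
Stark corrections). Dual-valued cells are stored as two explicit fields
with the evaluation convention recorded on the table: comparisons use
35.5 Å for α-synuclein and the 150 mM bead-necklace value 44.6 Å for
Prothymosin α — the only choices consistent with the printed deviation
table. One printed cell (K23, scaling column) is inconsistent with the
printed deviations, the χ² totals, and the power law underlying the
column, all of which require ≈55.7 Å rather than the printed 54.7; the
fixture stores the corrected value with a comment. A two-peptide
extension fixture (KEIF 17.6 Å, Histatin-5 dimer 18.7 Å) ships
separately.

Per system the error is the signed percentage deviation
100(S−E)/E, rounded to integer only for presentation. Across systems a
model is scored by the modified Pearson χ² = Σ (E_i−S_i)²/E_i — the
plain unnormalized sum, which reproduces all six published totals
(15.4/7.1/7.6/17.8 and, without the longest tau construct,
13.0/8.8) within the rounding tolerance of the 0.1 Å printed inputs.
Leave-one-out χ² satisfies the exact identity
χ² = χ²_loo(p) + (E_p−S_p)²/E_p, which the suite asserts for every p.

Bias trendlines are ordinary least squares of the signed error on a
protein property. Alongside the line, the caption-compatible statistic
is the *signed correlation coefficient* r — a plain coefficient of
determination cannot be negative, and r is what reproduces the
published trendline numbers (e.g. 0.86 for Martini-simulated vs
experimental Rg, −0.25 for Martini error vs N); unsigned R² is reported
as well.

## Scaling law

Rg = A·N^ν. The canonical constants are recovered by a log-log fit to
the fixture's scaling column (A = 2.1334 Å, ν = 0.5896, reproducing
every printed cell to < 0.15 Å) and frozen as `CANONICAL_LAW`. Fitting
the *experimental* column instead gives ν ≈ 0.50 with R² ≈ 0.94 in log
space (0.93 from nonlinear least squares in linear space) — the data
set behaves like near-ideal random coils, not self-avoiding ones.
Whether the published R² of 0.93 was computed in log or linear space is
not stated; both fit spaces are implemented, log-log is the default
(it linearizes the model, the standard choice for scaling laws), and
both land within 0.02 of 0.93.

## Synthetic data

The generators exist so that every stage is testable offline with known
ground truth: sequences hit integer-exact FCR/NCPR/proline targets
(charged residues from {K,R}/{D,E}; His excluded so pH-7 targets stay
exact; a greedy palette fill approximates a Kyte–Doolittle target);
power-law datasets add lognormal multiplicative noise to an exact law
with N log-uniform over the benchmark's 24–441 range; phantom chains
are exact independent-bond samples. They deliberately do *not* mimic
real IDP sequence grammar (no dipeptide statistics, no charge
patterning), so passing tests demonstrate correctness of the machinery,
not transferability of the model to real proteomes.

## Problem sizes in the test suite

The suite's Monte Carlo runs use reduced cycle counts chosen as the
smallest sizes at which each qualitative claim is resolved beyond 3σ:
the phantom 10-mer (2000+30000 cycles), the charged 50-mer salt pair
(2×(1500+5000) per condition), Histatin 5 (2000+15000). Production
studies should use the published protocol (200,000 equilibration +
1,000,000 production cycles), which is the package default.

## Known limitations

* No enhanced sampling; very long chains at low salt equilibrate slowly.
* The energy loop is vectorized NumPy (O(N) per single-particle move,
  O(N²) for slither); hundreds of beads are practical, thousands are not.
* The merged-termini mode silently (well, with a warning) absorbs one
  unit of net charge when a terminal residue is charged.
* Charge regulation is absent by design: charges are fixed for the whole
  run, matching the model being benchmarked.
* The scaling law and the statistics operate on printed, 0.1 Å-rounded
  table values; totals inherit that rounding (±0.3–0.5).
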