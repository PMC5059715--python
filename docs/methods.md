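# Methods

## The reduced model

`cphmc` represents a titratable protein region as an Ising-like system of
binary degrees of freedom: a deprotonation bit `d_i` per titratable site, an
occupancy bit per ion-binding term and an activity bit per conformational
flag. The energy of a microstate, in kT at a single fixed temperature, is

    E(x) = Σ_{u<v} J_uv q_u q_v
         + Σ_b occ_b (μ_b + Σ_u K_bu q_u)
         + Σ_c act_c (ε_c + Σ_u g_cu q_u + Σ_b h_cb occ_b)
         + Σ_i d_i ΔG_i

where `q_u` is the instantaneous charge of a charge centre: an acid carries
0/−1 (protonated/deprotonated), a base +1/0, and a *fixed charge* (e.g. an
arginine held charged) a constant integer. Fixed centres may appear in the
pair couplings and in the binding/flag couplings, where they contribute
constant fields; they never titrate. `ΔG_i` is a per-site offset applied to
the deprotonated state; because the apparent pKa of an otherwise isolated
site is exactly `pKa_ref + ΔG/ln 10`, these offsets are the calibration
knobs and the model-compound reference pKa's are never touched.

pH enters only through the sampling weight, never the energy:

    P(x | pH) ∝ exp(−E(x)) · Π_i 10^{ d_i (pH − pKa_ref,i) }

the semi-grand ensemble in which proton counts fluctuate at the chemical
potential set by pH and the reference pKa. Histidine is treated as a single
macroscopic two-state site (no tautomer resolution), which is the level at
which macroscopic pKa tables are defined.

For any system with ≤ 20 binary degrees of freedom, `enumerate_states`
computes the distribution exactly (the energy is quadratic in the bits, so
all 2^n states are evaluated vectorially). The enumerator is the oracle
against which the sampler, the toy-model calibration and several analysis
functions are tested.

## The sampler

`run_fixed_ph` performs single-bit-flip Metropolis Monte Carlo. One *sweep*
attempts one flip per degree of freedom in randomized order (move weights
can re-weight the per-class attempt rates; stationarity is unaffected and is
tested). Deprotonation of site k is accepted with
`min(1, exp(−ΔE + ln10·(pH − pKa_ref,k)))`, reprotonation with the
reciprocal exponent, occupancy/flag flips with `min(1, exp(−ΔE))`. The
local field `h + Qx` is updated incrementally, so a flip costs O(n_bits).

`run_ph_replica_exchange` runs one replica per pH on a strictly increasing
ladder; every `exchange_interval` sweeps, either the even or the odd set of
adjacent pairs (strictly alternating) attempts configuration swaps, accepted
with `min(1, 10^{(pH_i − pH_j)(D_j − D_i)})` where `D` is the replica's
total number of deprotonated sites. This is the Metropolis criterion
obtained from the semi-grand weights when two replicas exchange
configurations. Exchange attempts and acceptances are recorded per
neighbour pair; the acceptance ratio is reported as a diagnostic, never
asserted to a target, because it is a property of the system and ladder
spacing. Swapping configurations versus swapping pH labels are equivalent
views; the implementation swaps configurations and keeps per-pH series.

Randomness: one master `numpy.random.SeedSequence(seed)` spawns one child
stream per replica plus one for swap decisions, so results are bit-for-bit
reproducible and independent of scheduling. Default burn-in is 20% of the
sweep budget (only the tail of a run is analysed); it is configurable.

## Titration analysis

The unprotonated fraction S(pH) is a per-pH frame count; conditioning on a
per-frame boolean (e.g. "sodium bound this frame") produces microscopic
curves, and the macroscopic curve is exactly the frame-count-weighted
mixture of the two — an identity the code verifies to machine precision.
pH points with no qualifying frames are omitted from a conditional curve and
recorded; a condition satisfied nowhere at all leaves that branch empty
(`None`) rather than inventing a curve.

Fits use the generalized Henderson–Hasselbalch form
`S = 1/(1 + 10^{n(pKa − pH)})` by weighted least squares
(`scipy.optimize.curve_fit`), with points weighted by √(frame count) so the
uneven counts that arise under conditioning are handled consistently.
Bounds: pKa within the sampled pH range widened by 2 units on each side,
Hill n ∈ [0.2, 4]; the initial guess is the linear midpoint crossing with
n = 1. Both free-n and fixed-n (n = 1) fits are exposed, since published
tables often do not state which was used. A fit is flagged
`incomplete_titration` when max S < 0.9 or min S > 0.1 over the ladder —
the apparent pKa then extrapolates beyond the well-constrained range.
Fewer than 4 points, or a constant curve, is an error, not a fit.

The net-charge reconstruction treats a residue table of (pKa, kind) as
independent sites with n = 1: an acid contributes its mean charge
`−1/(1+10^{pKa−pH})`, a base its protonated fraction, fixed charges add as
constants. The sign-switch pH is found by linear interpolation on an
evaluated grid (default step 0.05 pH). Per-frame net-charge curves report
the RMSF (population standard deviation over frames) as the error bar.
The reconstruction includes the two fixed arginines in the sensor set:
whether published net-charge figures include them is usually ambiguous, but
the reconstruction only reproduces the printed plateau values if they are
included, so inclusion is the default here.

## Geometry analysis

All cutoff rules are strict inequalities, following the usual caption
wording ("below 3 Å", "greater than 28°"): sodium is bound below 3.0 Å
from the nearest target atom (carboxylate oxygens of Asp163/Asp164, backbone
carbonyl O of Thr132 by default), a water oxygen is in the first shell below
3.5 Å of the nearest carboxylate oxygen, a helix frame is bent above 28°.
Binding probabilities are plain frame counts.

The gate radius of gyration is the unweighted (geometric) RMS distance of
the sidechain heavy atoms from their centroid; a mass-weighted variant
exists but is not the default, since "sidechain heavy atoms" alone does not
specify weighting. The helix bending angle is 180° minus the internal angle
of the Cα triple (default residues 152/163/174), i.e. deviation from
linearity, 0° for a straight helix. The hydrogen-bond criterion
(donor–acceptor < 3.5 Å, D–H···A > 150° when the hydrogen is present,
heavy-atom-only otherwise) is a standard convention, configurable.

Water density maps are water-oxygen counts per voxel divided by
(frames × voxel volume × bulk density), so voxel values are in units of
bulk water; the default bulk number density 0.0334 Å⁻³ is an external
physical constant (ambient liquid water), overridable. Total counts are
conserved by construction and tested. Maps can be written as OpenDX text.

Superposition is least-squares rigid (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`). PCA runs on flattened
Cα coordinates after iterative superposition onto the running mean until the
mean moves < 1e−6 Å RMS (single-pass alignment is a special case; iterative
is the default because the alignment reference should be self-consistent).
Eigenvalues are clipped at zero, modes are orthonormal, variance fractions
sum to 1, and projecting onto all modes reconstructs the centred coordinates
to 1e−8 Å.

PDB conventions: residue numbers are kept exactly as in the file (1-based);
MODEL records become frames with 0-based indices; alternate locations keep
the highest occupancy, ties broken toward 'A'; insertion codes are
preserved; waters are recognized by a residue-name dialect list (HOH, TIP3,
WAT, SOL, ...) and sodium by NA/SOD. Reading and writing go through
MDAnalysis. Binary trajectory formats (DCD/XTC) are out of scope; XYZ text
trajectories are supported.

## The calibrated reduced NhaA model

`build_nhaa_toy_model()` assembles 12 titratable sites (the eight-residue pH
sensor plus the Asp133/Asp163/Asp164/Lys300 core), two fixed arginines
(Arg81, Arg250), one sodium-binding term and two flags (`gate_open`,
`tmv_bent`) — 15 binary degrees of freedom, small enough for exact
enumeration.

Calibration proceeded once, by enumeration, and the resulting constants are
frozen in `cphmc.nhaa`:

- sensor sites get offsets `ΔG = ln10·(pKa_target − pKa_ref)` placing each
  at its tabulated macroscopic pKa (acids 2.6–3.3, histidines 6.3–6.9,
  Lys249 at 11.2);
- the Asp163–Lys300 salt-bridge coupling J = 2.76 kT raises the unbound
  Lys300 apparent pKa to 11.6 and lowers Asp163 toward 2.4;
- the sodium term (μ = 1.0 kT) is favoured by charged Asp163/Asp164
  (K = 3.0 / 2.0 kT) and disfavours a charged Lys300 (K = 5.76 kT), fixing
  the bound-state Lys300 apparent pKa at 8.9; occupancy therefore rises
  with pH, from ~0 below pH 4 to > 0.9 above pH 11;
- `gate_open` (ε = 1.5 kT, coupling 2.5 kT to Asp164's charge) titrates
  from ~0.18 to ~0.73 across the Asp164 transition; `tmv_bent` (ε = 0.5 kT,
  3.0 kT against a charged Lys300, −1.0 kT per bound sodium) tracks Lys300
  deprotonation.

These numbers are calibration outputs of this reduced model — tuned values,
not measured constants. The Lys300 conditional-pKa targets (11.6/8.9) and
the two-decimal offsets reflect a deliberate choice to make the reduced
model's conditional titration land on round reference values; the qualitative
structure (salt bridge raises the pKa, sodium binding lowers it by ~3 units,
gate follows Asp164, bend follows Lys300) is the point, and it is what the
tests assert.

## Synthetic data

Generators plant known truth and emit a JSON manifest recording it. They
emulate: independent Bernoulli protonation frames along prescribed Hill
curves, optionally as a two-population mixture driven by a per-pH condition
frequency; an idealized Cα helix (rise 1.5 Å, radius 2.3 Å) with a rigid
planted kink; a gate scene with the five gate sidechain atoms placed on a
ring of exactly the target radius of gyration, shell waters at prescribed
distances and placed sodium ions; and trajectories with planted PCA
variances over an isotropic background. The helix twist defaults to
1080/11 ≈ 98.18°/residue so that the canonical probe residues (11 apart)
share helical phase and a straight helix measures exactly 0°; the textbook
100°/residue twist is available and leaves a small (~3°) phase residual on
the probe triple.

What the generators do *not* emulate — and hence what passing tests do not
show about real data: frames are independent draws (no autocorrelation in
time), protonation and geometry are generated separately (no
protonation-conformation coupling in the synthetic trajectories), scenes
contain no lipids and no realistic packing, and noise is isotropic Gaussian.
Conclusions about sampler correctness rest on the enumeration oracle, not on
the generators.

## Problem sizes and numerical choices

Default analysis-scale runs use thousands of sweeps across tens of pH
conditions (seconds); the sampler-versus-oracle equivalence checks use 10⁶
sweeps on systems of 3–10 bits, where the empirical joint distribution
matches enumeration to total-variation distance < 0.01. The model-compound
benchmark uses 5×10⁴ recorded sweeps per pH over pH 8.5–12.5 in 0.5 steps
and recovers the lysine reference pKa of 10.4 to ±0.05 across seeds.
Mixture-recovery checks use 4–5×10³ frames per pH, which puts binomial noise
well below the ±0.15 tolerance on the planted microscopic pKa pair.

Tie-breaks and degenerate inputs: a Metropolis move with ΔlogW = 0 is always
accepted (hence a lone site at pH = pKa_ref alternates deterministically —
still the correct stationary distribution); constant titration curves and
zero-variance trajectories raise instead of fitting; empty conditional
curves are omitted per pH and an all-empty condition is an error (or a
`None` branch in the conditional decomposition); coincident Cα atoms make
the bending angle undefined and raise.

## Known limitations

- The model is a reduced, discrete-state caricature: no atomistic
  energetics, no implicit-solvent model, no continuous titration
  coordinates, no tautomers, no temperature dependence.
- Apparent pKa's of the calibrated model away from the calibrated
  conditions (e.g. the macroscopic Lys300 value, which mixes bound and
  unbound populations) are emergent and not individually tuned.
- The crystal-structure gate-Rg checks need the real coordinate files,
  which are not bundled; without them those two tests fail with an
  explanatory message rather than silently passing.
- The exchange-acceptance ratio of the reduced model's ladders differs from
  what an all-atom simulation with the same ladder would show; it is
  reported, not asserted.
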