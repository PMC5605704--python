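# Methods

## Model

The system is a Kremer–Grest bead–spring **ring polymer** of N monomers
(diameter a = σ) confined in a cylinder of diameter D, together with N_c
spherical **crowders** (diameter a_c = 0.3a) at volume fraction φ_c.  All
non-bonded pairs (monomer–monomer, monomer–crowder, crowder–crowder, and
particle–wall) repel through the Weeks–Chandler–Andersen potential

    U_WCA(r) = 4 ε_ij [ (σ_ij/r)^12 − (σ_ij/r)^6 + 1/4 ],  r < 2^(1/6) σ_ij,

and exactly zero beyond the minimum.  Diameters mix additively
(σ_ij = (σ_ii + σ_jj)/2); all interaction strengths are ε except the
monomer–wall strength ε₁₃, the experimentally varied knob (1–3 ε).
Consecutive monomers are bonded by the FENE potential

    U_FENE(r) = −(k r₀²/2) ln[1 − (r/r₀)²],   k = 30 ε/σ²,  r₀ = 1.5 σ,

whose combination with WCA gives a rest bond length ≈ 0.97 σ.  Units are
reduced throughout: lengths in a, energies in ε, times in τ₀ = σ√(m/ε),
temperature k_BT = ε.

**Wall.**  The production wall is a smooth cylinder: the WCA law with
parameters (ε_i3, σ_i3) acts on the radial gap d = (D/2 + σ_i3) − ρ, so a
particle center at ρ = D/2 sits exactly at pair contact (U = ε_i3) and the
force-free region ends 0.12 σ_i3 inside D/2.  This placement is what makes
the rescaled radial statistics come out on the conventional scale: monomer
centers effectively fill the nominal cross-section of radius D/2, a uniform
distribution gives ⟨r²⟩ = 0.5, the relaxed chain gives ⟨r²⟩ ≈ 0.4, and a
wall-adsorbed chain approaches (but does not exceed) 1.  An explicit
bead-built wall (staggered rings of σ-sized beads on the cylinder of radius
D/2 + σ₁₃, spacing configurable, default 1 a) is available where the wall's
sub-σ corrugation could matter; it is the default for the capped-box
profile experiments and an option elsewhere (it is costlier and slightly
shifts the accessible radius per species).  Caps always use the smooth
axial law on the gaps z + σ_i3 and (L − z) + σ_i3; periodic mode wraps the
longitudinal coordinate with period L and tracks integer image counters so
unwrapped coordinates are exact.

## Dynamics

Langevin dynamics with friction γ = 0.1 τ₀⁻¹ and the fluctuation–
dissipation noise ⟨W_i(t)·W_j(t′)⟩ = 6 γ k_BT m_i δ_ij δ(t−t′), integrated
with velocity-Verlet at Δt = 0.002 τ₀.  The thermostat is discretized as a
BAOAB splitting: the Ornstein–Uhlenbeck velocity refresh
v ← e^{−γΔt} v + √(k_BT/m (1−e^{−2γΔt})) ξ sits between two half-drifts,
inside the usual half-kicks.  This realizes the noise contract exactly at
the stationary point (the kinetic temperature equilibrates to k_BT with no
O(γΔt) bias) and reduces identically to symplectic velocity-Verlet at
γ = 0, which is what the NVE drift check exercises.  All species carry
mass 1: equilibrium averages are mass-independent.  Initial velocities are
Maxwell–Boltzmann at k_BT.

Forces are evaluated two ways.  A plain O(n²) summation over
`ringcrowd.potentials` is the oracle; the production path uses a Verlet
pair list (skin 0.25 a, rebuilt whenever any particle has moved more than
half the skin) built from a linked-cell grid sized to the crowder–crowder
cutoff, with monomer pairs collected by direct loop.  The two paths agree
to 10⁻¹⁰ per force component on every fixture; the pair-list path is what
the integrator calls.  Integration runs in compiled chunks; the noise
stream is a PCG64 generator seeded per replicate (seed + replicate index),
so runs are reproducible bit-for-bit for a fixed build.

## Initial conditions

The ring is built as a deterministic **accordion fold**: the chain runs up
and down M columns (M even, as many as fit) placed on a circle inside the
force-free radius, winding once around the axis per circuit, with vertical
and turn bonds near the rest length, every non-bonded pair ≥ 0.85 σ apart,
and one extra bead folded into the closing turn when N is odd.  A literal
closed helix cannot satisfy these clearances at large N (the fold back
places mirrored beads at identical heights), and cannot fit the shortest
capped boxes at all; the accordion does both.  Tiny rings that fit inside
the cross-section are built as a flat regular polygon.

Crowders are inserted uniformly at random over the accessible cross-section
and length, rejecting candidates closer than 0.9× contact to anything
placed before (spatial-hash accelerated).  Random sequential insertion
stalls near φ_c ≈ 0.3, so above φ_c = 0.25 crowders are inserted at reduced
diameter (scaled so the reduced packing is 0.25) and inflated to full size
over 14 stages of short, strongly damped relaxation runs (700 steps each at
Δt = 5·10⁻⁴, γ = 1).  N_c is computed from the nominal cylinder volume
π(D/2)²L; whether the reference work used nominal or crowder-accessible
volume is not stated there, and the nominal convention is recorded in every
run's config echo since it shifts the effective crowding slightly.

The box length is L = 3 R₀ for periodic production runs (R₀ = relaxed
chain span at φ_c = 0) and a configurable fraction of R₀ for capped boxes.
R₀ values are cached per (N, D): the (135, 5a) entry is the literature
value 26 a; the others — 34 a (135, 4a), 39.4 a (135, 3a), 13.2 a (60, 5a),
8.8 a (40, 5a), 4.3 a (20, 5a) — were measured once with this engine
(4 replicates of long crowder-free periodic runs) and frozen.

## Observables

Per frame, over monomers only:

- **R** — longitudinal span max(z) − min(z) after unwrapping z along the
  bonded path (an error is raised if the ring winds the periodic box).
- **⟨r²⟩** — mean squared transverse position rescaled by D/2; 0.5 for a
  cross-sectionally uniform distribution, → 1 for a wall-adsorbed chain.
- **⟨r_L·r_R⟩** — angular correlation of the two arms.  The ring is split
  at monomers 0 and ⌊N/2⌋; r_L and r_R are averaged independently over the
  monomers of each arm (splits excluded), so the statistic is the dot
  product of the two arm-centroid transverse positions (equivalently the
  mean over all cross-arm monomer pairs).  −1: arms coherently on opposite
  sides at the wall; +1: arms collapsed together at the wall; ≈ 0: arms
  intermingled or centered.
- **ρ(x)** — transverse density projected on a plane containing the axis:
  each monomer contributes its x- and its y-coordinate (azimuthal
  symmetry) rescaled by D/2; histogrammed on [−1, 1] (41 bins by default,
  enough to resolve wall peaks at desk-scale sample counts).  A folded |x|
  variant is emitted alongside, since either axis convention is defensible.

Replicates are frame-averaged after discarding the first 20% of frames
(equilibration; configurable — the equilibration criterion of the original
study is unstated), then ensemble-averaged with standard errors across
replicates (seed + k for replicate k).

**Organization states.**  The (⟨r²⟩, ⟨r_L·r_R⟩) plane is partitioned into
the five regimes: (iv) arm_corr > 0.1; (ii) arm_corr < −0.2 and
⟨r²⟩ > 0.8; (iii) |arm_corr| ≤ 0.1 and ⟨r²⟩ > 0.8; (iii′) |arm_corr| ≤ 0.1
and ⟨r²⟩ < 0.6; else (i).  The thresholds are qualitative reading of the
regime descriptions and are config-exposed — the regime boundaries are
smooth, model-dependent crossovers, not sharp transitions.  The "M-shape"
judgement for profiles is operationalized as: global maxima off-center
(|x| > 0.2) and a central dip of at least 5% of the peak height.

## Scale presets and problem sizes

The full study protocol (N = 135, L = 3R₀, 5·10⁷ steps, 16 replicates,
up to ~3·10⁴ crowders) is cluster-scale; the "paper" preset encodes it for
completeness.  The "desk" preset keeps the physics at single-CPU sizes:
N = 135 with 2·10⁶ steps and 4 replicates for crowder-free runs, and the
reduced crowded system N = 40, L = 1.5 R₀ (≈ 5·10³ crowders at
φ_c = 0.28) with shorter runs.  Adsorption onto the wall is a local,
fast-equilibrating phenomenon, so the reduced system reproduces the
⟨r²⟩ → 1 signature; quantities that depend on global chain relaxation
(e.g. the precise depth of the ⟨r_L·r_R⟩ minimum at φ_c ≈ 0.25) would need
the full protocol and are not asserted at desk scale.

## What the generator does and does not emulate

The synthetic systems reproduce the study conditions exactly as stated:
geometry, interaction table, crowder size and fraction, thermostat
constants, helico-folded start, random crowder placement.  They do not
emulate the biology the model abstracts: no replication, supercoiling,
polydisperse crowders, heterogeneous (big/small) monomers or transertion
tethering — the monomer–wall strength ε₁₃ is the single coarse-grained
stand-in for wall affinity.  Passing tests therefore validate the physics
of the coarse-grained model, not chromosome behavior in vivo.

## Numerical choices and limitations

- Tolerances: oracle-vs-production force agreement 10⁻¹⁰ per component;
  energy–force finite differences 10⁻⁶ relative; NVE drift < 10⁻³ over
  10⁴ steps; thermostat within 2% of k_BT.
- Bond overstretch (r ≥ r₀) and wall escape raise errors naming the step
  rather than clamping: silent clamping hides time-step instability.
- The measured relaxed span at (N = 135, D = 5a) is ~29–30 a, some 15%
  above the literature's ≈ 26 a, while ⟨r²⟩ ≈ 0.39 matches its ≈ 0.4.
  The span prefactor is sensitive to where the wall surface effectively
  sits (a bead-built, corrugated wall is effectively narrower than the
  smooth wall at the same nominal D) and to the span's extreme-value
  nature; the radial statistics pin the geometry better and were given
  priority in fixing the wall convention.
- Observables assume a single connected ring; arm statistics for even N
  exclude the two split monomers, giving N/2 − 1 pairs.
- The organization-state labels near regime boundaries are sensitive to
  the configurable thresholds; only well-separated regimes are asserted
  in tests.
- Narrow-channel bimodality is weaker here than the operational indicator
  expects.  In capped D = 3a boxes at L/R₀ ≈ 0.65 the annulus-normalized
  radial density shows a clear wall shell (≈ 2× the axis density) and the
  projected profile has off-center maxima (|x| ≈ 0.25–0.35), while
  D = 4a/5a keep a single central projected peak — the qualitative
  contrast is reproduced, with both wall models.  The projected central
  dip, however, converges to only ~3–4%, below the indicator's default 5%
  threshold, so the D = 3a "M"-shape test fails at the default setting;
  the threshold is left where it is and the gap is documented rather than
  calibrated away.
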