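# Methods

This note documents the models implemented in `iontrack`, their
assumptions, the tunable parameters and their defaults, the numerical
choices, and what the synthetic components do and do not capture.

## Hydrogen baseline (surrogate interaction data)

The package needs hydrogen-in-water interaction data as the substrate
for effective-charge scaling. Instead of shipping external
cross-section tables, it generates a closed-form surrogate
(`iontrack.baseline`):

* **Stopping power.** Above the stopping maximum, the relativistic
  Bethe formula for protons in water with mean excitation energy
  I = 75 eV at unit density. Below the maximum, a velocity-proportional
  power law S = 220 · E^0.45 keV/μm (E in MeV/u). The two branches are
  blended with a p-norm join S = (S_low⁻⁶ + S_high⁻⁶)^(−1/6); the Bethe
  branch is frozen at its turnover value (~0.093 MeV) below it so the
  join never sees the formula's unphysical collapse. A small
  multiplicative spline correction exp(q(ln E)) acts between 0.25 and
  1.8 MeV (log-amplitudes 0.020 at 0.45 MeV and 0.008 at 0.90 MeV,
  clamped to zero at both ends); plain Bethe with I = 75 eV is a few
  percent low there relative to evaluated stopping tables.

  The three free constants (low-branch coefficient, two spline
  amplitudes) were fixed **once**, by a grid search against published
  stopping-table anchors: the ~4 μm range of 0.25 MeV protons, the
  870 keV/μm scaled carbon stopping at 0.25 MeV/u, and the positions of
  the scaled stopping maxima of carbon (0.25 MeV/u) and neon
  (0.40 MeV/u). With the frozen values the package computes 4.00 μm,
  866 keV/μm, 0.251 MeV/u and 0.401 MeV/u. They were not revisited
  afterwards. The hydrogen curve that results peaks near 0.13 MeV at
  ~75 keV/μm (evaluated tables: ~0.08 MeV, ~82 keV/μm) — the shape
  below ~0.1 MeV/u is unconstrained surrogate territory.

* **IMFP and transfer spectrum.** Per-collision energy transfers follow
  a truncated inverse-square spectrum p(τ) ∝ τ⁻² on [10 eV, τ_max(E)],
  with τ_max the kinematic free-electron maximum 2 m_e c² β²γ² (floored
  at 30 eV). The total inverse mean free path is *defined* as stopping
  divided by the spectrum's analytic mean, so `imfp × mean transfer =
  stopping` holds to machine precision at every grid point. The
  spectrum shape is the simplest one with a realistic hard tail; only
  its mean is physically constrained.

* **Grid and interpolation.** 800 log-spaced points over
  0.001–300 MeV/u; queries interpolate log-log linearly and refuse to
  extrapolate. User tables loaded from TSV are validated (sorted,
  positive, duplicate-free) and get their transfer cutoffs re-solved
  from their own stopping/IMFP ratio.

## Effective-charge scaling

`iontrack.barkas` implements Z_eff = Z(1 − exp(−125 β Z^(−2/3))) with
β relativistic (amu rest energy 931.494 MeV — at 256 MeV/u, β ≈ 0.62,
a classical β would be off by ~20%). The scaling factor
F = Z_eff(Z)²/Z_eff(1)² multiplies the baseline stopping and IMFP at
the same energy per nucleon. The constant 125 and exponent −2/3 are
hard-coded; a configurable constant would silently break the printed
limits (F → Z^(2/3), F → Z², (Z_eff/β)² → 15 625 Z^(2/3)). Note that
the Z^(2/3) limit converges slowly: the leading correction is
~125 β (1 − Z^(−2/3)) per factor, about 1% at β = 10⁻⁴ and 0.1% only
below β ≈ 10⁻⁵. Energies below 0.01 MeV/u trigger a warning (nuclear
stopping, absent here, is no longer negligible there).

## Transport

Ions travel in straight lines (no lateral scattering, no nuclear
interactions, no projectile fragmentation). The slowing-down loop
alternates exponential free flights (mean 1/scaled IMFP) with sampled
transfers; a continuous residual deposit closes any gap between the
discrete-collision loss rate and the scaled stopping power (zero for
the packaged table by construction, nonzero for user tables whose IMFP
under-accounts the stopping). Collisions are processed in chunks sized
so rates drift < 1% within a chunk. Tracks end below 0.01 MeV/u (the
remaining kinetic energy is deposited at the endpoint) or on leaving
the 14.22 μm scoring sphere. Energy bookkeeping closes to machine
precision per track, and the measured mean loss per path length equals
the scaled stopping power within the sampling error — the central
transport invariant, checked for all six ions at 0.25, 1, 16 and
256 MeV/u at 2%.

**Electron kernel.** How a transfer splits between a local deposit and
the secondary electron is not constrained by the surrogate's sources:
here the first 40 eV stay at the collision point and the remainder is
placed at a displaced position with exponential radial scale
s(τ) = 0.05 μm · (τ/1 keV)^1.7 capped at 5 μm, isotropic azimuth,
forward-biased polar angle (cos θ uniform on [0, 1]). The constants are
declared tuning knobs chosen so that sub-50 eV transfers stay within
nanometres while the MeV-scale δ-ray tail can carry energy out of the
nucleus — reproducing qualitatively the ~20% LET-below-stopping-power
deficit of high-energy ions in this tangential-source geometry. One
deposit per electron; no angular physics is claimed.

**Ranges.** `compute_range` integrates dE/dx = −S deterministically and
applies the 10%-energy extrapolation rule (depth at which E has fallen
to 10% of its initial value, extended linearly to zero with the local
slope). `csda_range` integrates to the table floor. For the packaged
baseline the two differ by ~7% at 0.25 MeV (4.00 vs 4.30 μm for
protons) because the extrapolation cuts the sub-peak tail.

## Geometry and LET scoring

Nucleus: 10 μm sphere at the origin. Source: 80 μm² disc tangent at the
beam pole; 5 primaries per run started parallel from uniform disc
positions (fluence 0.0625 μm⁻² per run). Simulations run in the beam
frame; the per-run random source rotation is applied to the chromatin
model instead (statistically identical for a spherical nucleus, and
deposits are far fewer than chromatin voxels). Dose is the summed
in-region energy over the region's water mass; LET = D/(0.1602 φ).

For stoppers, the dose-averaging volume is the spherical cap at the
beam entrance. The cap height uses the **full** slowing-down path
length rather than the 10%-rule range: the Bragg-end deposits would
otherwise fall just beyond the cap and be lost from the average. The
frequently quoted identity "stopper LET ≈ deposited energy / range"
holds exactly only for a depth-uniform deposition profile (it then
follows from cap volume = fluence-weighted chord integral); with this
package's surrogate stopping, which decays faster at very low energy
than evaluated tables (no nuclear stopping), stopper profiles are
front-loaded and the identity holds only within ~30%. The test suite
asserts the exact identity on a uniform synthetic profile and a
0.5–1.1 band for simulated stoppers.

Local LET uses 50 slabs of 200 nm perpendicular to the beam, with
per-slab dose over the slab∩sphere volume and the run fluence; slab
energies close on the total in-nucleus energy exactly.

## Chromatin model and damage induction

The genome (default 6.4 Gbp diploid; configurable) is laid out as a
randomized walk on a 50 nm lattice, 5500 bp per voxel (midpoint of the
5–6 kbp chromatin-fiber element), occupying ~28% of the nucleus'
lattice cells. Chromosomes are 50–245 Mbp territories grown as
self-avoiding-ish walks: blocked walks resume from the most recent
voxel with a free neighbour; a fully enclosed territory (rare) starts a
fresh connected component. Genomic coordinates increase monotonically
along the walk; loop (100 kbp) and domain (1 Mbp) boundaries are
bookkeeping. DNA mass per slab is averaged over random rotations and
follows the analytic sphere-chord profile within 3%.

Break induction parameters (`DamageParams`):

| parameter | default | meaning |
|---|---|---|
| `f_dna` | 0.030 | P(deposit in a chromatin voxel strikes DNA) |
| `p_oh` | 0.25 | P(non-DNA deposit spawns an •OH surrogate) |
| `oh_step_um` | 0.012 | radical random-walk step (μm) |
| `oh_max_steps` | 8 | walk length (scavenging lifetime surrogate) |
| `p_deoxy` | 0.026 | P(deoxyribose encounter per chromatin voxel visit) |
| `k_max_radicals_per_voxel` | 12 | per-(voxel, track) cap on radical origins |
| `sb_to_dsb` | 0.01 | SB→DSB conversion probability |

Deposits striking DNA are projected onto the voxel's local walk
direction for a sub-voxel bp offset (preserving the spatial↔genomic
proximity needed by the 10/25 bp rules), strand by fair coin; energies
accumulate per (bp, strand) sugar–phosphate group per exposure and
break with the 5→37.5 eV linear ramp. Radicals that enter chromatin
voxels encounter deoxyribose with `p_deoxy`, and 65% of encounters
produce a break; the per-voxel origin cap emulates radical–radical
recombination in dense track cores, which is what makes the indirect
yield fall at high LET. The 1% conversion adds an opposite-strand
partner at the same bp.

The first five defaults were calibrated **once** against the standard
low-LET reference yields (direct ≈ 60, indirect ≈ 100, total ≈ 150–170
strand breaks Gy⁻¹ Gbp⁻¹ with > 60% indirect) using a uniform 1 Gy
synthetic exposure of the full-genome model (the calibration run gave
direct 60.6, indirect 105, total 166), and are not asserted by tests.
The radical walk is an 8-step caricature of the diffusion–reaction
chemistry: it reproduces the yield scale and the density suppression,
not reaction kinetics, species spectra, or time structure. Damage
yields per Gbp are approximately independent of the configured genome
length in the dilute regime, but tests that use reduced genomes probe
the rules, not absolute yields.

## Damage classification

Deterministic pipeline: (1) same-strand breaks at adjacent or equal
positions merge to the run's lowest position (idempotent); (2) greedy
DSB pairing — scan by ascending position, plus strand first on ties;
each unpaired break takes the nearest unpaired opposite-strand break
within 10 bp, ties resolved to the lower position then plus strand.
Greedy pairing is deterministic and order-independent after sorting and
agrees with a maximum-cardinality matching on ≥95% of random instances
(the matching bounds it from above). (3) DSB representative position =
floor of the pair midpoint; single-linkage chaining at ≤25 bp gives
clusters (≥2 members) and isolated DSB; sites = isolated + clusters;
cluster representative = mean of member positions. (4) Fragments are
gaps between consecutive same-track, same-chromosome site positions;
end pieces are not counted; a multiplicity-m cluster additionally
carries m−1 intra-cluster micro-fragments (≤25 bp) which never enter
the ≥60 bp bins. Inter-track fragments are excluded by construction —
the per-track definition matches the low-dose regime in which fragment
yields are reported.

Summary invariants, asserted as property tests: SB = SSB + 2·DSB;
DSB = isolated + clustered; sites = isolated + clusters; fragments per
chromosome per track = max(0, sites − 1); invariance under coordinate
translation and chromosome relabeling; idempotence under
reclassification of reconstructed break lists.

## Statistics and reproducibility

An experiment executes n independent runs from spawned children of one
seed (`numpy.random.SeedSequence`); identical configurations reproduce
byte-identical outputs. Reported values are means over runs with
uncertainties of twice the standard error of the mean (undefined and
reported as NaN for n = 1); the 2×SEM shrinks as 1/√n. Default run
counts in desk-scale tests (4–32 runs, 50–100 Mbp genomes) are chosen
as the package's own test conditions; the full-genome, 256-run
configuration is the supported production setting.

## Known limitations

* No nuclear stopping, projectile fragmentation, lateral scattering or
  energy-loss straggling beyond collision statistics; below ~1.5 keV/u
  (where nuclear stopping dominates for carbon) the model is outside
  its domain even though the table extends to 1 keV/u.
* Electron transport is a one-deposit displacement kernel, not
  event-by-event tracking; dose build-up and δ-ray angular structure
  are approximate.
* The chemistry stage is a parametric radical walk; absolute indirect
  yields inherit its calibration.
* The 256 MeV proton slowing-down integral gives 39.7 cm with the
  I = 75 eV Bethe branch, in line with standard CSDA tables (~39.4 cm
  at 256 MeV); quoted round figures of ~38 cm correspond to ~250 MeV.
* Charge-state-resolved cross sections, excitation/ionization channel
  splits, base damage, and repair are out of scope.
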