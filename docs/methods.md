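# Methods

`ppmoens` resolves the solution structure of peptide-conjugated morpholino
oligonucleotides (PPMOs) as a *population of conformers* rather than a
single structure. Four coupled analyses are implemented: geometric
structural metrics on conformer ensembles, deconvolution of a circular
dichroism (CD) spectrum into conformer weights, ensemble-averaged viscosity
prediction, and folding-thermodynamics bookkeeping. Synthetic generators
provide every input with known ground truth so the whole chain is testable.

## Structural metrics

**Base-fixed frames.** Each nucleobase gets a right-handed orthonormal
frame: origin at the unweighted centroid of the six-membered-ring atoms
(N1, C2, N3, C4, C5, C6), z-axis the unit normal of the least-squares ring
plane (SVD of the centered ring coordinates), x-axis the in-plane unit
projection of the centroid→C2 vector, y = z × x. C2 anchors the x-axis
because it exists in both purine and pyrimidine ring systems. Plane
normals from a fit are sign-ambiguous, so the inter-normal angle θ is
folded to [0°, 90°]; the normal's sign is fixed deterministically (largest
component positive) so signed z-displacements are reproducible.

**Stacks and pairs.** For bases k, j with mutual displacement d:
z_kj = d·ẑ_k (rise), ρ_kj = √(|d|² − z_kj²) (slide), θ the folded
inter-normal angle. Two bases are *stacked* iff

    (|z_kj| > 2 Å and |z_jk| > 2 Å) and (ρ_kj < 2.5 Å or ρ_jk < 2.5 Å)
    and θ < 40°,

and *paired* iff they are **not** stacked, θ < 60°, and at least one
base–base hydrogen bond links them (stacking takes precedence). All
cutoffs are strict inequalities; exact ties (measure-zero events) count as
non-interactions. The mixed and/or grouping of the stacking rule is
implemented exactly as written; it is symmetric under k↔j (the |z|
condition uses both orders, ρ uses "either", θ is symmetric), which the
test suite asserts on 10⁴ random frame pairs.

**Hydrogen bonds.** A D–H⋯A triple is a hydrogen bond iff the
donor–acceptor distance d_DA < 3.3 Å and the D–H–A angle exceeds 140°
(the community-standard angle convention; the criterion's angle vertex is
not universal, D–H–A was chosen). A hydrogen belongs to a donor when it
lies within 1.2 Å of it in the same residue. Donor/acceptor atom names
per residue kind ship as an editable YAML table
(`ppmoens/data/hbond_roles.yaml`): nucleobase amino/imino nitrogens and
ring/carbonyl/phosphorodiamidate acceptors, backbone amides, and the
arginine guanidinium. Potential donors without a bonded hydrogen are
skipped with a warning (emitted once per atom type to avoid log floods at
ensemble scale).

**Contacts and time fractions.** Two residues interact when their
all-atom mass-weighted centers of mass are closer than 7.5 Å. Interaction
maps over an ensemble report the exact rational fraction k/n of conformers
in which each residue pair interacts; variants restrict the COM to base,
backbone, or side-chain atom subsets, or require a hydrogen bond. Display
labels number nucleotides from the 3′ end (the 3′-terminal base is 1) and
peptide residues from the attachment point; internally everything is
1-based from the 5′ end.

**Scalars.** End-to-end distance X is the distance between the P atoms of
the first and last nucleotide. R_g is the mass-weighted radius of gyration
about the center of mass over all atoms (hydrogens included).

**SASA.** Solvent-accessible surface area uses the Shrake–Rupley
procedure: Bondi radii, probe 1.4 Å, 960 quasi-uniform test points per
atom on a golden-spiral lattice. A deterministic point lattice makes the
closed-form single-atom case exact (4π(r+1.4)²) and the output
reproducible; the implementation is cross-checked against an independent
Shrake–Rupley implementation in a unit test. Per-residue areas sum
exactly to the total.

**Ensemble pre-screening.** A greedy pass in ensemble order keeps a
conformer iff its dissimilarity to every kept conformer is at least the
threshold. The dissimilarity is pluggable (an eRMSD implementation can be
supplied); the default is the RMSD of base-frame origins after optimal
Kabsch superposition — cheap, rotation-invariant, and adequate for
redundancy removal, though it ignores base orientation.

## CD deconvolution

The observed mean-residue ellipticity is modelled as
Θ_th(λ) = Σᵢ wᵢ θᵢ(λ) with wᵢ ≥ 0, Σwᵢ = 1, where θᵢ are per-conformer
basis spectra (inputs; computing them from structures is out of scope).
The fit minimises MSE = (1/m) Σⱼ [Θ(λⱼ) − Θ_th(λⱼ)]² on a shared grid,
by default 200–330 nm in 1-nm steps (m = 131).

The simplex constraint is enforced by construction through a softmax
parameterisation wᵢ = exp(lᵢ)/Σ exp(lⱼ), and the unconstrained logits are
optimised with Adam (10,000 iterations; learning rate 0.05; β₁ = 0.9,
β₂ = 0.999, ε = 1e-8). The iteration count follows the published
protocol; the learning rate is a conventional choice that converges for
range-normalised spectra and is exposed in the config. For conditioning,
target and basis are internally mean-centred (by the target mean — valid
because Σw = 1 makes a common shift transparent) and divided by the target
range; the reported MSE is rescaled to the original units. Default 20
restarts with logits initialised uniformly in [−1, 1] from seeds
seed+0…seed+19; all restarts run vectorised. The best restart by MSE is
returned, and every restart is kept so the thermodynamic tie-break can be
applied: among candidates with MSE within 5% of the best (`mse_tolerance`,
the operational meaning of "similar MSE"), the one with the most negative
⟨ΔG⟩ = Σ wᵢ ΔGᵢ wins. Conformers with w ≥ 0.05 form the reported
ensemble; weight ties are broken by lower conformer index for determinism.

Verification: the fitted MSE is compared against a dense simplex grid
search (step 0.01) for three-component bases; noiseless synthetic targets
are recovered to < 0.01 L∞.

**Identifiability under noise.** Smooth Gaussian-band spectra are nearly
collinear as vectors even when pairwise cosines are modest, so with 10
components and noise at 5% of the target range the *exact* constrained
least-squares estimate can deviate by ~0.1 L∞ from the generating weights
— no optimizer can do better. Noisy-recovery guarantees therefore
presume well-separated basis spectra; the generator's `well_separated`
mode (below) realises that premise, and the noisy-recovery test uses it.

## Viscosity

The solution viscosity follows the Einstein/Huggins expansion

    η(C) = η_s (1 + [η] c + k_H [η]² c²),

with η_s the solvent viscosity (default 0.909 mPa·s, the y-intercept of
the experimental profiles; overridable), [η] the intrinsic viscosity in
cm³/g, k_H the dimensionless Huggins constant, and c the concentration in
g/cm³. User-facing concentrations are mg/mL as plotted experimentally;
the fixed ÷1000 conversion makes [η]·c dimensionless and is the only
convention under which the reported [η] values reproduce the reported η
curves. The ensemble average is [η]_th = Σ wᵢ ηᵢ / Σ wᵢ over the selected
conformers with their fitted weights (per-conformer ηᵢ are inputs, e.g.
from bead-model hydrodynamics).

With η_s and [η] fixed the model is *linear* in k_H, so the "non-linear
fit" reduces to an exact closed-form least-squares projection; unweighted
residuals on η are used (the weighting scheme is not specified; fitting on
η versus η/η_s changes nothing but a constant factor in the residuals).
Noiseless round trips recover k_H to machine precision. The dilute-regime
intrinsic viscosity fit is the least-squares slope through the origin of
η/η_s − 1 versus c.

## Thermodynamics

Per-conformer enthalpies H and entropies S (inputs, e.g. from an MM/GBSA
decomposition with normal-mode entropies) are differenced against an
unfolded reference record: ΔH_j = H_j − H_ref, ΔS_j = S_j − S_ref,
ΔG_j = ΔH_j − T·ΔS_j at T = 300 K by default. The reference-structure
construction is not reproducible here, so the reference is a required
input. Optional enthalpy components (E_int, E_C, E_vdW, E_p, E_np) are
carried and validated to sum to H but never computed. Distributions are
histogram probability estimates with edges aligned to multiples of the bin
width (default 10 kcal/mol; the published histograms do not state their
binning); probabilities are counts/total and sum to one exactly.

## Synthetic data

The generators emulate the statistical structure of the study inputs, not
their chemistry, and every one is a pure function of (config, seed).

* **Ensembles with planted truth.** Base rings sit at cluster anchors on
  a planar grid with 40 Å spacing, each cluster rigidly rotated with an
  out-of-plane tilt bounded at 8°. A planted stack is two parallel rings
  at 3.4 Å rise and < 1 Å slide; a planted pair is two coplanar rings 7 Å
  apart joined by an inserted N4–H4⋯O2 triple at d_DA = 2.9 Å, 180°.
  The geometry *guarantees* the truth: with anchors ≥ 40 Å apart, cluster
  extents ≤ 7 Å and tilts ≤ 8°, the elevation angle of any cross-cluster
  separation is ≤ ~10°, so the angle between a separation vector and any
  ring normal is ≥ ~72°, forcing ρ ≥ ~25 Å — an order of magnitude above
  the 2.5 Å stacking cutoff — while all cross-cluster atom distances stay
  far above the 3.3 Å hydrogen-bond cutoff. Backbone P atoms form a
  separate 6.1 Å-step self-avoiding random walk in their own region, so X
  and R_g fluctuate across conformers while the planted counts stay
  fixed. This decoupling of backbone and bases is chemically unrealistic;
  the ensemble is a geometric fixture for classifier validation, not a
  model of PPMO conformations. Default planted counts (4 pairs, 8
  stacks) sit inside the reported 4–6 pair / 5–11 stack regime; the
  default ensemble size is 5,500 conformers as in the study (tests use
  smaller explicit sizes).
* **Trajectories.** Single-bead residues at sites 25 Å apart; each
  scheduled pair is placed 5 Å apart (inside the 7.5 Å cutoff) with
  independent per-frame Bernoulli probability, else ≥ 20 Å away.
* **Basis spectra.** Rows are sums of 2–5 signed Gaussian bands, centers
  205–290 nm, widths 5–20 nm (echoing the 210/240/270 nm features of
  measured morpholino spectra), with pairwise cosine < 0.95 enforced by
  resampling. The `well_separated` mode stratifies each row's dominant
  band (one stratum per conformer, widths 4–6 nm, plus one weak
  overlapping band), keeping the row space well conditioned so that noisy
  weight recovery is statistically meaningful.
* **Observed spectra and viscosity curves** add i.i.d. Gaussian noise to
  the exact superposition/Einstein curve. The default viscosity noise,
  0.02 mPa·s, reflects ~2% instrument repeatability at the solvent
  baseline; the spectrum default is noiseless (noise is added explicitly
  where a test or user wants it).
* **Energies.** ΔH ~ N(−125, 40) kcal/mol and T·ΔS ~ N(−45, 30) kcal/mol
  (independent, T = 300 K), so ΔG is N(−80, 50): ±3σ spans reproduce the
  reported broad ranges (ΔH ≈ −250…0, ΔG ≈ −200…50 kcal/mol), and the
  T·ΔS center is consistent with the printed 22-mer values
  (ΔH = −86, ΔG = −49 ⇒ TΔS = −37 kcal/mol). Components are a random
  additive split of H. An optional compactness score induces rank
  correlation (more compact ⇒ more negative ΔH).

What passing tests on these fixtures shows: the classifiers implement the
printed rules exactly, the optimizer finds the constrained least-squares
optimum, and the fits invert the generating models. What they do not
show: robustness to real conformational disorder, force-field or
instrument systematics, non-Gaussian noise, or basis spectra whose
computation (out of scope) carries its own error.

## Problem sizes

Test and verification runs use sizes chosen for quick iteration while
keeping every statistical claim honest: ensembles of 3–20 conformers for
geometry (the classifiers are per-conformer and size-independent),
2,000-frame trajectories for Bernoulli time-fraction checks, 10-component
bases with 20 restarts × 10,000 iterations for CD recovery, 11-point
viscosity curves, and 5,500-record energy tables matching the study's
ensemble size.

## Known limitations

* The default prescreen dissimilarity is a base-origin RMSD, not eRMSD;
  the slot is pluggable but no eRMSD implementation ships.
* SASA is Shrake–Rupley, a deliberate substitution for the LCPO method
  used by the original MD toolchain; absolute areas differ slightly
  between the algorithms.
* The H-bond donor/acceptor tables are name-based, not base-specific:
  chemically impossible combinations (e.g. a protonated N1 on cytosine)
  are excluded only by the absence of the hydrogen, not by the table.
* `classify_stacking` implements the printed rule literally, including
  its unbounded |z| condition: two distant, coaxially aligned rings would
  count as stacked. The synthetic generator's layout bounds rule out
  such configurations; real trajectories conventionally restrict
  candidate pairs by distance first.
* MSE may be computed on mean-residue or raw ellipticity; the scale is
  the caller's responsibility (mean-residue by convention here).
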