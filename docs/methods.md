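# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user auditing results should know about.
Units are nm, ps and kJ/mol unless stated; event-scale times are ns.

## Coordinate conventions

All analyses assume orthorhombic boxes and membrane-centred coordinates:
the mass-weighted lipid centre of mass defines z = 0 in every frame
(`center_on_membrane`, idempotent, x/y untouched). The outward normal of
the upper leaflet is +z and of the lower leaflet is −z; angle-type analyses
flip lower-leaflet vectors so 0° always means "pointing out of the
membrane". Leaflet membership is the sign of the lipid P-atom z.
Inter-particle and lateral distances use the orthorhombic minimum-image
convention. Nonuniform frame spacing is rejected rather than resampled,
because the ACF and event algorithms assume one fixed Δt. Solute z series
are treated as continuous in time (never re-wrapped mid-event) and
leaflet-folded to |z| where profiles are built, which doubles sampling and
matches the symmetric treatment of the two leaflets.

## Partitioning

The positional density p(z) uses 0.1 nm bins by default. Per-bin 95%
bands come from blocking analysis of the bin-indicator series; the series
is pre-aggregated into ≤4096 contiguous chunks before blocking, which
keeps memory flat and leaves the plateau unchanged whenever the motion
decorrelates within a chunk (the intended regime; the chunk count is a
parameter).

Boltzmann inversion gives ΔG(z) = −RT ln[p(z)/p(z_eq)] with z_eq the most
probable bin; empty bins are masked (NaN), never ±∞. The water/membrane
interface defaults to z_w/mem = 4.0 nm, where the profile becomes flat.

The **water plateau** ΔG(z_w) is defined as −RT ln⟨e^{−ΔG(z)/RT}⟩ over the
sampled bins beyond z_w/mem — i.e. the pooled water density converted to a
free energy. Averaging the per-bin ΔG values instead (the log of each
density) carries a Jensen bias of order half the squared relative bin
fluctuation; with correlated sampling that bias reaches the percent level
and breaks the exact algebraic equivalence between the slab-integral and
occupancy-ratio partition estimators, so pooling is used throughout.

The three estimators are: the well point estimate
K_P = exp{−[ΔG(z_eq) − ΔG(z_w)]/RT} (evaluated at the profile minimum so
it is invariant to shifting ΔG by a constant); the slab integral
(1/z_w/mem)∫₀^{z_w/mem} e^{−ΔΔG/RT} dz computed as a rectangle sum on the
bin grid (which matches the histogram estimate of the density integral
exactly — a trapezoid would not), with masked membrane bins contributing
zero rather than an interpolated barrier shape; and the occupancy ratio
(p_mem/p_w)(⟨z_w⟩/⟨z_mem⟩) with ⟨z_mem⟩ = z_w/mem and
⟨z_w⟩ = box half-height − z_w/mem. The point estimate exceeds the slab
average whenever the insertion well is narrower than the membrane slab.

## Insertion events

A residence interval is a maximal run of |z| < 3.0 nm. A lag of 10 ns is
trimmed at both ends (entry + lag, exit − lag) so only equilibrated frames
enter the membrane state; intervals shorter than 2×lag yield no event and
their frames are labelled `excluded-lag`. No gap tolerance is applied: a
single frame at or beyond the threshold closes the interval. An interval
still open at the trajectory end becomes a right-censored event, kept for
state masks but excluded from mean residence times. Exit is timed at the
first frame at/above threshold, which makes the rule time-reversal
symmetric up to one frame. Comparisons on the floating-point time grid
carry a 1 ns×10⁻⁹ guard so exact-boundary intervals are classified
deterministically.

## Rotational dynamics

Vectors: the coordinated-oxygen plane normal is the eigenvector of the
smallest principal moment of the four coordinated O positions, its sign
made continuous in time; Gd–O_water/Gd–H_water use the currently
coordinated water (identity from the exchange tracker; the two hydrogens
are averaged, as they are not distinguished); the amphiphilic moment is
COM(hydrophilic) − COM(hydrophobic), normalized.

C(t) = ⟨P₂(u(s)·u(s+t))⟩ averages over all time origins whose full span
lies inside one contiguous run of the requested state, so no origin pair
straddles a state transition or an excluded-lag gap. Lags with fewer than
10 valid pairs are truncated.

The fit model is C(t) = Σᵢ aᵢ e^{−t/τᵢ} + a∞ with aᵢ, a∞ ≥ 0 and
Σaᵢ + a∞ = 1 enforced by a softmax parametrization; Levenberg–Marquardt
with multistart over log-spaced τ initializations. τ_R is the
amplitude-weighted mean Σaᵢτᵢ/Σaᵢ with the plateau excluded — the standard
convention, which reduces exactly to the single-exponential time. Defaults
are 2 exponentials in water and 3 with plateau in the membrane; corrected
AIC comparison is available but never applied silently. The residual a∞
("wobbling") encodes hindered orientation sampling in the bilayer.

## Water exchange

A water O within 0.32 nm of Gd is the coordination candidate — a cutoff
just beyond the first Gd–O_water RDF peak, before the first minimum. The
coordinated identity changes only after a new water has remained the
nearest in-cutoff candidate for ≥ 10 ps (min_dwell), so transient
recrossings of the departing water are not double-counted; once confirmed,
the exchange is backdated to the takeover frame. Dwells touching the
trajectory ends are censored.

τ_m comes from the remaining-events curve N(t) = number of completed
dwells ≥ t, fitted by unweighted least squares to N₀e^{−t/τ_m} (that curve
is the primary observable); the maximum-likelihood estimate — the mean
completed dwell — is reported alongside as a cross-check, and the two
agree within ~10% for exponential kinetics at n ≳ 200. A fit whose rms
exceeds 15% of N₀ is flagged non-exponential. No Kaplan–Meier correction
is applied; censored dwells are simply excluded from the curve.

## Bilayer structure

Area/lipid is ⟨L_x L_y⟩ per leaflet lipid; the chelate-corrected variant
subtracts, per leaflet, n_inserted × π(d/2)² with d = 0.871 nm (the
crystal-structure distance between opposite non-coordinated oxygens);
n_inserted may be fractional (time-averaged occupancy). Volume/lipid is
area/lipid × D_NN/2. The Luzzati thickness D_B is the distance between
the two z where the linearly interpolated water density crosses half its
bulk plateau (bulk = mean over the outer 1 nm, configurable). D_HH is the
separation of the two electron-density maxima with quadratic peak
interpolation; the electron-vs-mass weighting is recorded in the profile
metadata and switchable. D_PP/D_NN are distances between per-leaflet mean
P/N positions. Tilt angles are per-lipid vectors (P→N, chain C1→C_ter)
against the outward normal, lower leaflet flipped. S_CH uses
⟨(3cos²θ − 1)/2⟩ per C–H bond (cos² makes the leaflet flip irrelevant);
prochiral bonds are reported separately only when labelled and differing
by more than 0.02, and MAD scoring averages split values before matching
unless the reference itself is split.

## Lateral structure

Solute-centric profiles bin per-lipid instantaneous properties against the
minimum-image xy distance from the solute COM (0.1 nm bins; bins with
fewer than 50 samples masked). Density maps accumulate counts in the
solute frame (0.05 nm cells) and normalize by the mean over cells farther
than 2.0 nm laterally, so the far field is 1 by construction. 2-D RDFs
normalize annulus counts by the instantaneous per-leaflet surface density
(the box fluctuates); same-leaflet pairing is by z sign per centre.
Damped-sinusoid fits run over r ≥ 0.26 nm for lipid–lipid curves and
r ≥ 0.95 nm for solute-centred curves (below which depletion/first-peak
structure is outside the model), with multistart over ω ∈ [2π/0.6,
2π/0.3] nm⁻¹ and either a constant or a three-parameter logistic baseline
L/(1 + e^{−k(r−r₀)}); the logistic form is an explicit choice recorded in
the fit metadata. The characteristic length is 2π/ω by definition.

## Interactions

3-D RDFs use shell-volume normalization against the whole-box mean density
of the partner selection — the convention of standard tooling, noted in
the metadata as systematically biased for interfacial species. Cumulative
numbers integrate the raw shell counts per origin. H-bonds require
D–A ≤ 0.35 nm (minimum image) and ∠H–D–A ≤ 30° measured at the donor (the
angle convention is documented because ∠D–H–A conventions also exist);
both criteria are inclusive with a 10⁻⁹ numerical guard. Improper bonds
use methylene C–H donors and ester-oxygen acceptors under the same
geometry.

## Relaxivity bookkeeping

1/τ_c = 1/τ_m + 1/τ_R + 1/T_ie with omitted terms contributing zero.
Temperature extrapolation is Eyring, τ(T₂) = τ(T₁)(T₁/T₂)e^{ΔH‡/R(1/T₂ −
1/T₁)}, for the water residence time (activation enthalpy 49.8 kJ/mol
reproduces 244 ns at 298.15 K → 108 ns at 310.15 K) and plain Arrhenius
for the rotational time (16.1 kJ/mol, 77 ps → 60 ps); the model is always
an explicit argument. The two-compartment suspension relaxivity assumes
additivity over the water and membrane pools with bound fraction
f = K_P V̄_L[L]/(1 + K_P V̄_L[L]) (V̄_L = 0.765 M⁻¹ for POPC); with
r₁ = 3.4/14 mM⁻¹s⁻¹ and K_P = 1.5 it gives 3.5 mM⁻¹s⁻¹ at 10 mM lipid.
A water-model self-diffusion correction (e.g. ×2 for TIP3P-like fast
diffusion) is exposed as an explicit multiplier that returns a provenance
string, never applied silently. The full Solomon–Bloembergen–Morgan
inner/outer-sphere machinery is out of scope: only the printed
correlation-time combination and the compartment model are implemented.

## Uncertainty machinery

Blocking follows Flyvbjerg–Petersen: successive pairwise block averaging,
SE at each level √[c₀/(m−1)] over m blocks with its own uncertainty
SE/√[2(m−1)]. Plateau selection is automated — the smallest level L with
se(L+1) − se(L) < se_of_se(L); if the SE is still rising when fewer than
8 blocks remain, the maximum SE is reported and flagged `no_plateau`.
The rule is deliberately conservative; the literature leaves this choice
to judgment. Weighted means (weights ∝ sampling time) use the Cochran
ratio-variance SE in the Gatz–Smith form, which reduces exactly to the
ordinary t-interval for equal weights and tracks a nonparametric bootstrap
within ~10%. All intervals are 95% two-sided Student-t.

## Synthetic generators

Every generator is a pure function of its integer seed. The Langevin
generator integrates overdamped Euler–Maruyama dynamics
z ← z − (D Δt/RT)G′(z) + √(2DΔt)ξ on a piecewise-linear PMF with
reflecting boundaries at 0 and z_max (the solute never crosses the bilayer
centre; reflection at 0 mimics leaflet folding); the drift per step is
required to stay below 2% of the support, and forces are tabulated on a
4096-point grid. Default D = 1 nm²/ns is a realistic small-molecule
diffusion constant. The rotational generator rotates the vector by
√(4DrΔt)|ξ| about a random perpendicular axis, exact to O(Δt) against the
P₂ closed form e^{−6Dr t}. Exchange dwells are i.i.d. exponential. The
toy bilayer is a square lattice (perfect-square lipid count per leaflet)
with prescribed area/lipid, P→N tilt at random azimuth, straight chains,
C–H bonds at a prescribed polar angle, optional Gaussian jitter and an
error-function water interface.

These fixtures are geometric, not physical: they carry the observable
under test and nothing else. Passing tests therefore demonstrate that the
estimators recover known ground truth under the stated statistical
assumptions (Markovian z-motion, isotropic rotation, exponential exchange,
ideal lattices) — not that real bilayer ensembles satisfy those
assumptions.

## Problem sizes and test design

The validation suite runs at desk scale: 10⁶-step Langevin walks for
density/partition checks, rotor trajectories of 500 τ_R averaged over four
independent rotors (as one would average over the chelate copies in a
simulation box), 500 exchange dwells, 2¹⁷-point AR(1) series for blocking.
At these sizes the oracle agreements hold at the few-percent level;
single-rotor runs of a few hundred τ_R carry ~5–10% fit scatter, which is
why the rotational checks average rotors. Headline MD observables from
the original study (μs-trajectory K_P, τ_R and τ_m values) require the
deposited trajectories and are not reproduced by the synthetic fixtures.

## Known limitations

Orthorhombic boxes only; no trajectory alignment, no umbrella-sampling
reweighting, no anisotropic rotational diffusion, no H-bond kinetics, no
Kaplan–Meier censoring correction, and no surface-adsorbed-state
sub-classification (the threshold rule treats surface and inserted states
together). RDF normalization at interfaces inherits the whole-box density
convention. The exchange tracker enforces a single coordinated water
(q = 1) and warns when two candidates sit in-cutoff simultaneously.
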