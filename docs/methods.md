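# Methods

This note documents the models, numerical choices and limitations behind
`wclike`. The package quantifies transient Watson–Crick-like conformations
of wobble G·T/U mismatches — a tautomeric excited state (ES1) and an anionic
one (ES2) — and how they partition nucleotide-misincorporation flux.

## Bloch–McConnell forward model

Magnetization of one ¹⁵N spin exchanging between *n* chemical states under a
continuous off-resonance spin lock evolves as `dM/dt = A·M` with a 3n×3n
generator `A` combining, per state, the rotating-frame precession
(`Ω_s = Ω_GS + Δω_s`, ppm converted via `Δω_rad = 2π·larmor_mhz·Δω_ppm`),
nutation `ω₁` about x, relaxation (R2 on x/y, R1 on z, decay toward zero —
adequate for spin-lock periods ≤ 120 ms, where thermal recovery is
negligible), and first-order exchange. Exchange rates come from the
fitted-parameter convention `k_i→j = k_ex,ij · p_j/(p_i+p_j)`, which
enforces detailed balance exactly and reduces to `k_f = p_ES·k_ex` for
two states. All states share R1 and R2.

Signs follow the convention that the ground state resonates at 0 and an
excited state at +Δω; a dispersion peak therefore appears at a carrier
offset of −Δω.

Initial magnetization is equilibrated across states (fraction `p_s` each)
and aligned along one common axis: the GS effective field when
`k_ex/|Δω|` of the major excited state is below the alignment threshold
(default 5, configurable — the literature convention does not fix a
number), otherwise the population-average effective field. The observable
is the projection of `expm(A t)·M(0)` onto that axis, evaluated by
eigendecomposition (batched over spin-lock conditions, which is what makes
global fitting affordable). R1ρ is extracted exactly as from experimental
data: a mono-exponential fit of the projected intensities at the
measurement delays (log-linear seed + Gauss–Newton refinement; Monte-Carlo
resampling of the intensity noise for its uncertainty, default 500 draws).

Two identities anchor the implementation: with all Δω = 0 the simulated
R1ρ equals `R1·cos²θ + R2·sin²θ` to ~1e-6 relative (the residual is the
genuine non-secular R1/R2 mixing), and the propagation agrees with
adaptive-step ODE integration to 1e-8 relative on randomized models.

The closed-form fast-exchange check `Rex = p_G·p_E·Δω²·k_ex/(k_ex²+ω_eff²)`
holds to 5% at `k_ex/|Δω| = 20` when R1 = R2. With R1 ≠ R2 a genuine
relaxation–exchange cross-term, odd in the carrier offset and absent from
the closed form, contributes |ΔRex| ≈ p_ES·(R2−R1) off resonance (~6% of
Rex under realistic ¹⁵N conditions); the oracle test therefore uses
R1 = R2 off resonance and realistic relaxation on resonance, where the odd
term vanishes.

## Global dispersion fitting

Weighted least squares (`scipy.optimize.least_squares`, trust-region
reflective) against observed R1ρ with observed sds as weights. Populations
and exchange rates are fitted as log10 (bounds: 1e-6 ≤ p ≤ 0.1,
100 ≤ k_ex ≤ 1e6 1/s); Δω in ppm is bounded to [0, 100], which resolves
its sign degeneracy toward the convention above; R1 ∈ [0.05, 20],
R2 ∈ [0.5, 200] 1/s per nucleus. p_ES and the k_ex of every edge are
shared across nuclei; Δω and R1/R2 are per nucleus.

Multi-start: 2-state fits start from a coarse k_ex grid {1e3, 5e3, 2e4}
crossed with two scalings of a data-driven Δω seed (the offset of the
largest observed R2+Rex bump). 3-state fits are seeded from the 2-state
solution for the ES1 branch and multi-started over the ES2 branch,
including on/off Δω_ES2 patterns across nuclei because an anionic state
may leave the guanine nitrogen unshifted. A triangular 3-state model is
invariant under swapping its excited states, so fits are canonicalized
afterward: ES2 (the anion) is the state with the smaller |Δω| on the
guanine reporter.

Optima whose chi² lies within 2 of the best (statistically
indistinguishable at one residual unit) are resolved toward the smallest
summed exchange rate. This is a reproducibility tie-break; it also avoids
near-degenerate solutions that trade a fraction of a chi² unit for
inflated minor-exchange rates.

Model comparison uses the residual-variance criteria
`AIC = N·ln(chi²/N) + 2K` and `BIC = N·ln(chi²/N) + K·ln N` with the usual
exp(−Δ/2) weights; a Gaussian-likelihood form using the known per-point
sds is available behind a switch. Parameter uncertainties come from a
Monte-Carlo scheme: each observation is resampled from
Normal(fitted value, observed sd) and refitted from the best-fit vector.

## pKa analysis

Titrations combine ¹³C/¹⁵N shift changes (relative to the lowest-pH,
most-protonated point) into `Δδ_obs = √((0.341·Δδ_13C)² + (0.154·Δδ_15N)²)`
and fit the rearranged Henderson–Hasselbalch curve
`Δδ_obs = Δδ_deprot + (Δδ_prot − Δδ_deprot)/(1 + 10^(pH−pKa))` by
nonlinear least squares (lmfit), endpoints free — the highest-pH samples
need not be fully deprotonated. One protonation site, no Hill coefficient.
sds are square roots of the covariance diagonal; a fit whose midpoint
falls outside the sampled range or has sd > 0.5 is flagged
non-identifiable. The apparent pKa of the duplex anion is
`pKa_app = pH − log10(p_anion/(p_wobble + p_tautomer))` from
dispersion-derived populations.

## pH extrapolation

Deprotonation-driven ES2 kinetics rise with pH; tautomer (ES1) kinetics
are pH-independent by construction (the module refuses to rescale them).
Two routes: (i) `ln k = a·pH + b_i` with a shared slope, default
a = ln 10 per pH unit (hydroxide-mediated deprotonation; consistent with
the observed ~2.5-fold forward-rate rise over 0.4 pH units), duplex-
specific intercepts; (ii) the pKa route, `p_ES2` from the
Henderson–Hasselbalch curve of pKa_app and
`k_GS→ES2 = k_ES2→GS·p_ES2/(1−p_ES2−p_ES1)` with the backward rate treated
as exactly pH-independent. On the dT·rG scheme the two routes agree on the
flux partition within 5 percentage points, and route (ii) is the default
in the analysis scripts.

## Flux partition

The 4-species scheme (GS, ES1, ES2, MIS; the downstream step k₂ acts
identically on both excited states, k₋₂ on the reverse) is integrated to
`t_sim = 10 s` (≫ the ~5 ms equilibration time) with a stiff BDF solver,
rtol 1e-8 / atol 1e-12, constant Jacobian, and a ‖dp/dt‖ < 1e-9 warning
check. Tightening rtol to 1e-10 moves f_A by < 0.01 points; atol below
~1e-12 stalls the solver near equilibrium without changing the result.
Pathway fluxes compose the equilibrium one-step fluxes `F = p·k` by the
serial (harmonic) and parallel (additive) rules; f_A = 100·F_A/(F_T+F_A).
Zero-flux serial chains return 0 by continuity.

During k₂ sweeps k₋₂ tracks k₂ by default so the committed state never
becomes absorbing; f_A is insensitive to this choice because it is a
ratio of fluxes homogeneous in the populations (verified: tracking vs
fixed k₋₂ agree to all printed digits). The harmonic serial composition
is accurate while k₂ stays below the ES→GS return rates (the polymerase
regime, k₂ ≲ 10³ 1/s against return rates of 4–10×10³ 1/s): there it
matches a stochastic first-passage count (embedded-chain Gillespie,
10⁵ events) within 2 percentage points, and f_A rises monotonically from
the thermodynamic limit `p_ES2/(p_ES1+p_ES2)` toward the kinetic limit
`k_GS→ES2/(k_GS→ES1+k_GS→ES2)`. Past that scale the algebra can overshoot
the kinetic limit by up to ~2 points (e.g. the dG·rU curve peaks at 46.5%
near k₂ ≈ 2×10⁴ 1/s before settling at 45.9%) — a property of the
harmonic approximation, not of the underlying kinetics. The 5-species
variant with the NTP binding step (G ⇌ GS) changes f_A by < 1 point for
representative binding rates, which is why the 4-species scheme is the
default.

## Synthetic data: what it emulates, what it does not

The generator reproduces the acquisition design: spin-lock powers
{400, 800, 1200, 1600, 2000} Hz, 13 carrier offsets evenly spaced within
±3.5× the power, delays {0, 40, 80, 120} ms, ¹⁵N at 70.95 MHz. Intensity
noise is Gaussian at 1.5% of the initial intensity (typical of 1D
selective-excitation dispersion data); R1ρ and its sd are then extracted
exactly as for real data. Ground-truth exchange models carry the central
fitted values for the two hybrid duplexes; entries whose values were never
published (the dT·rG anionic Δω at pH 7.8, and the B-DNA/A-RNA duplexes)
are synthetic stand-ins and are marked as such in the fixture table.
Titrations evaluate the Henderson–Hasselbalch transition per nucleus on
the measured pH grids with 0.01 ppm shift noise; the endpoint shifts
(¹⁵N 158→183 ppm, ¹³C 168→171 ppm) are representative N3/C4 magnitudes,
not published values.

Not emulated: spectrometer drift, RF-field inhomogeneity, phase errors,
off-resonance excitation effects, replicate scheduling, and the exact
per-resonance offset lists of the original experiments. Passing recovery
tests therefore demonstrates correctness of the estimation machinery under
the stated noise model, not robustness to instrumental artifacts.

### Identifiability at the study conditions

The 2-state tautomer parameters are recovered tightly (p_ES and k_ex to a
few percent). The 3-state anion branch is near the detection limit by
design — the published uncertainties (p_ES2 = 0.12 ± 0.06%,
Δω = 58 ± 7 ppm, k_ex,minor = 13000 ± 6000 1/s) already say so. Across
generator seeds the recovered anionic Δω_U-N3 stays within the published
±7 ppm, while p_ES2 fluctuates at the scale of the published ±0.06%; for
occasional noise draws a statistically better (Δchi² ≈ 10) solution with a
scrambled ES2 branch wins, which is a property of the likelihood surface
at this information content, not of the optimizer. Problem sizes used in
the shipped tests (reduced grids for replicate studies, 40–60 Monte-Carlo
refits) are chosen so the full suite completes on a single CPU.

## Known limitations

- Only ¹⁵N dispersion is exercised; the machinery is nucleus-agnostic but
  ¹³C-specific effects (CSA, homonuclear couplings) are out of scope.
- No van't Hoff (temperature) analysis; extrapolations are in pH only and
  are flagged outside pH 6–9.
- The flux algebra is the paper-standard serial/parallel composition;
  exact first-passage flux would differ near k₂ ≈ k_ES→GS (see above).
- k₂/k₋₂ presets for specific polymerases are user inputs; none ship with
  the package.
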