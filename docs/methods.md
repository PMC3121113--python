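# Methods

## The model

`caspulse` simulates death-receptor-induced apoptosis signaling as a
five-species delayed kinetic system and couples it to a phenomenological
cell-population death model. The species are bound TNF receptor
[TNF-R], pro-caspase-8 [Casp8], pro-caspase-3 [Casp3], active caspase-8
dimer [Casp8*], and active caspase-3 [Casp3*] (all nM; time in seconds):

    d[TNF-R]/dt  = k_on [TNF] ([TNF-R]_0 − [TNF-R]) − k_off [TNF-R]
    d[Casp8]/dt  = v_Casp8 − d_casp8 [Casp8] − 2 V1
    d[Casp8*]/dt = V1 − d_Casp8* [Casp8*]
    d[Casp3]/dt  = v_Casp3 − d_casp3 [Casp3] − V2 − V3
    d[Casp3*]/dt = V2 + V3 − d_Casp3* [Casp3*]

with fluxes

    V1 = v1 [TNF-R] · c² / (K1 K2 + K2 c + c²),      c = [Casp8]
    V2 = v2 [Casp8*] [Casp3]
    V3 = v3 [Casp3] [Casp9*](t),  [Casp9*] = [Casp9]_0 · x/(K3 + x),
         x = [Casp8*](t − τ)

V1 is the quasi-equilibrium DISC occupancy: each bound receptor hosts a
death-inducing signaling complex that carries 0, 1 or 2 pro-caspase-8
molecules with Boltzmann weights 1, c/K1, c²/(K1·K2); only doubly loaded
complexes release an active dimer (triply loaded states are neglected
because dimer release is fast). The factor 2 in the [Casp8] balance is the
dimer stoichiometry: each activation event consumes two zymogens.

V2 is the direct, type-I cleavage of pro-caspase-3 by cytosolic active
caspase-8. V3 is the type-II mitochondrial arm — Bid cleavage, Bax
recruitment, cytochrome-c release and apoptosome assembly are compressed
into a caspase-9 activity that is a saturating (Michaelis–Menten) function
of the caspase-8 signal delayed by τ = 30 min, cleaving pro-caspase-3 at a
rate proportional to active caspase-9. Ligand is an external input
(no depletion), held piecewise-constant by a `StimulusProtocol`.

The model's defining feature is *rapid degradation of the active
caspases*: `d_c8a` and `d_c3a` are two to three orders of magnitude larger
than the zymogen turnover rates. Sustained stimulation therefore produces
a transient *pulse* of caspase activity — not a switch to a high steady
state — and the system has a unique, globally attracting steady state at
every ligand dose (no bistability). Commitment to death comes from the
downstream accumulation of the pulse, not from hysteresis.

### Rate-law provenance

The functional forms above are reconstructed from the narrative
description of the published model (the printed rate-expression table is
not machine-readable in our source). Two candidate forms existed for the
mitochondrial flux: V3 proportional to the caspase-9 *activation
fraction* x/(K3+x) (total caspase-9 cancelling) or to the active
caspase-9 *concentration* [Casp9]_0·x/(K3+x). Only the second reproduces
the published pulse amplitudes: the fraction form caps peak caspase-3 at
~16 % of the pool against the reported ~40 %, and makes the caspase-8
calibration target unreachable (see below). We therefore adopt the
concentration form; `v3` then acts per nM of active caspase-9
(nM⁻¹ s⁻¹) although the source prints s⁻¹ — a units discrepancy we keep
documented rather than silently rescaling.

### Parameters

All rate constants are the published set (`KineticParameters` defaults):
k_on = 9.09e-5 nM⁻¹s⁻¹, k_off = 1.00e-4 s⁻¹, [TNF-R]_0 = 10 nM,
v1 = 2.65e-3 s⁻¹, K1 = K2 = 50 nM, v2 = 6.00e-5 nM⁻¹s⁻¹,
v3 = 2.60e-4 (see above), K3 = 8 nM, [Casp9]_0 = 20 nM, τ = 1800 s,
v_Casp8 = 6.67e-4 nM s⁻¹, v_Casp3 = 4.00e-5 nM s⁻¹,
d_casp8 = 2.00e-5 s⁻¹, d_casp3 = 2.00e-7 s⁻¹, d_Casp3* = 2.40e-4 s⁻¹.
The resting pools follow as v_Casp8/d_casp8 = 33.35 nM and
v_Casp3/d_casp3 = 200.00 nM.

One constant is not fixed by the published table: the active-caspase-8
degradation rate `d_c8a`. It is constrained to 100–1000 × d_casp8
("2–3 orders faster") and calibrated by a monotone 1-D root-find so that
the reference stimulation (2.0 nM ligand, 10 h, starting from rest) peaks
at 2.8 % of the resting pro-caspase-8 pool. The calibrated value,
d_c8a = 3.4119e-3 s⁻¹ (171 × d_casp8), ships as the default; the
calibration routine remains available and reproduces it (fixed point).
Pool fractions for caspase-8 are counted in monomer equivalents
(2·[Casp8*]/[Casp8]₀), the like-for-like comparison a densitometry ratio
makes; under a dimer-based fraction the 2.8 % target is unreachable
anywhere in the admissible band.

A known, deliberate discrepancy: with the published receptor kinetics the
bound-receptor relaxation time at 2.0 nM is 1/(k_on·2.0 + k_off) ≈ 59 min,
and holding the caspase-8 peak at 2.8 % with any in-band `d_c8a` forces
pro-caspase-8 depletion fast enough that the caspase-8 maximum lands near
1.1 h. The reported "~2 h to maximum" is reproduced by caspase-*3*
(peak at 1.83 h) but cannot be reproduced for caspase-8 jointly with the
2.8 % amplitude under any structural variant we examined; we report the
simulated peak times as they are.

## Delay integration

The system is integrated by the *method of steps*: the interval is cut at
every multiple of τ and at every protocol discontinuity, so within a chunk
the delayed term is a known continuous function, evaluated from the dense
(piecewise-polynomial) output of already-completed chunks. Chunks are
solved with SciPy's LSODA (stiffness-switching) at rtol = 1e-8,
atol = 1e-10 nM by default; the system is mildly stiff, with rates
spanning 2e-7 to ~3e-3 s⁻¹. History before stimulus onset is the constant
pre-stimulus value of [Casp8*] (zero when starting from rest). Protocol
steps restart the integrator exactly rather than being smoothed. Peaks
are located by a coarse scan plus bounded scalar minimization on the
continuous dense output, so peak metrics do not depend on an output grid.
Delays below 1 ms are treated as zero (far beneath every system
timescale) instead of generating astronomically many chunks.

Verification: the τ = 0 limit matches an independent one-shot LSODA solve
of the same right-hand side to < 1e-6 relative; with synthesis and
degradation off, [Casp8] + 2[Casp8*] and [Casp3] + [Casp3*] are conserved
along trajectories to < 1e-6; halving tolerances moves the caspase-3 peak
by < 0.05 %.

## Population fate model

Caspase-3 drives death through a *cumulative* hazard:

    r_apop(t) = r_0 + p · ∫_{max(0, t−τ_d)}^{t} Hill([Casp3*](s)) ds,
    Hill(a)   = aⁿ / (K4ⁿ + aⁿ)

with defaults fitted to Jurkat/TRAIL kinetics: r_0 = 3.31e-6 s⁻¹,
p = 1.05e-8, K4 = 55 nM, n = 4, τ_d = 11 h, r_pro = 0. The Hill term is
the instantaneous trigger (threshold K4), the sliding window of length
τ_d the memory ("effective time") of caspase-3. Under this form p carries
s⁻²; the source prints s⁻¹, another retained units discrepancy — the
alternative reading (time-averaged Hill, p in s⁻¹) caps the stimulated
rate at ≈ 1.003·r_0 and cannot produce the observed 16-h killing.
Survivors obey dS/dt = (r_pro − r_apop)S, dA/dt = r_apop S, solved in
closed form via the cumulative hazard (S + A is conserved when
r_pro = 0); the observable is f_a = A/(S+A). The hazard quadrature uses a
15-s grid, giving < 1e-6 relative agreement with brute-force quadrature.

Half-life T½(dose) solves S(T)/S₀ = 1/2, i.e. cumulative hazard = ln 2,
with r_pro forced to 0 (otherwise T₀ may not exist). Signaling is
simulated until the pulse has passed (a fixed multiple of the active-form
lifetimes and receptor relaxation, ≥ 12 h beyond the protocol); past that
horizon the hazard is constant (the residual steady-state caspase-3
activity is synthesis-limited to ≤ v_Casp3/d_Casp3* ≈ 0.17 nM, with Hill
contribution ~1e-10), so a crossing beyond the simulated span is obtained
in closed form without loss of accuracy.

The response coefficients are EC = T½(2.0 nM)/T₀ (smaller = more
effective killing) and RC = −(ΔT½/Δ[TNF])/T₀ at zero dose (smaller =
better resistance to weak signals). RC is reported as the *forward secant*
at a reference step of 1e-3 nM: with n = 4 the hazard responds
quartically to vanishing doses, the literal zero-dose derivative of T½ is
exactly zero, and the secant scales as (step)³ — so the step is part of
the definition, quoted alongside the value, and Richardson extrapolation
is deliberately not applied (it would extrapolate toward the degenerate
limit and overshoot negative). ΔT½ is extracted from the excess
cumulative hazard rather than by subtracting two ~10⁵-s half-lives,
avoiding catastrophic cancellation at small steps.

## Sensitivities and activation efficiencies

Linearizing the steady state at zero ligand factorizes the marginal
response into a chain: receptor slope K₀·[TNF-R]₀ (K₀ = k_on/k_off),
caspase-8 activation efficiency A_Casp8 = v1·occ([Casp8]_ss)/d_Casp8*,
and caspase-3 activation efficiency
A_Casp3 = [Casp3]_ss·(v2 + v3·[Casp9]₀/K3)/d_Casp3* (the saturating
caspase-9 term linearizes at zero signal). Each efficiency is an
activation-to-degradation rate ratio — the model's statement that a
cell's responsiveness is set jointly by activation kinetics and
active-form turnover. At the defaults A_Casp8 = 0.164, A_Casp3 = 591.7,
δ[Casp8*] = 1.487, δ[Casp3*] = 880.0 (nM per nM ligand).

The closed forms are cross-validated against forward finite differences
of the full nonlinear steady state, Richardson-extrapolated over
{ε, ε/2}. The default ε is 1e-6 nM: the linear regime is narrow because
pro-caspase-3 turnover (d_casp3 = 2e-7 s⁻¹) is so slow that cleavage
terms become comparable to it already at [Casp8*] ~ 1e-4 nM; at
ε = 1e-4 the oracle is ~7 % off *any* closed form, at 1e-6 it agrees to
< 0.01 %. Steady states themselves are found by damped Newton iteration
on the full system (delayed value tied to the current state) with a
pseudo-time relaxation fallback, and are guarded by an exact reduction:
the receptor decouples, pro-caspase-8 satisfies a monotone scalar
balance (unique root), and the remaining species follow in closed form —
which also proves uniqueness of the steady state at every dose.

## Parameter sweeps

The trade-off experiment draws activation parameters log-uniformly —
caspase-8 panel: v1, d_c8a ∈ (1e-5, 1e-2), K1 = K2 ∈ (10, 1000);
caspase-3 panel: v2, v3, d_c3a ∈ (1e-5, 1e-2), K3 ∈ (1, 100) — and
computes (A_Casp8, A_Casp3, EC, RC) per draw (defaults: 500 draws/panel,
seeded; sweep integrations run at rtol 1e-6, ample for rank statistics).
Failures are recorded per-row, never fatal. `trend_summary` reports
Spearman correlations with seeded bootstrap confidence intervals. The
headline property — good effectiveness implies poor resistance — appears
as a strongly negative EC–RC rank correlation (ρ ≈ −0.96 on the
caspase-8 panel at n = 100). Because the published upper bound for the
caspase-8 panel's rate range is garbled in our source, it is taken as
1e-2, mirroring the intact caspase-3 panel; this is a documented
reconstruction.

## Synthetic data

The generators stand in for the study's measurements and define the
package's test conditions:

* **Immunoblot series** — pro-caspase levels normalized to t = 0 under
  the reference 2.0 nM stimulation, with mean-one multiplicative
  log-normal noise of coefficient of variation 0.1 by default (the
  minimal standard model for densitometry).
* **Flow-cytometry counts** — binomial draws of apoptotic cells out of
  n_cells = 10⁴ per timepoint from the model's f_a(t) at 1.0 nM (the
  50 ng/ml TRAIL surrogate), 13 timepoints over 24 h.
* **Dose response** — binomial counts after 16 h incubation across a
  log-spaced dose grid.

These emulate assay noise and sampling but not real-data features such as
blot loading artifacts, gating ambiguity, cell-to-cell threshold
heterogeneity, or ligand depletion — so passing recovery tests shows the
inference machinery is sound under the stated noise model, not that the
model is identifiable from arbitrary real data.

Fate-parameter fitting is bounded least squares on f_a residuals
(log-space parameters; bounds r_0 ∈ [1e-8, 1e-4], p ∈ [1e-11, 1e-5],
K4 ∈ [1, 500], n ∈ [1, 8], τ_d ∈ [0.5, 48] h), multi-start with 8 seeded
starts, optionally inverse-variance weighted by the binomial standard
error. With the generator's defaults, {r_0, p, K4, τ_d} are recovered
with median errors of ~7 %, ~14 %, ~8 %, ~1 % over 20 replicate
datasets; p and K4 share a partial ridge (the Hill saturates near the
pulse peak), which the binomial weighting substantially tames.

## Numerical choices and degenerate inputs

* Seconds and nM internally; CLI accepts `h`-suffixed durations.
  Ligand equivalences used by the reference scenarios: 100 ng/ml FasL ≡
  2.0 nM, 50 ng/ml TRAIL ≡ 1.0 nM.
* Integrator undershoots below zero are clipped at −1e-9 nM on state
  construction; trajectories are verified non-negative to that tolerance.
* The rapid-degradation band check warns (never errors) outside
  [100, 1000] × the pro-form rate, with 0.15 dex slack because the
  published defaults themselves sit at d_Casp3*/d_casp3 = 1200.
* Step protocols take effect at their start time (right-continuous);
  protocol segments must tile [0, t_end] starting at 0.
* All stochastic entry points take explicit seeds; outputs can carry a
  config-digest + seed sidecar.

## Known limitations

* The caspase-8 peak-time discrepancy described above.
* RC is step-defined (see above); comparisons across parameter sets are
  meaningful at a common step only.
* No single-cell heterogeneity, cell-cycle structure, ligand depletion,
  receptor internalization, or explicit IAP/cFLIP/Bcl-2 species; K1, K2,
  K3 absorb inhibitor effects phenomenologically.
* The apoptosis-rate functional is phenomenological; its printed form
  and the units of p are not recoverable from our source, and the
  adopted windowed-integral reading is the one consistent with the
  published kinetics.
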