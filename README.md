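# caspulse

A trigger model of apoptosis induced by TNF-family death-receptor
signaling: caspase activation as a transient **pulse** rather than a
bistable switch.

## The problem

Cells must ignore weak, incidental death signals yet commit irreversibly
once stimulation is strong enough. Classic models explain the threshold
with bistability — coexisting low- and high-caspase-3 steady states.
`caspulse` implements the alternative: when the *active* forms of
caspase-8 and caspase-3 are degraded 2–3 orders of magnitude faster than
their zymogens, sustained stimulation produces a sharp pulse of caspase-3
activity that decays again, and commitment arises from the *cumulative*
action of that pulse on downstream death machinery. The signaling system
has a unique steady state at every dose; no bistability is required.

The package is for systems biologists who want a tested, scriptable
implementation of this model class: simulate stimulation protocols, fit
the cell-death layer to flow-cytometry data, compute sensitivity
statistics, and sweep parameters for effectiveness/resistance trade-offs.

## The model

Five species — bound receptor [TNF-R], pro-caspases [Casp8], [Casp3],
active forms [Casp8*] (dimer), [Casp3*] — with delayed kinetics:

    d[TNF-R]/dt  = k_on[TNF]([TNF-R]₀ − [TNF-R]) − k_off[TNF-R]
    d[Casp8]/dt  = v_Casp8 − d_casp8[Casp8] − 2·V1
    d[Casp8*]/dt = V1 − d_Casp8*[Casp8*]
    d[Casp3]/dt  = v_Casp3 − d_casp3[Casp3] − V2 − V3
    d[Casp3*]/dt = V2 + V3 − d_Casp3*[Casp3*]

V1 is DISC-mediated caspase-8 activation (quasi-equilibrium occupancy of
doubly-loaded complexes), V2 direct (type-I) cleavage of pro-caspase-3,
and V3 the mitochondria-amplified (type-II) arm, in which caspase-9
activity follows the caspase-8 signal delayed by τ = 30 min through a
Michaelis–Menten function. A cell population then dies at rate

    r_apop(t) = r₀ + p·∫ over the last τ_d of Hill([Casp3*](s)) ds,

and the apoptotic fraction f_a = A/(S+A) is the flow-cytometry
observable. Population half-lives define the effective coefficient
EC = T½(2 nM)/T₀ and resistance coefficient RC = −(ΔT½/Δ[TNF])/T₀ at
zero dose, and zero-stimulus linearization gives the caspase activation
efficiencies A_Casp8 and A_Casp3. See `docs/methods.md` for the full
formulation, parameter provenance, and numerical choices.

## Worked example

```python
import caspulse as cp

params = cp.KineticParameters()          # published rate constants
fate = cp.FateParameters()               # published cell-death parameters

# reference stimulation: 2.0 nM ligand (≈ 100 ng/ml FasL) for 10 h
traj, pulse = cp.run_figure3(params)
print(f"caspase-8 peak: {100 * pulse.peak_act_c8_fraction:.1f}% of pool "
      f"at {pulse.t_peak_c8 / 3600:.2f} h")
print(f"caspase-3 peak: {100 * pulse.peak_act_c3_fraction:.1f}% of pool "
      f"at {pulse.t_peak_c3 / 3600:.2f} h (lag {pulse.peak_lag / 60:.0f} min)")

rc = cp.response_coefficients(params, fate)
print(f"T0 = {rc.T0 / 3600:.1f} h, T1/2(2 nM) = {rc.T_half_ref / 3600:.2f} h")
print(f"EC = {rc.EC:.4f}, RC = {rc.RC:.2e} /nM (step {rc.fd_step} nM)")

eff = cp.steady_state_sensitivities(params)
print(f"A_Casp8 = {eff.A_c8:.4f}, A_Casp3 = {eff.A_c3:.1f}")
```

prints

    caspase-8 peak: 2.8% of pool at 1.06 h
    caspase-3 peak: 40.3% of pool at 1.83 h (lag 46 min)
    T0 = 58.2 h, T1/2(2 nM) = 5.13 h
    EC = 0.0881, RC = 2.87e-03 /nM (step 0.001 nM)
    A_Casp8 = 0.1636, A_Casp3 = 591.7

Meaning: sustained strong stimulation converts 2.8 % of the
pro-caspase-8 pool and 40 % of the pro-caspase-3 pool at the pulse peaks,
with caspase-3 trailing caspase-8 by ~3/4 of the mitochondrial delay
window; the same stimulus shortens the population half-life eleven-fold
(EC ≈ 0.09), while a 1 pM dose barely moves it (small RC) — the cell is
simultaneously responsive to strong signals and resistant to weak ones.

The same operations are available from a CLI:

    caspulse simulate --tnf 2.0 --t-end 10h --out traj.csv
    caspulse fate --tnf 1.0 --t-end 24h --out fa.csv
    caspulse coefficients --out coeffs.json
    caspulse scan --panel casp8 --n 500 --seed 42 --out scan.csv
    caspulse synth --kind flow --seed 7 --out synthetic_counts.csv
    caspulse fit --data synthetic_counts.csv --out fitted.json

## Layout

    src/caspulse/
      params.py       kinetic + fate parameter sets (published defaults)
      protocol.py     piecewise-constant stimulation protocols
      model.py        flux laws, right-hand side, steady states
      dde.py          method-of-steps delay integrator, reference scenarios
      population.py   cumulative hazard, survival, half-life, EC/RC
      sensitivity.py  activation efficiencies + finite-difference oracle
      scan.py         log-uniform sweeps and trend statistics
      calibration.py  d_Casp8* calibration, fate-parameter fitting
      synth.py        synthetic immunoblot / flow-cytometry generators
      config.py       TOML config, CSV tables, reproducibility sidecars
      cli.py          `caspulse` command-line interface
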