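# enzfilm

Reaction–diffusion modelling of enzymatic degradation of semicrystalline
polymer films, built around the thin-film PCL–lipase system: a two-state
(crystalline/amorphous) kinetic network coupled to porosity-dependent enzyme
transport, with joint calibration to weight-loss and crystallinity data,
Bayesian uncertainty quantification, variance-based sensitivity analysis and
predictive film-thickness sweeps.

It is aimed at people modelling bioresorbable polyester films (implants,
barrier membranes, drug-eluting patches) who need to predict not just mass
loss but the concurrent evolution of crystallinity — which controls
mechanical integrity and release behaviour — and to ask how both change with
film thickness without running a new experiment per geometry.

## Model

On the half-thickness domain x ∈ [0, L] (symmetric immersion), six species
evolve by mass action plus Fickian enzyme transport:

    ∂E/∂t  = ∂/∂x( De(φ) ∂E/∂x ) − k₁EC + k₋₁[EC] − k₃EA + k₋₃[EA]
              + k_conv[EC] + k_deg,C[EC] + k_deg,A[EA]
    ∂C/∂t  = −k₁EC + k₋₁[EC]
    ∂A/∂t  = −k₃EA + k₋₃[EA] + k_conv[EC]
    ∂[EC]/∂t = k₁EC − (k₋₁ + k_conv + k_deg,C)[EC]
    ∂[EA]/∂t = k₃EA − (k₋₃ + k_deg,A)[EA]
    ∂P/∂t  = k_deg,C[EC] + k_deg,A[EA]

with porosity φ = 1 − (C + A), effective diffusivity De(φ) = De0(1 + αe φ),
E = 1 at the exposed surface and zero flux at the mid-plane. Observables are
percent weight loss and bulk crystallinity χc = ∫C dx / ∫(C+A) dx. The
eight-parameter vector θ = (k₁, k₋₁, k₃, k₋₃, k_conv, k_deg,C, k_deg,A, De0)
is calibrated by weighted least squares, sampled by differential-evolution
MCMC with snooker updates under log-uniform priors, and ranked by
time-dependent Sobol indices. Details and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import enzfilm as ez

cfg = ez.case_study_config()          # L = 0.25 mm (0.5 mm film), C0 = 0.302
traj = ez.simulate(cfg.kinetics, cfg.transport, cfg.geometry,
                   cfg.initial, cfg.solver)
s = ez.observable_series(traj, cfg.geometry, cfg.initial)
for t, wl, xc in zip(s.times, s.weight_loss_pct, s.crystallinity_pct):
    print(f"t={t:4.0f} h   weight loss {wl:5.2f} %   crystallinity {xc:5.2f} %")
m = ez.damkohler(cfg.kinetics, cfg.transport, L=4.0)
print(f"8 mm film: tau_diff = {m.tau_diff:.2f} h, Da_A = {m.Da_A:.3f}")
```

prints

```
t=   0 h   weight loss  0.00 %   crystallinity 30.20 %
t=   4 h   weight loss  0.64 %   crystallinity 17.53 %
t=   8 h   weight loss  1.96 %   crystallinity 11.45 %
t=  16 h   weight loss  5.21 %   crystallinity  2.88 %
t=  20 h   weight loss  6.89 %   crystallinity  1.15 %
t=  24 h   weight loss  8.56 %   crystallinity  0.43 %
t=  40 h   weight loss 14.96 %   crystallinity  0.01 %
t=  64 h   weight loss 23.74 %   crystallinity  0.00 %
8 mm film: tau_diff = 9.64 h, Da_A = 0.048
```

Weight loss climbs steadily while crystallinity collapses from its initial
30.2% — the signature of an enzyme that amorphises crystalline lamellae
rather than only consuming amorphous material. The 8 mm film's diffusion
timescale (~9.6 h) is no longer negligible against the catalytic timescale,
which is where degradation turns transport-influenced; at the experimental
0.5 mm it is ~0.04 h and the film is firmly reaction-limited.

The same pipeline is scriptable from the shell:

```sh
enzfilm template --out model.yaml
enzfilm simulate  --config model.yaml --out run/
enzfilm synth     --config model.yaml --out synth.csv --seed 1
enzfilm fit       --config model.yaml --data synth.csv --out fit.json
enzfilm sample    --config model.yaml --data synth.csv --out mcmc/
enzfilm sobol     --config model.yaml --out sobol.csv --thickness-mm 0.5
enzfilm thickness --config model.yaml --out sweep/
```

Every command writes a `manifest.json` (config snapshot, seeds, input
checksums) sufficient to re-run it.

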