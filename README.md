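# electrodiff

Electrodiffusion of ions and the electric potential in brain
extracellular space (ECS), on structured grids, for computational
neuroscientists who need ion-concentration dynamics and extracellular
potentials together on tissue scales (millimetres, seconds) — the regime
of seizures, spreading depression and other pathologies driven by large
ECS concentration shifts.

## The model

Each ion species k obeys a continuity equation with the Nernst–Planck
flux in a porous medium (tortuosity λ, ECS volume fraction α):

    ∂c_k/∂t = ∇·[ D̃_k ∇c_k + (D̃_k z_k c_k / ψ) ∇φ ] + f̃_k,
    D̃_k = D_k/λ²,  f̃_k = f_k/α,  ψ = RT/F,

driven by point current sources f̃_k representing neuronal membrane
exchange. Four closures for the potential φ are implemented behind one
interface:

| scheme | potential closure | resolves | cost |
|--------|------------------|----------|------|
| PNP  | Poisson, ∇²φ = −ρ/ε | nm / ns charge relaxation | prohibitive beyond microns |
| KNP  | bulk electroneutrality, ∂ρ/∂t = −ĩ_cap → ∇·(σ∇φ + ∇b) + FΣz_k f̃_k + ĩ_cap = 0 | quasi-steady φ, concentration dynamics | tissue scale |
| VC   | ∇·(σ∇φ_VC) + sources = 0, concentrations frozen | ohmic potential only | closed-form scale |
| DO   | φ = 0 | diffusion only | cheapest |

with σ = FΣ_k D̃_k z_k² c_k/ψ (conductivity) and b = FΣ_k D̃_k z_k c_k,
whose gradient is the diffusive current density. The KNP potential
splits as φ = φ_VC + φ_diff, separating the membrane-current
contribution from the liquid-junction (diffusion) potential. PNP and KNP
are advanced by monolithic implicit Euler + Newton; all four schemes
share one conservative finite-volume discretisation.

The packaged ion table (Na⁺ 150 mM, K⁺ 3 mM, Ca²⁺ 1.4 mM, X⁻ 155.8 mM
with Cl⁻ mobility; λ = 1.6, α = 0.2) is an electroneutral standard
cortical ECS composition.

## Worked example

The classic sanity check: a 1-D bath of NaX with a concentration step
(140 mM for x ≤ 0, 150 mM for x > 0). Because X⁻ is more mobile than
Na⁺, a liquid-junction potential forms; the electroneutral scheme should
produce the Henderson value instantly.

```python
import electrodiff as ed

ions = ed.default_ion_set()
print(f"baseline conductivity: {ed.conductivity(ions.c_baseline, ions):.3f} S/m")
print(f"charge relaxation time: {ions.constants.eps / ed.conductivity(ions.c_baseline, ions) * 1e9:.2f} ns")

res = ed.run_app1("KNP", "short", {"spacing": 0.4e-9, "extent": 0.02e-6,
                                   "dt": 0.1e-9, "t_end": 1e-9})
dphi = res.probes["dphi"].values[0]
oracle = ed.junction_potential_binary(140, 150, *res.final_state.ions.D_eff,
                                      ions.constants.psi)
print(f"KNP quasi-steady junction potential: {dphi * 1e3:.4f} mV")
print(f"closed-form (Henderson) value:       {oracle * 1e3:.4f} mV")
```

prints

```
baseline conductivity: 0.766 S/m
charge relaxation time: 0.92 ns
KNP quasi-steady junction potential: 0.3715 mV
closed-form (Henderson) value:       0.3716 mV
```

The conductivity is that of standard ECS saline; the 0.92 ns charge
relaxation time is why PNP needs nanosecond steps while KNP can take
milliseconds; and the simulated step-gradient potential (+0.37 mV, high
side positive, because the faster anion runs ahead) matches the
closed-form junction potential to 0.03%.

The same runs are available from the shell:

```sh
electrodiff app1 --scheme KNP --variant short --out app1_out
electrodiff app2 --scheme KNP --t-end 0.1 --out app2_out
electrodiff gen-sources --rate 5 --duration 10 --seed 1 --out sources.csv
electrodiff app3-surrogate --sources sources.csv --t-end 10 --out app3_out
electrodiff run my_config.yaml
```

Each run writes `probes.csv`, `step_report.csv`, VTK/CSV field
snapshots, and a `manifest.json` (resolved configuration + seed +
version) that reproduces it bit-identically.

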