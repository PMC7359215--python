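# celldose

Subcellular dosimetry and radiobiology for Auger-electron-emitting
radiopharmaceuticals.

Auger emitters such as ⁹⁹ᵐTc deposit most of their electron energy within
nanometres of the decay site, so the biological effect of a radiolabelled
compound hinges on *where in the cell* the radionuclide ends up. `celldose`
is for experimentalists who measure cellular uptake of such compounds with a
gamma counter and want to turn those counts into compartment-resolved
absorbed doses, survival-curve parameters and relative biological
effectiveness (RBE) — the full chain from cpm to RBE, with uncertainties.

## What it computes

**Activity kinetics.** Counts per minute at measurement time `t` become
activity via the counter efficiency ε (default 54%), are back-extrapolated
to the start of incubation with the decay law
`A(t) = A₀ exp(−ln2·t/T_p)` (T_p = 6.02 h for ⁹⁹ᵐTc), and integrated to the
cumulated activity

    Ã = (T_p/ln2) · A₀ · (1 − exp(−ln2·Δt/T_p))   [Bq·s],

which is then split between nucleus and cytoplasm using the measured
nuclear fraction of internalized activity. Surface-bound and medium
activity are excluded: their Auger electrons cannot reach the nucleus.

**MIRD cellular dosimetry.** Compartment doses follow the cellular S-value
bilinear form

    D_N  = Ã_N·S(N←N)  + Ã_Cy·S(N←Cy)
    D_Cy = Ã_N·S(Cy←N) + Ã_Cy·S(Cy←Cy),

with the published ⁹⁹ᵐTc matrix (2 μm nucleus / 4 μm cell) shipped as the
named default `Tc99m_MIRD`: S(N←N) = 1.19×10⁻², S(Cy←Cy) = 1.74×10⁻³,
cross terms 1.82×10⁻⁴ Gy/(Bq·s).

**Monte Carlo cross-check.** A straight-ray CSDA electron transport engine
in a concentric-sphere phantom (central 0.7 μm "chromatin" source, 2 μm
nucleus, 4 μm cell, liquid water) computes per-decay compartment deposits
and S-values for any discrete electron spectrum, with per-entry standard
errors and a 10 eV transport floor.

**Radiobiology.** Plating efficiency, survival fractions, the
single-parameter exponential survival model `SF = exp(−κD)` fitted on the
log scale, IC₅₀ from survival-vs-activity curves, and RBE with
delta-method error propagation:

    RBE₀.₅ = κ_test/κ_ref,    RBE₂Gy = exp(2(κ_test − κ_ref)).

## Worked example

Synthetic uptake for a compound with a 45% mean nuclear fraction, measured
counts normalized to the average cell (50 000 cells per well), pushed
through the MIRD chain:

```python
import dataclasses
from celldose import (UptakeModelParams, generate_uptake_table, DecayParams,
                      TC99M_MIRD, dose_table_frame)

CELLS_PER_WELL = 50_000
params = UptakeModelParams(nuclear_fraction_mean=0.45, seed=1)
well = generate_uptake_table(params, [7.4e3, 1.85e5, 7.4e5, 1.85e6, 7.4e6],
                             compound="C3")
per_cell = [dataclasses.replace(r,
                                internalized_cpm=r.internalized_cpm / CELLS_PER_WELL,
                                surface_cpm=r.surface_cpm / CELLS_PER_WELL)
            for r in well]
print(dose_table_frame(per_cell, DecayParams(), TC99M_MIRD).to_string(index=False))
```

```
 applied_activity_bq  dose_nucleus_gy  dose_cytoplasm_gy  dose_cell_gy  nuclear_dose_fraction
                7400            32.01              5.411         37.42                 0.8554
            1.85e+05            734.8              124.2           859                 0.8554
             7.4e+05             2344              396.1          2740                 0.8554
            1.85e+06             4170              704.8          4875                 0.8554
             7.4e+06             6835               1155          7990                 0.8554
```

The `nuclear_dose_fraction` column is the headline number: with this
compound's nuclear uptake around 45%, the nucleus receives ~85% of the
intracellular dose — the S-value asymmetry concentrates dose in the
nucleus well beyond the activity split. Absolute doses scale linearly with
the supplied counts (here, synthetic saturable uptake); the share column
does not.

The Monte Carlo configuration with a DNA-bound (central-source) geometry
concentrates the dose even further:

```python
from celldose import (toy_spectrum, run_s_value_mc, nuclear_dose_share_mc,
                      CellPhantom)
res = run_s_value_mc(toy_spectrum("tc99m_like"), CellPhantom(),
                     "central_sphere", n_histories=100_000, rng_seed=1)
print(nuclear_dose_share_mc(res))        # 0.9967
print(res.s_values["nucleus"]["value"])  # 1.158e-02 Gy/(Bq.s)
```

and survival fitting plus RBE:

```python
from celldose import (SurvivalModelParams, generate_survival_data,
                      fit_linear_survival, SurvivalFit, rbe)
pts = generate_survival_data(SurvivalModelParams(kappa_true=0.6, noise_cv=0.05, seed=1))
fit = fit_linear_survival(pts)           # kappa = 0.597 +/- 0.005 Gy^-1
r = rbe(SurvivalFit(kappa=0.25, kappa_se=0.02), fit)
print(r.rbe_05, r.rbe_2gy)               # 2.39 +/- 0.19, 2.00 +/- 0.08
```

A κ twice the reference slope halves the dose needed for 50% kill — the
RBE₀.₅ of 2.4 here reflects exactly that slope ratio.

## Command line

`celldose` exposes the same pipeline as subcommands:

```sh
celldose simulate-uptake --compound C3 --seed 1 --out uptake.csv
celldose dose-mird uptake.csv --out-prefix dose
celldose dose-mc --spectrum toy:tc99m_like --seed 1 --n-histories 100000 --out mc.json
celldose fit-survival clonogenic.csv --out fits.json
celldose rbe fits.json --reference-kappa 0.25 --out rbe.json
```

All outputs are CSV/JSON; JSON reports embed the package version and a
configuration hash. Logs go to stderr only.

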