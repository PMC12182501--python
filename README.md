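# soilresp

Process-based modelling of **partitioned soil respiration** — the split of
total soil CO₂ efflux (SR) into heterotrophic respiration (HR, microbial
decomposition of soil organic matter) and autotrophic respiration (AR,
fine-root maintenance plus growth) — for subtropical evergreen forests.
It is written for ecosystem-carbon researchers who need to calibrate simple
respiration models against chamber/trenching observations, select among
competing model structures, run multi-decade simulations from driver time
series, and ask *why* the simulated fluxes changed: temperature, moisture,
root biomass, productivity, or ENSO.

## Models

Heterotrophic respiration from soil organic carbon (SOC, g kg⁻¹), soil
temperature *T* (°C, 5 cm) and volumetric soil moisture *M* (%, 5 cm) —
three candidate structures:

    HR₁ = SOC · (α + γM) · e^(βT)
    HR₂ = α · SOC · M/(M + k_M) · e^(βT)
    HR₃ = α · SOC · min( T/(T + k_T), M/(M + k_M) ) · e^(βT)

with Michaelis–Menten half-saturation constants k_T, k_M set to half the
record maximum of the corresponding driver; α, β (and γ) are fitted by
bounded multi-start least squares.

Autotrophic respiration from fine-root biomass (FRB = P_rl·LAI/SLA), GPP
and temperature:

    Rm = FRB · δ · ε^((T−20)/10)          (maintenance)
    Rg = 0.25 · P_rt · NPP                 (growth)
    AR = Rm + Rg,  NPP = GPP − AR/P_rt

which closes, for the default root allocation P_rt = 0.15, to

    AR = 0.8 · Rm + 0.03 · GPP

Model comparison uses origin-R², RMSE, normalized standard deviation,
AIC = 2k + n·ln(RSS/n), and the modelled-vs-observed regression slope.
Interannual analysis provides OLS trends, detrended standard deviation
(DSD) and normalized C.V., first-order Taylor attribution of flux changes
to drivers, and Oceanic Niño Index (ONI) winter composites. A fully seeded
synthetic-site generator (three archetypes with site-specific SOC,
temperature seasonality and HR parameters) supplies known-truth data for
every pipeline stage.

## Worked example

```python
import soilresp as sr

# a needleleaf site with low SOC, biweekly observations, 10 % noise
scn = sr.scenario_from_archetype("ENF-S", years=3, seed=11)
forcing, oni = sr.generate_forcing(scn)
site, hr_truth, ar_truth = sr.truth_models(scn)
truth = sr.generate_truth(forcing, site, hr_truth, ar_truth)
obs = sr.sample_observations(truth, interval_days=14, rel_noise_sd=0.10, seed=12)

k_T, k_M = sr.michaelis_constants(forcing)
fit = sr.fit_hr("HR3", obs, forcing, SOC=scn.SOC, k_T=k_T, k_M=k_M)
print(f"alpha = {fit.params.alpha:.4f}  (truth {scn.alpha})")
print(f"beta  = {fit.params.beta:.4f}  (truth {scn.beta})")
print(f"n = {fit.n}, RSS = {fit.RSS:.3f}")
```

prints

```
alpha = 0.1148  (truth 0.11)
beta  = 0.0377  (truth 0.039)
n = 79, RSS = 1.065
```

i.e. from 79 biweekly noisy observations the decomposition rate α is
recovered within ~4 % and the temperature-sensitivity β within ~3 % of the
generating values; the residual sum of squares reflects the injected 10 %
observation noise.

The same pipeline is scriptable from the shell:

```sh
soilresp synth     --config site.yaml --seed 1 --out run/
soilresp calibrate --config cal.yaml  --out run/fits
soilresp select    --config cal.yaml  --out run/selection
soilresp simulate  --config sim.yaml  --out run/sim
soilresp analyze   --config an.yaml   --out run/tables
```

Every command writes CSV tables plus a `manifest.txt` echoing the resolved
configuration and package version, so runs are bit-reproducible.

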