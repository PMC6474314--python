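# sedmix

Quantitative analysis of the upper half-meter of coastal marine
sediment: **how deep and how fast benthic macrofauna mix the seabed**,
and what that mixing means for the microbial communities being buried
through it. The package is aimed at biogeochemists and
geomicrobiologists working with sediment cores who have gamma-count
radionuclide profiles, 35S sulfate-reduction incubations, qPCR/cell
counts, and amplicon OTU tables from the same core.

## What it computes

**Bioturbation.** Sediment mixing is modeled as bio-diffusion in a
two-zone column: coefficient `D_up` above a division depth `z_mix`,
`D_low` below, with burial advection `w`. Tracer concentration obeys

    ∂C/∂t = ∂/∂z( D(z) ∂C/∂z ) − w ∂C/∂z − λC

Excess 210Pb (λ = ln2/22.3 yr⁻¹, constant depositional flux) is solved
at steady state; 137Cs (λ = ln2/30.17 yr⁻¹) as a 29-yr transient from
the Chernobyl fallout impulse. `fit_mixing_model` inverts both profiles
simultaneously for `(D_up, D_low, z_mix)` by multi-start Nelder-Mead on
a combined log-210Pb / inventory-normalized-137Cs loss.

**Rates and energetics.** `srr_from_tracer` converts 35S incubations to
sulfate reduction rates, `SRR = [SO4]·φ·f_TRIS·1.06/t`. Combined with
dsrB-qPCR-derived sulfate-reducer abundances (one gene copy per genome,
7% DNA extraction efficiency), this yields cell-specific rates
(csSRR), biomass turnover times `T_b = (21.5 fg C/12) / (0.08·2·csSRR)`
and, via the burial clock (1 cm per 10.4 yr at w = 0.96 mm/yr), the
cumulative generations a community completes during burial.

**Abundances and community structure.** Extraction-efficiency
calibration (4.1/1.6 16S operons per bacterial/archaeal cell), absolute
OTU and lineage abundances anchored to qPCR, rarefaction, Bray-Curtis
dissimilarities, a from-scratch Kruskal NMDS (isotonic regression +
Guttman updates), Spearman depth correlations with exact small-n
permutation p-values, persister-OTU tracing and top-OTU rankings.

**Synthetic scenarios.** `sedmix.synthetic` generates every input above
with the statistical structure the analysis assumes (forward-model
radionuclides with Poisson counting noise, invertible tracer
incubations, lognormal qPCR noise, multinomial OTU tables with
surface-decliner / mid-peak / subsurface-riser / persister archetypes),
so the whole pipeline is testable without any downloads.

## Worked example

`examples/01_fit_bioturbation.py` simulates noisy radiotracer profiles
at known mixing parameters and inverts them:

```text
truth:  d_up=0.01 m2/yr  d_low=4e-05 m2/yr  z_mix=6.00 cm
fitted: d_up=0.00475 m2/yr  d_low=3.99e-05 m2/yr  z_mix=6.04 cm
loss=1.64  converged=True  z_mix identifiable=True
```

The division depth and the weak deep mixing are recovered tightly; the
upper-zone coefficient is only bounded from below once mixing is fast
enough to homogenize the layer (any larger value fits equally well), so
single noisy fits scatter around it — the structural feature that makes
"at least 10⁻² m² yr⁻¹" the honest statement for intense mixing.

`examples/02_srr_energetics.py` chains rates into the generation budget:

```text
SRR peak: 200 nmol/cm3/d at 1.5 cm; 0.43 nmol/cm3/d at 49.5 cm
csSRR peak: 0.098 fmol/cell/d
turnover: 0.31 yr near the surface -> 52.1 yr at depth (mean 9.9 yr)
total generations over the core: 309; 44% of them above the 6-cm mixed-layer bottom
```

Nearly half of all cell divisions available during half a meter of
burial happen in the top 6 cm — the bioturbated layer is where the
future deep-biosphere community is assembled. The remaining examples
cover community depth structure (`03`) and the end-to-end pipeline
(`04`); `sedmix --help` lists the equivalent CLI subcommands
(`simulate`, `fit-mixing`, `rates`, `abundance`, `energetics`,
`community`, `run-all`).

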