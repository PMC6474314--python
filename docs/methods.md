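# Methods

`sedmix` analyzes the upper half-meter of an organic-rich coastal marine
sediment: how intensely macrofauna mix it, how fast sulfate reducers
respire and divide within and below the mixed layer, and how microbial
community composition restructures with burial. This note documents the
models, their assumptions, the numerical choices, and what the bundled
synthetic scenario does and does not emulate.

## Two-zone bio-diffusion model (`sedmix.mixing`)

Bioturbation is represented as Fickian particle diffusion. The column
is split at a division depth `z_mix` into an upper zone with
bio-diffusion coefficient `d_up` and a lower zone with `d_low`
(`d_up >= d_low`); burial is constant downward advection at the
sedimentation velocity `w`. A tracer concentration obeys

    dC/dt = d/dz( D(z) dC/dz ) - w dC/dz - lambda C

**Excess 210Pb** (half-life 22.3 yr) is solved at steady state with a
prescribed total flux across the sediment surface — the depositional
supply, estimated in the inverse problem from the depth-integrated
excess activity (`flux = lambda * inventory + w * C_bottom`).
**137Cs** (half-life 30.17 yr) is solved as a transient from a unit
impulse in the top millimeter, representing the 1986 Chernobyl fallout
pulse, and integrated for the elapsed time to core collection (29 yr
default).

Assumptions: solid-phase tracers (no porewater exchange), constant
porosity and bulk density, purely local (diffusive) mixing — no
conveyor-belt feeding or discrete burrow geometry. Particles cannot
cross the sediment-water interface except by deposition, so the surface
is a zero-diffusive-flux boundary for the Cs pulse; the bottom of the
36-cm domain has zero diffusive gradient with advective outflow.

### Discretization

Conservative finite volume on a uniform grid (default 0.05 cm).
Face fluxes use the Scharfetter-Gummel exponential fitting
`J = D/dz * [B(-Pe) C_up - B(Pe) C_down]`, `B(x) = x/(e^x - 1)`,
`Pe = w dz / D`, which reduces to central differencing for small Peclet
numbers and to pure upwinding as `D -> 0`, so the same scheme covers
the intensely mixed layer (`Pe ~ 5e-5`) and the no-mixing limit.
Interface diffusivities are harmonic means; the cell containing `z_mix`
gets a thickness-weighted harmonic mean so the solution — and therefore
the fit loss — varies continuously with `z_mix`. The transient uses
implicit Euler steps (default 0.1 yr), unconditionally stable; its only
conservation error is the decay-discretization bias of order
`lambda^2 dt / 2` per year (about 0.05% over 29 yr). Verified limits:
the constant-coefficient steady state matches the two-mode closed form
to better than 0.01%; a no-mixing impulse peaks at `w*t`; inventories
follow pure decay to <1%.

### Inverse fit

Free parameters `(log10 d_up, log10 d_low/d_up, z_mix)`; the ratio
parametrization enforces `d_up >= d_low` by construction. The loss sums
two per-bin-normalized terms: squared residuals of log excess-210Pb
activity (the profile spans orders of magnitude, and log residuals
weight the informative tail) and squared linear residuals of 137Cs
after normalizing both data and model to unit inventory (removing the
unknown fallout magnitude). Counting uncertainties, when present,
enter as relative weights. Minimization is Nelder-Mead from 8
deterministic coarse-grid starts plus a polishing restart of the best
solution. Diagnostics: convergence flag, per-start losses, and a
`z_mix_identifiable` flag that trips when the fitted coefficients are
within 0.1 dex of each other (a single-diffusivity profile carries no
information about the division depth).

Identifiability caveat: once the upper layer is mixed much faster than
it is buried, the tracer profiles saturate to homogeneity and the data
only bound `d_up` from below. Single noisy fits therefore scatter
upward in `d_up` (the fitted lower bound is robust, as is `z_mix` and
`d_low`); recovery tests use the median over seeds.

The box-model penetration estimate is deliberately simple: a pulse
homogenized through a mixed layer of depth `z_mix` and then buried by
the offset that positions the unmixed pulse peak reaches at most
`z_mix + offset`. The unmixed-peak offset is an input datum, not
derived from `w*t` (the two differ slightly in published usage).

## Sulfate reduction rates (`sedmix.srr`)

The 35S method: the fraction of injected tracer recovered as total
reduced inorganic sulfur (TRIS) after incubation, times the ambient
sulfate pool, times the 1.06 isotope-discrimination correction, per
incubation time:

    SRR = [SO4] * phi * (aTRIS - blank) / ((aTRIS - blank) + aSO4) * 1.06 / t

reported as nmol SO4 per cm^3 wet sediment per day. Porosity `phi`
(default 0.8, configurable) converts the porewater concentration to a
whole-sediment pool; killed-control blanks are subtracted per
measurement, with negative corrected TRIS clipped to zero. The formula
assumes tracer turnover is small over the incubation (fraction << 1)
and no reoxidation of reduced 35S.

## Abundance calibration (`sedmix.calibration`)

Gene copies become cells through fixed conversion constants: 4.1 and
1.6 16S rRNA operons per bacterial and archaeal cell, one dsrB copy per
sulfate-reducer genome, and a DNA extraction efficiency (default 7%)
estimated by comparing operon-corrected 16S copies against microscopy
total cell counts (TCC). Per-depth efficiencies above 1 are flagged,
never clipped; the mean over depths is the headline figure with the
pooled ratio available as a diagnostic.

Per-OTU absolute abundances anchor each OTU's relative sequence
abundance to the qPCR copy number of its own domain (bacterial OTU
fraction of bacterial reads x bacterial copies / 4.1) — the only
convention under which OTU abundances sum to each domain's qPCR total.
A whole-community alternative is exposed (`per_domain=False`).
Lineage-level dsrB abundances stay in gene copies per gram
(no efficiency correction), matching how such profiles are usually
plotted; sulfate-reducer *cell* numbers for energetics do apply the
efficiency. An OTU with zero reads at a depth is treated as absent
(NaN), not as zero cells.

## Energetics (`sedmix.energetics`)

Cell-specific sulfate reduction rate: `csSRR = SRR * 1e6 / cells`
(nmol/g/d over cells/g gives fmol/cell/d). Rates per cm^3 are converted
with an explicit dry bulk density; mixing bases without one is a hard
error (default density 1.0 g/cm^3 must be set deliberately for real
cores).

Biomass turnover divides standing biomass carbon by carbon
assimilation: per-cell carbon 21.5 fg C = 21.5/12 fmol C; assimilation
= yield x (mol C oxidized per mol SO4) x csSRR = 0.08 x 2 x csSRR
fmol C/d. The yield applies to the oxidized-carbon flux — the only
reading that uses both the 8% yield and the 2:1 C:SO4 stoichiometry.
With csSRR = 0.07 fmol/cell/d this gives T_b = 160 d = 0.438 yr
(365.25 d/yr). Zero rates give absent (infinite) turnover, flagged.

Burial at `w` = 0.096 cm/yr makes each 1-cm interval a 10.42-yr
residence; generations per bin = residence / T_b, accumulated downward.
Bins with absent T_b contribute zero generations (a conservative
undercount), and the fraction of total generations completed above a
depth interpolates linearly within a bin. The average turnover time
reported by the pipeline is the simple mean over bins, not
depth-weighted.

## Community statistics (`sedmix.community`)

Rarefaction draws exactly `depth` reads per sample without replacement
(multivariate hypergeometric), dropping shallower samples with a
warning; the default depth is the smallest sample total. Dissimilarity
is Bray-Curtis. NMDS is the Kruskal formulation written in-package:
disparities by isotonic (pool-adjacent-violators) regression of
configuration distances on dissimilarity ranks, configuration updates
by Guttman transform with disparities rescaled to the current distance
norm (preventing collapse to the origin), quality measured as stress-1.
One classical-scaling start plus seeded random restarts (default 20);
best configuration returned centered, with the stress history and a
convergence flag. Because only dissimilarity ranks enter, the result is
invariant under strictly increasing transforms of the input — a
property the tests exercise, alongside a cross-check against an
independent SMACOF implementation.

Depth correlations are Spearman with average-rank ties; p-values use
the t-approximation, or the exact two-sided permutation distribution of
rho for small n (all n! orderings, evaluated on ranks).
Benjamini-Hochberg adjustment is offered for families of per-taxon
correlations but not forced. Persisters are OTUs with count >= 1
(configurable) in every sample; the summary reports their share of
reads and of richness in the deepest sample. Top-OTU rankings break
count ties by OTU id for determinism.

## Synthetic scenario (`sedmix.synthetic`)

The default `ScenarioConfig` encodes a station like the one the package
targets: mixing truth `d_up = 1e-2`, `d_low = 4e-5` m^2/yr, `z_mix = 6`
cm, `w = 0.096` cm/yr; SRR peaking at 200 nmol/cm^3/d at 1-3 cm
(suppressed in the top centimeter, where Mn/Fe reduction outcompetes
sulfate reduction) and declining log-linearly to 0.4 at 50 cm; sulfate
falling monotonically from ~27 mM at 3 cm to ~2 mM at 50 cm; TCC
dropping 65% over the mixed zone while bacterial and archaeal gene
copies drop 86% and 70%.

Noise models: Poisson counting statistics for gamma activities
(expected counts = activity x counting-time parameter, declared 1-sigma
= sqrt(counts)/time), lognormal multiplicative noise for qPCR (CV 0.25)
and TCC (CV 0.15) — the qPCR/TCC noise magnitudes are package choices,
as is the counting-time default (roughly 2% relative error on
well-counted surface bins). Every generator is a pure function of
(config, seed); noise-free modes reproduce the deterministic forward
models exactly, and truth parameters ride along in output metadata so
recovery tests are self-contained.

Two internal consistencies deserve note. First, with a constant
extraction efficiency, gene copies exactly track cell numbers, so a TCC
that drops *less* than both domains' copies is only possible if
microscopy counts decline more slowly than extractable cells — the
default scenario therefore carries an independent TCC profile (its own
decline in the mixed zone, tracking total cells below), under which the
*apparent* per-depth efficiency falls from the configured 7% at the
surface to ~3% at depth. Closed-loop efficiency recovery uses the
consistent mode (`tcc_surface=None`), where the configured efficiency
is recovered exactly at every depth. Second, the sulfate-reducer
abundance that reproduces a ~0.07 fmol/cell/d peak csSRR under the 7%
efficiency convention is of the same order as the total cell count —
a known artifact of this calibration chain (the efficiency-corrected
SRM estimate is an upper bound), reproduced rather than hidden.

Community archetypes: 60 surface-decliner OTUs (logistic decline around
6.5 cm), 20 mid-core bloomers (Gaussian at 12 cm), 25 subsurface risers
(logistic rise below ~9 cm, tiny floor everywhere, reaching ~13% of
reads at 50 cm from <0.01% in the mixed zone), and 60 flat persisters.
Within an archetype, OTU weights follow a rank power law (1/(j+1)^0.7).
Counts are one multinomial draw per depth at 20 000 reads.

What the generator does *not* emulate: sequencing error and chimeras,
compositional coupling between domains, patchy horizontal structure or
discrete burrows, seasonal variability, porosity/compaction gradients,
and diagenetic reoxidation of reduced sulfur. Passing recovery tests on
this scenario therefore demonstrates the correctness of the estimators
under the stated statistical model, not robustness to every
real-sediment complication.

## Problem sizes

Defaults keep every computation at desk scale: 720-cell grids for the
PDE solves, 29-yr transients in ~300 implicit steps, 8-start inverse
fits on a 0.1-cm fit grid (tens of seconds), 50-sample x ~165-OTU
community tables, and Monte-Carlo checks at 200-1000 replicates on
coarsened grids.

## Known limitations

- `d_up` is one-sided once mixing saturates the upper layer: the data
  support "at least this fast", and single noisy fits scatter upward.
- The average-efficiency convention (mean of per-depth values) differs
  from the pooled ratio when profiles decline at different rates; both
  are reported.
- Turnover times assume a single uniform cell quota (21.5 fg C) and
  yield; bins with zero measured rate are excluded rather than
  extrapolated, biasing cumulative generations low where rates fall
  below detection.
- The NMDS implementation targets small sample sets (tens of samples);
  no Procrustes alignment across runs is provided.
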