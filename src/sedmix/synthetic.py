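"""Synthetic study-scenario generator.

Produces every input the pipeline consumes — radionuclide profiles,
35S tracer incubations with sulfate, qPCR/TCC profiles and OTU tables —
with the statistical structure the analysis assumes for an organic-rich
coastal sediment with an intensely bioturbated surface layer:

* radionuclides: the two-zone forward model run with the configured
  truth parameters (mixing 0-6 cm, D pair 1e-2 / 4e-5 m^2 yr^-1),
  perturbed by Poisson counting noise;
* sulfate reduction: peak rates ~200 nmol cm^-3 d^-1 at 1-3 cm
  (suppressed in the top cm where Mn/Fe reduction outcompetes sulfate
  reduction), declining log-linearly to ~0.4 at 50 cm; porewater
  sulfate declining monotonically ~27 mM (3 cm) to ~2 mM (50 cm);
  tracer measurements back-computed so the rate calculator inverts them
  exactly;
* abundances: log-declining TCC and per-domain cell numbers, with gene
  copies = cells x operons x extraction efficiency x lognormal noise;
* communities: taxon archetypes (surface-decliners, mid-peak,
  subsurface-risers, flat persisters) whose expected relative
  abundances follow smooth depth responses, sampled multinomially at
  the configured sequencing depth.

Every generator is a pure function of (config, seed): identical seeds
give identical outputs, truth parameters travel in output metadata, and
noise-free mode reproduces the deterministic forward model exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .mixing import GridSpec, MixingParams, steady_state_pb210, transient_cs137
from .profiles import DepthProfile, OtuTable, RadionuclideProfile
from .srr import TracerMeasurement

__all__ = [
    "TaxonArchetype",
    "ScenarioConfig",
    "gen_radionuclide_data",
    "gen_qpcr_tcc",
    "gen_srr_and_sulfate",
    "gen_community",
    "default_archetypes",
    "expected_relative_abundance",
    "true_srr",
    "true_sulfate",
]


@dataclass(frozen=True)
class TaxonArchetype:
    """A family of OTUs sharing one depth-response shape.

    kind
        ``surface`` (logistic decline around ``center``), ``riser``
        (logistic rise below ``center``), ``midpeak`` (Gaussian bump) or
        ``flat`` (depth-independent).
    weight
        The archetype's total expected weight at its own peak, relative
        to the other archetypes.
    floor
        Baseline fraction of ``weight`` present at every depth; any
        archetype with ``floor > 0`` contributes persister OTUs.
    """

    name: str
    kind: str
    n_otus: int
    weight: float
    center: float = 0.0
    width: float = 1.0
    floor: float = 0.0
    taxonomy: str = "unclassified"

    def __post_init__(self) -> None:
        if self.kind not in ("surface", "riser", "midpeak", "flat"):
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.n_otus < 1 or self.weight <= 0 or self.width <= 0:
            raise ValueError("archetype needs n_otus >= 1, weight > 0, width > 0")
        if not (0.0 <= self.floor <= 1.0):
            raise ValueError("floor must lie in [0, 1]")

    def response(self, z: np.ndarray) -> np.ndarray:
        """Expected weight at depth z (cm); never negative."""
        z = np.asarray(z, dtype=float)
        if self.kind == "surface":
            f = 1.0 / (1.0 + np.exp((z - self.center) / self.width))
        elif self.kind == "riser":
            f = 1.0 / (1.0 + np.exp(-(z - self.center) / self.width))
        elif self.kind == "midpeak":
            f = np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))
        else:
            f = np.ones_like(z)
        return self.weight * (self.floor + (1.0 - self.floor) * f)


def default_archetypes() -> tuple[TaxonArchetype, ...]:
    """Archetype mix emulating the down-core community shift: dominant
    surface populations give way to subsurface risers below the mixed
    zone, over a flat persister background."""
    return (
        TaxonArchetype("surface_decliner", "surface", n_otus=60, weight=1.0,
                       center=6.5, width=0.8, taxonomy="Proteobacteria"),
        TaxonArchetype("midpeak", "midpeak", n_otus=20, weight=0.06,
                       center=12.0, width=5.0, taxonomy="Deltaproteobacteria"),
        TaxonArchetype("subsurface_riser", "riser", n_otus=25, weight=0.015,
                       center=9.0, width=1.0, floor=1e-4, taxonomy="Atribacteria"),
        TaxonArchetype("persister_flat", "flat", n_otus=60, weight=0.1,
                       floor=1.0, taxonomy="Chloroflexi"),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """All truth parameters of the synthetic study scenario."""

    true_mixing: MixingParams = field(
        default_factory=lambda: MixingParams(d_up=1e-2, d_low=4e-5, z_mix=6.0,
                                             flux_pb=500.0))
    grid: GridSpec = field(default_factory=lambda: GridSpec(dz=0.05, dt=0.1))
    t_run_cs: float = 29.0
    supported_activity: float = 25.0    # Bq kg^-1, depth-constant
    cs_inventory: float = 50.0          # activity cm^-2 column, impulse size
    counting_time: float | None = 10.0  # expected gamma counts per Bq kg^-1; None = noise off

    # sulfate reduction
    srr_surface_max: float = 200.0      # nmol cm^-3 d^-1, peak at 1-3 cm
    srr_deep: float = 0.4               # nmol cm^-3 d^-1 at 50 cm
    srr_deep_depth: float = 50.0
    sulfate_shallow_mm: float = 27.0    # mM at 3 cm
    sulfate_deep_mm: float = 2.0        # mM at srr_deep_depth
    porosity: float = 0.8
    incubation_time_h: float = 5.0
    tracer_total_activity: float = 2.0e5

    # abundances (cells per g sediment)
    bac_cells_surface: float = 3.6e9
    arch_cells_surface: float = 4.0e8
    srm_cells_surface: float = 3.1e9    # 7%-efficiency-corrected SRM estimate
    k_bac: float = 0.3277               # per cm: 86% drop over 0-6 cm
    k_arch: float = 0.2007              # 70% drop over 0-6 cm
    k_srm: float = 0.03                 # SRM decline much gentler than SRR decline
    tcc_surface: float | None = 4.0e9   # None -> TCC = bacterial + archaeal cells
    k_tcc: float = 0.175                # 65% drop over 0-6 cm
    extraction_efficiency: float = 0.07
    qpcr_cv: float = 0.25               # lognormal CV; 0 = noise off
    tcc_cv: float = 0.15
    operons_bac: float = 4.1
    operons_arch: float = 1.6

    # community
    archetypes: tuple[TaxonArchetype, ...] = field(default_factory=default_archetypes)
    sequencing_depth: int = 20000

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("srr_surface_max", "sulfate_shallow_mm", "sulfate_deep_mm",
                     "bac_cells_surface", "arch_cells_surface", "srm_cells_surface",
                     "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.srr_deep < 0:
            raise ValueError("srr_deep must be non-negative")
        if self.counting_time is not None and self.counting_time <= 0:
            raise ValueError("counting time must be positive (or None for noise off)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per output stream, all derived from seed."""
        return np.random.default_rng([self.seed, stream])

    def truth_metadata(self) -> dict:
        m = asdict(self)
        m["archetypes"] = [a.name for a in self.archetypes]
        return m


# ---------------------------------------------------------------------------
# radionuclides


def gen_radionuclide_data(cfg: ScenarioConfig) -> RadionuclideProfile:
    """Forward-model radionuclide profiles with Poisson counting noise.

    Expected activities come from the steady-state excess-210Pb and
    29-yr transient 137Cs solutions under ``cfg.true_mixing`` plus a
    depth-constant supported activity; each channel is perturbed by
    Poisson noise on expected counts = activity x counting time, and the
    declared 1-sigma is sqrt(counts)/time.  ``counting_time=None``
    returns the noise-free forward model (sigmas omitted).
    """
    params = cfg.true_mixing
    pb_excess = steady_state_pb210(params, cfg.grid, bin_cm=1.0)
    cs = transient_cs137(params, cfg.grid, t_run=cfg.t_run_cs, bin_cm=1.0,
                         inventory=cfg.cs_inventory)
    supported = np.full(len(pb_excess), cfg.supported_activity)
    total = pb_excess.value + supported
    cs_act = cs.value
    meta = {"truth": cfg.truth_metadata(), "seed": cfg.seed}

    if cfg.counting_time is None:
        return RadionuclideProfile(
            bin_top=pb_excess.bin_top, bin_bottom=pb_excess.bin_bottom,
            pb210_total=total, supported=supported, cs137=cs_act, metadata=meta)

    rng = cfg.rng(1)
    tau = cfg.counting_time

    def noisy(expected: np.ndarray):
        counts = rng.poisson(np.clip(expected, 0.0, None) * tau)
        return counts / tau, np.sqrt(np.maximum(counts, 1.0)) / tau

    total_n, s_total = noisy(total)
    supp_n, s_supp = noisy(supported)
    cs_n, s_cs = noisy(cs_act)
    return RadionuclideProfile(
        bin_top=pb_excess.bin_top, bin_bottom=pb_excess.bin_bottom,
        pb210_total=total_n, supported=supp_n, cs137=cs_n,
        sigma_pb210=s_total, sigma_supported=s_supp, sigma_cs137=s_cs,
        metadata=meta)


# ---------------------------------------------------------------------------
# abundances


def _bins_from_depths(depths) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(depths, dtype=float)
    tops = np.clip(z - 0.5, 0.0, None)
    return tops, tops + 1.0


def _true_cells(cfg: ScenarioConfig, z: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "bacteria": cfg.bac_cells_surface * np.exp(-cfg.k_bac * z),
        "archaea": cfg.arch_cells_surface * np.exp(-cfg.k_arch * z),
        "srm": cfg.srm_cells_surface * np.exp(-cfg.k_srm * z),
    }


def gen_qpcr_tcc(cfg: ScenarioConfig, depths) -> tuple[dict[str, DepthProfile], DepthProfile]:
    """qPCR gene-copy profiles (bac/arch 16S, dsrB) and a TCC profile.

    Copies = domain cells x operons x extraction efficiency x lognormal
    noise (CV ``qpcr_cv``; 0 disables noise).  With ``tcc_surface=None``
    TCC is exactly the sum of domain cells, making the extraction
    efficiency recoverable in closed loop; the default scenario instead
    uses an independent, more slowly declining TCC profile so that gene
    copies drop faster than microscopy counts over the mixed zone, as
    observed in real cores.
    """
    z = np.asarray(depths, dtype=float)
    tops, bottoms = _bins_from_depths(z)
    cells = _true_cells(cfg, z)
    eff = cfg.extraction_efficiency
    expected = {
        "bac": cells["bacteria"] * cfg.operons_bac * eff,
        "arch": cells["archaea"] * cfg.operons_arch * eff,
        "dsrb": cells["srm"] * 1.0 * eff,
    }
    if cfg.tcc_surface is None:
        tcc_expected = cells["bacteria"] + cells["archaea"]
    else:
        # microscopy counts decline more slowly than extractable cells inside
        # the mixed zone (k_tcc) and track the total-cell decline below it
        zmix = cfg.true_mixing.z_mix
        tot = cells["bacteria"] + cells["archaea"]
        tot_at_zmix = (cfg.bac_cells_surface * math.exp(-cfg.k_bac * zmix)
                       + cfg.arch_cells_surface * math.exp(-cfg.k_arch * zmix))
        upper = cfg.tcc_surface * np.exp(-cfg.k_tcc * np.minimum(z, zmix))
        tcc_expected = np.where(z <= zmix, upper,
                                cfg.tcc_surface * math.exp(-cfg.k_tcc * zmix)
                                * tot / tot_at_zmix)

    rng = cfg.rng(2)

    def lognoise(values: np.ndarray, cv: float) -> np.ndarray:
        if cv <= 0:
            return values
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return values * np.exp(rng.standard_normal(len(values)) * sigma - sigma**2 / 2.0)

    meta = {"truth": cfg.truth_metadata(), "seed": cfg.seed}
    qpcr = {
        key: DepthProfile(bin_top=tops, bin_bottom=bottoms,
                          value=lognoise(vals, cfg.qpcr_cv),
                          units="copies g-1", metadata=dict(meta))
        for key, vals in expected.items()
    }
    tcc = DepthProfile(bin_top=tops, bin_bottom=bottoms,
                       value=lognoise(tcc_expected, cfg.tcc_cv),
                       units="cells g-1", metadata=dict(meta))
    return qpcr, tcc


# ---------------------------------------------------------------------------
# sulfate reduction


def true_srr(cfg: ScenarioConfig, z: np.ndarray) -> np.ndarray:
    """Deterministic SRR depth response in nmol cm^-3 d^-1.

    Linear ramp over the top cm (sulfate reduction suppressed where Mn
    and Fe reduction dominate), a plateau at ``srr_surface_max`` over
    1-3 cm, then log-linear decline to ``srr_deep`` at ``srr_deep_depth``.
    """
    z = np.asarray(z, dtype=float)
    peak = cfg.srr_surface_max
    out = np.empty_like(z)
    ramp = z <= 1.0
    out[ramp] = peak * (0.5 + 0.5 * z[ramp])
    plateau = (z > 1.0) & (z <= 3.0)
    out[plateau] = peak
    below = z > 3.0
    if cfg.srr_deep > 0:
        k = math.log(peak / cfg.srr_deep) / (cfg.srr_deep_depth - 3.0)
        out[below] = peak * np.exp(-k * (z[below] - 3.0))
    else:
        out[below] = peak * np.clip(
            1.0 - (z[below] - 3.0) / (cfg.srr_deep_depth - 3.0), 0.0, None)
    return out


def true_sulfate(cfg: ScenarioConfig, z: np.ndarray) -> np.ndarray:
    """Monotone porewater sulfate decline (mM): near-seawater at the
    surface, ``sulfate_shallow_mm`` at 3 cm, log-linear to
    ``sulfate_deep_mm`` at depth."""
    z = np.asarray(z, dtype=float)
    c3, cd = cfg.sulfate_shallow_mm, cfg.sulfate_deep_mm
    out = np.empty_like(z)
    shallow = z <= 3.0
    out[shallow] = c3 + (3.0 - z[shallow]) / 3.0  # gentle rise toward seawater
    k = math.log(c3 / cd) / (cfg.srr_deep_depth - 3.0)
    out[~shallow] = c3 * np.exp(-k * (z[~shallow] - 3.0))
    return out


def gen_srr_and_sulfate(cfg: ScenarioConfig, depths):
    """(SRR profile, sulfate profile, tracer measurements).

    The tracer measurements are back-computed so that the rate formula
    reproduces the configured SRR profile exactly: the TRIS fraction is
    inverted from ``SRR = pool x fraction x 1.06 / t`` with zero blanks.
    """
    z = np.asarray(depths, dtype=float)
    tops, bottoms = _bins_from_depths(z)
    srr = true_srr(cfg, z)
    sulfate = true_sulfate(cfg, z)
    t_days = cfg.incubation_time_h / 24.0
    pool = sulfate * 1000.0 * cfg.porosity           # nmol SO4 per cm^3 sediment
    fraction = srr * t_days / (pool * 1.06)
    if np.any(fraction >= 1.0):
        raise ValueError("configured SRR exceeds the available tracer pool")
    a_total = cfg.tracer_total_activity
    measurements = [
        TracerMeasurement(
            a_tris=a_total * f, a_so4=a_total * (1.0 - f),
            sulfate_conc=float(s), incubation_time=cfg.incubation_time_h,
            porosity=cfg.porosity, blank_tris=0.0)
        for f, s in zip(fraction, sulfate)
    ]
    meta = {"truth": cfg.truth_metadata(), "seed": cfg.seed}
    srr_prof = DepthProfile(bin_top=tops, bin_bottom=bottoms, value=srr,
                            units="nmol cm-3 d-1", metadata=dict(meta))
    so4_prof = DepthProfile(bin_top=tops, bin_bottom=bottoms, value=sulfate,
                            units="mM", metadata=dict(meta))
    return srr_prof, so4_prof, measurements


# ---------------------------------------------------------------------------
# community


def expected_relative_abundance(cfg: ScenarioConfig, depths) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Expected per-OTU relative abundances at each depth.

    Within an archetype, OTU weights follow a power-law rank series
    (rank j gets 1/(j+1)^0.7), so a few OTUs dominate each guild.
    Returns (matrix depths x OTUs, otu_ids, taxonomy, archetype names).
    """
    z = np.asarray(depths, dtype=float)
    cols, otu_ids, taxonomy, arch_names = [], [], [], []
    for a in cfg.archetypes:
        ranks = np.arange(a.n_otus, dtype=float)
        shares = 1.0 / (ranks + 1.0) ** 0.7
        shares /= shares.sum()
        resp = a.response(z)                     # (n_depths,)
        cols.append(resp[:, None] * shares[None, :])
        otu_ids.extend(f"{a.name}_{j:03d}" for j in range(a.n_otus))
        taxonomy.extend([a.taxonomy] * a.n_otus)
        arch_names.extend([a.name] * a.n_otus)
    weights = np.concatenate(cols, axis=1)
    if np.any(weights < 0):
        raise ValueError("depth response produced a negative expectation")
    rel = weights / weights.sum(axis=1, keepdims=True)
    return rel, otu_ids, taxonomy, arch_names


def gen_community(cfg: ScenarioConfig, depths) -> OtuTable:
    """Multinomial OTU table over the configured archetypes.

    Needs at least two archetypes and a sequencing depth of 1000+.
    Counts at each depth are one multinomial draw of
    ``cfg.sequencing_depth`` reads from the expected relative
    abundances; OTUs from archetypes with a positive floor have nonzero
    expectation at every depth (the persister pool).
    """
    if len(cfg.archetypes) < 2:
        raise ValueError("need at least 2 taxon archetypes")
    if cfg.sequencing_depth < 1000:
        raise ValueError("sequencing depth must be at least 1000")
    z = np.asarray(depths, dtype=float)
    rel, otu_ids, taxonomy, arch_names = expected_relative_abundance(cfg, z)
    rng = cfg.rng(3)
    counts = np.stack([rng.multinomial(cfg.sequencing_depth, rel[i])
                       for i in range(len(z))])
    return OtuTable(
        counts=counts, otu_ids=tuple(otu_ids), taxonomy=tuple(taxonomy),
        sample_ids=tuple(f"d{zz:g}cm" for zz in z), sample_depth=z,
        metadata={"truth": cfg.truth_metadata(), "seed": cfg.seed,
                  "archetype_of_otu": tuple(arch_names)},
    )
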