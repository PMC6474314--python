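"""Absolute-abundance calibration of qPCR and amplicon data.

qPCR yields marker-gene copies per g sediment; converting these to cell
abundances needs (i) the average marker copy number per genome — 4.1
and 1.6 16S rRNA operons per bacterial and archaeal cell, one dsrB copy
per sulfate-reducer genome — and (ii) the DNA extraction efficiency,
estimated by comparing operon-corrected 16S copies to microscopy total
cell counts (TCC).  Relative sequence abundances from amplicon OTU
tables are anchored to the qPCR copy numbers to obtain per-OTU and
per-lineage absolute abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import DepthProfile, OtuTable, ProfileValidationError

__all__ = [
    "CalibrationConstants",
    "AbundanceProfile",
    "EfficiencyResult",
    "extraction_efficiency",
    "srm_cells",
    "absolute_otu_abundance",
    "lineage_absolute",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Conversion assumptions shared across the calibration and energetics steps.

    operons_bac / operons_arch
        Average 16S rRNA gene copies per bacterial / archaeal cell
        (4.1 and 1.6).
    dsrb_per_genome
        dsrB copies per sulfate-reducer genome (single copy assumed).
    extraction_efficiency
        Fraction of cells whose DNA the extraction recovers (default 0.07).
    carbon_per_cell
        fg C per cell (21.5, subseafloor average).
    growth_yield
        Fraction of oxidized organic carbon assimilated into biomass (0.08).
    c_per_sulfate
        mol organic C oxidized per mol sulfate reduced (2).
    sed_rate
        Sedimentation rate, cm yr^-1 (0.096).
    """

    operons_bac: float = 4.1
    operons_arch: float = 1.6
    dsrb_per_genome: float = 1.0
    extraction_efficiency: float = 0.07
    carbon_per_cell: float = 21.5
    growth_yield: float = 0.08
    c_per_sulfate: float = 2.0
    sed_rate: float = 0.096

    def __post_init__(self) -> None:
        for name in ("operons_bac", "operons_arch", "dsrb_per_genome",
                     "extraction_efficiency", "carbon_per_cell",
                     "growth_yield", "c_per_sulfate", "sed_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.extraction_efficiency > 1.0:
            raise ValueError("extraction_efficiency cannot exceed 1")


@dataclass(frozen=True)
class AbundanceProfile:
    """Cell (or gene-copy) abundance per depth bin with an explicit basis."""

    profile: DepthProfile
    basis: str = "per_g"       # "per_g" or "per_cm3"
    label: str = ""

    def __post_init__(self) -> None:
        if self.basis not in ("per_g", "per_cm3"):
            raise ValueError("basis must be 'per_g' or 'per_cm3'")
        vals = self.profile.value
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def value(self) -> np.ndarray:
        return self.profile.value


@dataclass(frozen=True)
class EfficiencyResult:
    """Per-depth DNA extraction efficiencies plus summary statistics."""

    per_depth: DepthProfile
    mean: float
    pooled: float              # total corrected copies / total TCC, diagnostic
    exceeds_one: tuple[int, ...]   # bins where efficiency > 1 (flagged, not clipped)


def extraction_efficiency(tcc: AbundanceProfile, bac_copies: DepthProfile,
                          arch_copies: DepthProfile,
                          c: CalibrationConstants = CalibrationConstants()) -> EfficiencyResult:
    """DNA extraction efficiency from TCC vs operon-corrected 16S copies.

    Per depth: ``(bac/4.1 + arch/1.6) / TCC``.  Returns the per-depth
    vector, its mean over finite bins, and the pooled ratio (summed
    corrected copies over summed TCC) as a diagnostic.  Values above 1
    are flagged, never clipped.
    """
    prof = tcc.profile
    if not (prof.same_bins(bac_copies) and prof.same_bins(arch_copies)):
        raise ProfileValidationError("TCC and qPCR profiles must share bins")
    if np.any(np.nan_to_num(prof.value, nan=1.0) <= 0):
        bad = int(np.argmax(np.nan_to_num(prof.value, nan=1.0) <= 0))
        raise ValueError(f"zero TCC in bin {bad}: efficiency undefined")
    cells_implied = bac_copies.value / c.operons_bac + arch_copies.value / c.operons_arch
    eff = cells_implied / prof.value
    finite = np.isfinite(eff)
    per_depth = prof.with_values(eff, units="fraction")
    return EfficiencyResult(
        per_depth=per_depth,
        mean=float(np.mean(eff[finite])),
        pooled=float(np.nansum(cells_implied) / np.nansum(prof.value)),
        exceeds_one=tuple(int(i) for i in np.where(eff > 1.0 + 1e-9)[0]),
    )


def srm_cells(dsrb_copies: DepthProfile,
              c: CalibrationConstants = CalibrationConstants(),
              basis: str = "per_g") -> AbundanceProfile:
    """Sulfate-reducer cell abundance from dsrB copies.

    ``cells = copies / (dsrB per genome) / extraction efficiency`` —
    e.g. 7e5 copies/g at 7% efficiency imply 1e7 cells/g.
    """
    if np.any(dsrb_copies.value[np.isfinite(dsrb_copies.value)] < 0):
        raise ValueError("dsrB copy numbers must be non-negative")
    cells = dsrb_copies.value / c.dsrb_per_genome / c.extraction_efficiency
    return AbundanceProfile(
        profile=dsrb_copies.with_values(cells, units=f"cells {basis.replace('per_', '')}-1"),
        basis=basis, label="SRM",
    )


def _depth_bins_from_samples(depths: np.ndarray, width: float = 1.0):
    tops = np.asarray(depths, dtype=float) - width / 2.0
    tops = np.clip(tops, 0.0, None)
    return tops, tops + width


def absolute_otu_abundance(otus: OtuTable, bac_copies: DepthProfile,
                           arch_copies: DepthProfile,
                           domain_map: dict[str, str],
                           c: CalibrationConstants = CalibrationConstants(),
                           per_domain: bool = True) -> dict[str, AbundanceProfile]:
    """Per-OTU absolute cell abundances anchored to 16S qPCR.

    For OTU *i* in the sample at depth *z*:
    ``cells_i(z) = rel_abund_i(z) * copies_domain(z) / operons_domain``,
    with relative abundance computed within the OTU's own domain by
    default (``per_domain=True``; this conserves each domain's qPCR
    total) or over the whole community otherwise.  An OTU with zero
    count at a depth gets NaN (absent), not zero.  Samples are matched
    to qPCR bins by depth (sample depth inside ``[top, bottom)``).
    """
    unmapped = [o for o in otus.otu_ids if o not in domain_map]
    if unmapped:
        raise KeyError(f"OTUs without a domain assignment: {unmapped[:5]}")
    domains = np.array([domain_map[o] for o in otus.otu_ids])
    for d in np.unique(domains):
        if d not in ("bacteria", "archaea"):
            raise ValueError(f"unknown domain label: {d!r}")

    copies = {"bacteria": bac_copies, "archaea": arch_copies}
    operons = {"bacteria": c.operons_bac, "archaea": c.operons_arch}

    def copies_at(dom: str, z: float) -> float:
        p = copies[dom]
        mask = (p.bin_top <= z) & (z < p.bin_bottom)
        if not mask.any():
            raise ValueError(f"no qPCR bin covers sample depth {z} cm")
        return float(p.value[mask][0])

    counts = otus.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    n_s = otus.n_samples
    cells = np.full((n_s, otus.n_otus), np.nan)
    for s in range(n_s):
        z = float(otus.sample_depth[s])
        for dom in ("bacteria", "archaea"):
            sel = domains == dom
            if not sel.any():
                continue
            denom = counts[s, sel].sum() if per_domain else totals[s]
            if denom <= 0:
                continue
            scale = copies_at(dom, z) / operons[dom]
            vals = counts[s, sel] / denom * scale
            vals[counts[s, sel] == 0] = np.nan   # absent, not zero
            cells[s, sel] = vals

    tops, bottoms = _depth_bins_from_samples(otus.sample_depth)
    order = np.argsort(tops, kind="stable")
    out: dict[str, AbundanceProfile] = {}
    for j, otu in enumerate(otus.otu_ids):
        prof = DepthProfile(bin_top=tops[order], bin_bottom=bottoms[order],
                            value=cells[order, j], units="cells g-1")
        out[otu] = AbundanceProfile(profile=prof, basis="per_g", label=otus.taxonomy[j])
    return out


def lineage_absolute(dsrb_otus: OtuTable, dsrb_copies: DepthProfile) -> dict[str, AbundanceProfile]:
    """Per-lineage absolute dsrB abundances (gene copies per g sediment).

    Lineage copies = whole-community relative sequence abundance times
    the dsrB qPCR copy number at that depth; deliberately *not*
    efficiency-corrected, so values stay in gene-copy units.  Depths
    with no sequencing data stay absent (NaN).
    """
    lineages = sorted(set(dsrb_otus.taxonomy))
    rel = dsrb_otus.relative_abundance()
    tops, bottoms = _depth_bins_from_samples(dsrb_otus.sample_depth)

    def copies_at(z: float) -> float:
        mask = (dsrb_copies.bin_top <= z) & (z < dsrb_copies.bin_bottom)
        if not mask.any():
            raise ValueError(f"no dsrB qPCR bin covers sample depth {z} cm")
        return float(dsrb_copies.value[mask][0])

    qpcr = np.array([copies_at(float(z)) for z in dsrb_otus.sample_depth])
    order = np.argsort(tops, kind="stable")
    out: dict[str, AbundanceProfile] = {}
    for lin in lineages:
        sel = np.array([t == lin for t in dsrb_otus.taxonomy])
        lin_rel = np.nansum(np.where(np.isnan(rel[:, sel]), 0.0, rel[:, sel]), axis=1)
        lin_rel[np.all(np.isnan(rel), axis=1)] = np.nan
        vals = lin_rel * qpcr
        prof = DepthProfile(bin_top=tops[order], bin_bottom=bottoms[order],
                            value=vals[order], units="gene copies g-1")
        out[lin] = AbundanceProfile(profile=prof, basis="per_g", label=lin)
    return out
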