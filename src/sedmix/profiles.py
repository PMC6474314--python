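"""Depth-binned profile containers and CSV/TSV readers/writers.

Everything measured or derived in this package travels as a
:class:`DepthProfile`: a stack of non-overlapping, half-open 1-cm (or
arbitrary-width) depth bins ``[top, bottom)`` in cm below seafloor,
positive downward, each carrying a value, an optional 1-sigma
uncertainty and a unit label.  Gamma-spectroscopy data are carried as a
:class:`RadionuclideProfile` (total 210Pb, 226Ra-supported activity and
137Cs on a shared binning) and amplicon count data as an
:class:`OtuTable` (integer sample x OTU matrix with per-OTU taxonomy
and per-sample depth).

Files are plain UTF-8 CSV/TSV with a header row; missing values are
empty cells and stay missing (NaN), never zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "RadionuclideProfile",
    "OtuTable",
    "ProfileValidationError",
    "read_profile",
    "write_profile",
    "read_otu_table",
    "write_otu_table",
    "read_radionuclide_profile",
    "write_radionuclide_profile",
]


class ProfileValidationError(ValueError):
    """Raised when a profile or table violates its structural invariants."""


def _check_bins(bin_top: np.ndarray, bin_bottom: np.ndarray) -> None:
    if len(bin_top) == 0:
        return
    if np.any(bin_top < 0):
        raise ProfileValidationError("bin tops must be non-negative (cm below seafloor)")
    if np.any(bin_bottom <= bin_top):
        bad = int(np.argmax(bin_bottom <= bin_top))
        raise ProfileValidationError(f"bin_bottom must exceed bin_top (row {bad})")
    # bins are sorted by top; half-open [top, bottom) intervals must not
    # overlap (tolerance absorbs float round-off in adjacent fine bins)
    tol = 1e-9 * max(1.0, float(np.max(bin_bottom)))
    for i in range(1, len(bin_top)):
        if bin_top[i] < bin_bottom[i - 1] - tol:
            raise ProfileValidationError(
                f"overlapping depth bins at row {i}: "
                f"[{bin_top[i]}, {bin_bottom[i]}) intersects "
                f"[{bin_top[i - 1]}, {bin_bottom[i - 1]})"
            )


@dataclass(frozen=True)
class DepthProfile:
    """A depth-binned quantity: half-open bins ``[top, bottom)`` in cm.

    Parameters
    ----------
    bin_top, bin_bottom
        Bin boundaries in cm below seafloor; non-overlapping, sorted on
        construction.
    value
        The measured/derived quantity per bin; NaN marks an absent value.
    sigma
        Optional 1-sigma uncertainty per bin (non-negative where present).
    units
        Free-text unit label, e.g. ``"Bq kg-1"`` or ``"nmol cm-3 d-1"``.
    """

    bin_top: np.ndarray
    bin_bottom: np.ndarray
    value: np.ndarray
    sigma: np.ndarray | None = None
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        top = np.asarray(self.bin_top, dtype=float)
        bottom = np.asarray(self.bin_bottom, dtype=float)
        value = np.asarray(self.value, dtype=float)
        sigma = None if self.sigma is None else np.asarray(self.sigma, dtype=float)
        if not (len(top) == len(bottom) == len(value)):
            raise ProfileValidationError("bin_top, bin_bottom and value must have equal length")
        if sigma is not None and len(sigma) != len(value):
            raise ProfileValidationError("sigma length mismatch")
        order = np.argsort(top, kind="stable")
        top, bottom, value = top[order], bottom[order], value[order]
        if sigma is not None:
            sigma = sigma[order]
        _check_bins(top, bottom)
        if sigma is not None and np.any(sigma[np.isfinite(sigma)] < 0):
            raise ProfileValidationError("sigma must be non-negative")
        object.__setattr__(self, "bin_top", top)
        object.__setattr__(self, "bin_bottom", bottom)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.value)

    @property
    def midpoint(self) -> np.ndarray:
        """Bin midpoints in cm, used wherever a single depth per bin is needed."""
        return 0.5 * (self.bin_top + self.bin_bottom)

    @property
    def thickness(self) -> np.ndarray:
        return self.bin_bottom - self.bin_top

    def inventory(self) -> float:
        """Depth-integrated value (value x bin thickness), ignoring NaN bins."""
        v = np.nan_to_num(self.value, nan=0.0)
        return float(np.sum(v * self.thickness))

    def with_values(self, value: np.ndarray, sigma: np.ndarray | None = None,
                    units: str | None = None) -> "DepthProfile":
        """Same binning, new values (and optionally new sigma/units)."""
        return DepthProfile(
            bin_top=self.bin_top.copy(),
            bin_bottom=self.bin_bottom.copy(),
            value=np.asarray(value, dtype=float),
            sigma=sigma,
            units=self.units if units is None else units,
            metadata=dict(self.metadata),
        )

    def same_bins(self, other: "DepthProfile", atol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.bin_top, other.bin_top, atol=atol)
            and np.allclose(self.bin_bottom, other.bin_bottom, atol=atol)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"bin_top": self.bin_top, "bin_bottom": self.bin_bottom, "value": self.value}
        )
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df

    def equals(self, other: "DepthProfile", rtol: float = 0.0, atol: float = 1e-12) -> bool:
        if not self.same_bins(other, atol=atol):
            return False
        if not np.allclose(self.value, other.value, rtol=rtol, atol=atol, equal_nan=True):
            return False
        if (self.sigma is None) != (other.sigma is None):
            return False
        if self.sigma is not None and not np.allclose(
            self.sigma, other.sigma, rtol=rtol, atol=atol, equal_nan=True
        ):
            return False
        return True


@dataclass(frozen=True)
class RadionuclideProfile:
    """Gamma-count activities per depth bin: total 210Pb, supported activity, 137Cs.

    All channels share one binning; activities in Bq per kg dry sediment,
    with per-channel 1-sigma counting uncertainties.
    """

    bin_top: np.ndarray
    bin_bottom: np.ndarray
    pb210_total: np.ndarray
    supported: np.ndarray
    cs137: np.ndarray
    sigma_pb210: np.ndarray | None = None
    sigma_supported: np.ndarray | None = None
    sigma_cs137: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        top = np.asarray(self.bin_top, dtype=float)
        bottom = np.asarray(self.bin_bottom, dtype=float)
        _check_bins(top, bottom)
        n = len(top)
        for name in ("pb210_total", "supported", "cs137"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ProfileValidationError(f"{name} length mismatch")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ProfileValidationError(f"{name} activities must be non-negative")
            object.__setattr__(self, name, arr)
        for name in ("sigma_pb210", "sigma_supported", "sigma_cs137"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != n or np.any(arr[np.isfinite(arr)] < 0):
                    raise ProfileValidationError(f"{name} invalid")
                object.__setattr__(self, name, arr)
        object.__setattr__(self, "bin_top", top)
        object.__setattr__(self, "bin_bottom", bottom)

    def __len__(self) -> int:
        return len(self.bin_top)

    def channel(self, name: str) -> DepthProfile:
        """Extract one channel (``pb210_total``, ``supported`` or ``cs137``)."""
        sigma = getattr(self, f"sigma_{'pb210' if name == 'pb210_total' else name}", None)
        return DepthProfile(
            bin_top=self.bin_top,
            bin_bottom=self.bin_bottom,
            value=getattr(self, name),
            sigma=sigma,
            units="Bq kg-1",
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class OtuTable:
    """Sample x OTU integer count matrix with taxonomy and sample depths."""

    counts: np.ndarray              # (n_samples, n_otus) non-negative ints
    otu_ids: tuple[str, ...]
    taxonomy: tuple[str, ...]       # one label per OTU; "unclassified" allowed
    sample_ids: tuple[str, ...]
    sample_depth: np.ndarray        # cm per sample
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ProfileValidationError("counts must be a 2-D sample x OTU matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.allclose(as_int, counts):
                raise ProfileValidationError("counts must be integral")
            counts = as_int
        if np.any(counts < 0):
            raise ProfileValidationError("counts must be non-negative")
        n_s, n_o = counts.shape
        otu_ids = tuple(str(o) for o in self.otu_ids)
        if len(otu_ids) != n_o:
            raise ProfileValidationError("otu_ids length mismatch")
        if len(set(otu_ids)) != n_o:
            seen: set[str] = set()
            for o in otu_ids:
                if o in seen:
                    raise ProfileValidationError(f"duplicated OTU id: {o!r}")
                seen.add(o)
        taxonomy = tuple(str(t) if t else "unclassified" for t in self.taxonomy)
        if len(taxonomy) != n_o:
            raise ProfileValidationError("taxonomy length mismatch")
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(sample_ids) != n_s:
            raise ProfileValidationError("sample_ids length mismatch")
        depth = np.asarray(self.sample_depth, dtype=float)
        if len(depth) != n_s or np.any(~np.isfinite(depth)):
            raise ProfileValidationError("every sample needs a finite depth")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "otu_ids", otu_ids)
        object.__setattr__(self, "taxonomy", taxonomy)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "sample_depth", depth)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances; rows sum to 1 (NaN for empty samples)."""
        totals = self.sample_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals[:, None] > 0, self.counts / totals[:, None], np.nan)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(str(sample))
        except ValueError:
            raise KeyError(f"unknown sample: {sample!r}") from None

    def select_samples(self, idx: np.ndarray) -> "OtuTable":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            counts=self.counts[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            sample_depth=self.sample_depth[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-export layout: rows = OTUs, columns = taxonomy + one per sample."""
        df = pd.DataFrame({"otu_id": self.otu_ids, "taxonomy": self.taxonomy})
        for i, s in enumerate(self.sample_ids):
            df[s] = self.counts[i]
        return df


# ---------------------------------------------------------------------------
# readers / writers


def read_profile(path: str | Path, schema: dict[str, str] | None = None,
                 units: str = "") -> DepthProfile:
    """Read a DepthProfile from CSV (or TSV by suffix).

    ``schema`` maps logical names (bin_top, bin_bottom, value, sigma) to
    column names; by default columns are expected under the logical
    names.  Rows may come in any depth order; the result is sorted.
    Empty cells become NaN (absent), never zero.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    schema = schema or {}
    cols = {k: schema.get(k, k) for k in ("bin_top", "bin_bottom", "value", "sigma")}
    for logical in ("bin_top", "bin_bottom", "value"):
        if cols[logical] not in df.columns:
            raise ProfileValidationError(
                f"{path.name}: missing required column {cols[logical]!r}"
            )
    for logical in ("bin_top", "bin_bottom", "value"):
        col = cols[logical]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ProfileValidationError(
                f"{path.name}: non-numeric cell in column {col!r} at data row {row}"
            )
        df[col] = coerced
    sigma = None
    if cols["sigma"] in df.columns:
        sigma = pd.to_numeric(df[cols["sigma"]], errors="coerce").to_numpy()
    return DepthProfile(
        bin_top=df[cols["bin_top"]].to_numpy(),
        bin_bottom=df[cols["bin_bottom"]].to_numpy(),
        value=df[cols["value"]].to_numpy(),
        sigma=sigma,
        units=units,
    )


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    """Write a DepthProfile as CSV/TSV; full round-trip precision (repr floats)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    profile.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_radionuclide_profile(path: str | Path) -> RadionuclideProfile:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = ["bin_top", "bin_bottom", "pb210_total", "supported", "cs137"]
    for col in required:
        if col not in df.columns:
            raise ProfileValidationError(f"{path.name}: missing column {col!r}")
    kwargs = {col: pd.to_numeric(df[col], errors="coerce").to_numpy() for col in required}
    for col in ("sigma_pb210", "sigma_supported", "sigma_cs137"):
        if col in df.columns:
            kwargs[col] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    return RadionuclideProfile(**kwargs)


def write_radionuclide_profile(profile: RadionuclideProfile, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    data = {
        "bin_top": profile.bin_top,
        "bin_bottom": profile.bin_bottom,
        "pb210_total": profile.pb210_total,
        "supported": profile.supported,
        "cs137": profile.cs137,
    }
    for col in ("sigma_pb210", "sigma_supported", "sigma_cs137"):
        arr = getattr(profile, col)
        if arr is not None:
            data[col] = arr
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_otu_table(path: str | Path, sample_depth: dict[str, float]) -> OtuTable:
    """Read an OTU table from TSV (rows = OTUs, columns = otu_id, taxonomy, samples).

    ``sample_depth`` maps every sample column to its depth in cm; a
    sample column without a depth is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("otu_id", "taxonomy"):
        if col not in df.columns:
            raise ProfileValidationError(f"{path.name}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("otu_id", "taxonomy")]
    if not sample_cols:
        raise ProfileValidationError(f"{path.name}: no sample columns")
    missing = [c for c in sample_cols if c not in sample_depth]
    if missing:
        raise ProfileValidationError(f"samples without depth: {missing}")
    counts = df[sample_cols].to_numpy()
    if np.any(~np.isfinite(counts.astype(float))):
        raise ProfileValidationError(f"{path.name}: missing counts are not allowed")
    return OtuTable(
        counts=np.asarray(counts, dtype=float).T,  # validated + cast in __post_init__
        otu_ids=tuple(df["otu_id"].astype(str)),
        taxonomy=tuple(df["taxonomy"].fillna("unclassified").astype(str)),
        sample_ids=tuple(sample_cols),
        sample_depth=np.array([sample_depth[c] for c in sample_cols], dtype=float),
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
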