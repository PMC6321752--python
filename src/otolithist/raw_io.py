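"""Containers and plain-text I/O for LA-ICP-MS runs and calibrated transects.

A laser-ablation run is a time-ordered stream of per-isotope intensities
(counts per second) with a role: ``sample`` (an otolith transect), ``blank``
(1% HNO3 carrier acid) or ``standard`` (a certified otolith reference
material bracketing each block of samples). Calibrated transects are molar
Sr:Ca profiles indexed by position along the ablation path.

File formats are deliberately minimal: CSV with a header row for runs
(one time column plus one column per isotope, labelled element+mass such as
``Sr87``), and CSV with a small ``#``-prefixed metadata header for profiles.
Vendor binary formats are out of scope; export to CSV upstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError

ROLES = ("sample", "blank", "standard")
POINT_FLAGS = ("ok", "missing", "negative", "below_lod", "outlier_removed")
QUALITY_CODES = ("F", "H", "P", "O")
CAPTURE_CONTEXTS = ("freshwater", "estuary", "marine", "unknown")

_TIME_COLUMNS = ("time_s", "index", "time")
_ISOTOPE_RE = re.compile(r"^[A-Z][a-z]?\d{1,3}$")


def element_of(isotope: str) -> str:
    """``"Sr87" -> "Sr"``; raises FormatError for labels that are not element+mass."""
    m = _ISOTOPE_RE.match(isotope)
    if not m:
        raise FormatError(f"not an isotope label (expected element+mass, e.g. Sr87): {isotope!r}")
    return re.match(r"^[A-Z][a-z]?", isotope).group(0)


# ---------------------------------------------------------------------------
# Instrument configuration
# ---------------------------------------------------------------------------

#: Natural isotopic abundances (fraction of the element) for the default panel.
#: The Ca isotope is configurable: instruments report various minor Ca isotopes,
#: and only stable, naturally occurring ones have a defined abundance.
DEFAULT_ABUNDANCES = {"Sr87": 0.0700, "Ca43": 0.00135}
DEFAULT_ATOMIC_MASSES = {"Sr": 87.62, "Ca": 40.078}


@dataclass
class InstrumentConfig:
    """Acquisition and data-reduction settings for one LA-ICP-MS session.

    Parameters
    ----------
    standard_certified_ratio
        Certified molar Sr:Ca of the bracketing reference material, in
        mmol/mol (or a mass ratio, mg Sr per g Ca, when
        ``certified_is_mass_ratio`` is set). There is no default: the value
        belongs to the reference material's certificate, not to this package.
    scan_speed
        Laser raster speed in µm/s. Positions are ``time × scan_speed``.
    block_size
        Consecutive raw reads averaged into one data point.
    lod_sd_multiplier, lod_sign
        Limit-of-detection threshold per isotope is
        ``blank_mean + lod_sign × lod_sd_multiplier × blank_sd``. The default
        sign of -1 reproduces a "mean − 3·SD" rule; set ``lod_sign=+1`` for
        the conventional "mean + 3·SD".
    """

    standard_certified_ratio: float
    scan_speed: float = 5.0
    block_size: int = 10
    isotope_abundance: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ABUNDANCES))
    atomic_mass: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ATOMIC_MASSES))
    certified_is_mass_ratio: bool = False
    lod_sd_multiplier: float = 3.0
    lod_sign: int = -1
    sr_isotope: str = "Sr87"
    ca_isotope: str = "Ca43"

    def __post_init__(self) -> None:
        if self.scan_speed <= 0:
            raise ValueError("scan_speed must be > 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        for iso, ab in self.isotope_abundance.items():
            if not (0.0 < ab <= 1.0):
                raise ValueError(f"abundance of {iso} must be in (0, 1], got {ab}")
        for el, m in self.atomic_mass.items():
            if m <= 0:
                raise ValueError(f"atomic mass of {el} must be > 0, got {m}")
        if self.standard_certified_ratio <= 0:
            raise ValueError("standard_certified_ratio must be > 0")
        if self.lod_sign not in (-1, 1):
            raise ValueError("lod_sign must be -1 or +1")

    @property
    def certified_mmol_mol(self) -> float:
        """Certified standard ratio expressed as molar mmol Sr / mol Ca."""
        if not self.certified_is_mass_ratio:
            return self.standard_certified_ratio
        m_sr = self.atomic_mass[element_of(self.sr_isotope)]
        m_ca = self.atomic_mass[element_of(self.ca_isotope)]
        # (mg Sr per g Ca) -> mmol/mol
        return self.standard_certified_ratio * m_ca / m_sr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InstrumentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"instrument config {path} is not a key-value mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Raw runs
# ---------------------------------------------------------------------------

@dataclass
class RawRun:
    """One time-ordered instrument stream (sample, blank or standard).

    ``intensities`` maps isotope label to a float array aligned with
    ``times``; missing reads are NaN and mirrored in ``flags``. Negative
    raw counts are kept but flagged ``negative``.
    """

    run_id: str
    role: str
    times: np.ndarray
    intensities: dict[str, np.ndarray]
    fish_id: str | None = None
    block_id: int = 0
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role in ("blank", "standard") and self.fish_id:
            raise ValueError(f"{self.role} runs carry no fish_id (got {self.fish_id!r})")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.intensities = {k: np.asarray(v, dtype=float) for k, v in self.intensities.items()}
        for iso, arr in self.intensities.items():
            if arr.shape != self.times.shape:
                raise ValueError(f"intensity stream {iso} length {len(arr)} != times length {len(self.times)}")
        if self.flags is None:
            self.flags = self._derive_flags()
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.times.shape:
                raise ValueError("flags length mismatch")

    def _derive_flags(self) -> np.ndarray:
        flags = np.full(len(self.times), "ok", dtype=object)
        for arr in self.intensities.values():
            flags[np.isnan(arr)] = "missing"
        for arr in self.intensities.values():
            neg = (arr < 0) & (flags == "ok")
            flags[neg] = "negative"
        return flags

    def __len__(self) -> int:
        return len(self.times)

    @property
    def isotopes(self) -> tuple[str, ...]:
        return tuple(self.intensities)

    def usable_mask(self) -> np.ndarray:
        """Points that carry a numeric value for every isotope (ok or negative)."""
        return np.isin(self.flags, ("ok", "negative"))

    def replace(self, **kwargs) -> "RawRun":
        data = dict(
            run_id=self.run_id, role=self.role, times=self.times,
            intensities=self.intensities, fish_id=self.fish_id,
            block_id=self.block_id, flags=self.flags,
        )
        data.update(kwargs)
        return RawRun(**data)


def read_raw_run(
    path: str | Path,
    role: str,
    config: InstrumentConfig,
    fish_id: str | None = None,
    block_id: int = 0,
) -> RawRun:
    """Parse one instrument CSV export into a :class:`RawRun`.

    The file must have a header row with a time column (``time_s``,
    ``time`` or ``index``) and one column per isotope. Both configured
    isotopes (``config.sr_isotope``, ``config.ca_isotope``) are required;
    a missing one raises :class:`FormatError` naming the column. Malformed
    numeric cells become flagged missing points, never silent drops.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if table.empty and not len(table.columns):
        raise EmptyInputError(f"{path}: file is empty")
    table.columns = [c.strip() for c in table.columns]

    time_col = next((c for c in table.columns if c.lower() in _TIME_COLUMNS), None)
    if time_col is None:
        raise FormatError(f"{path}: no time column (expected one of {_TIME_COLUMNS})")
    for required in (config.sr_isotope, config.ca_isotope):
        if required not in table.columns:
            raise FormatError(f"{path}: missing required isotope column {required!r}")
    isotope_cols = [c for c in table.columns if c != time_col and _ISOTOPE_RE.match(c)]
    if len(isotope_cols) < 2:
        raise FormatError(f"{path}: header must name at least two isotope columns")
    if not len(table):
        raise EmptyInputError(f"{path}: no data rows")

    times = pd.to_numeric(table[time_col], errors="coerce").to_numpy()
    if np.isnan(times).any():
        raise FormatError(f"{path}: non-numeric value in time column {time_col!r}")
    if time_col.lower() == "index":
        # read index at the instrument repetition rate; treated as seconds-equivalent
        times = times.astype(float)
    intensities = {c: pd.to_numeric(table[c], errors="coerce").to_numpy() for c in isotope_cols}
    return RawRun(
        run_id=path.stem, role=role, times=times, intensities=intensities,
        fish_id=fish_id if role == "sample" else None, block_id=block_id,
    )


# ---------------------------------------------------------------------------
# Calibrated profiles
# ---------------------------------------------------------------------------

@dataclass
class ElementProfile:
    """A calibrated molar Sr:Ca transect along the ablation path.

    ``positions`` are µm from ablation start, strictly increasing. ``ratios``
    are mmol Sr per mol Ca; flagged points (anything but ``ok``/``negative``)
    carry NaN and are excluded from every downstream statistic. ``quality``
    is the transect-quality code: F (full, edge–core–edge), H (half,
    edge–core), P (partial, past the core but short of the far edge) or O
    (failed to go through the core).
    """

    fish_id: str
    positions: np.ndarray
    ratios: np.ndarray
    flags: np.ndarray | None = None
    quality: str | None = None
    capture_context: str = "unknown"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.positions.shape != self.ratios.shape or self.positions.ndim != 1:
            raise ValueError("positions and ratios must be 1-d arrays of equal length")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.flags is None:
            self.flags = np.where(np.isnan(self.ratios), "missing", "ok").astype(object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.positions.shape:
                raise ValueError("flags length mismatch")
        unknown = set(self.flags) - set(POINT_FLAGS)
        if unknown:
            raise ValueError(f"unknown point flags: {sorted(unknown)}")
        if self.quality is not None and self.quality not in QUALITY_CODES:
            raise ValueError(f"quality must be one of {QUALITY_CODES}, got {self.quality!r}")
        if self.capture_context not in CAPTURE_CONTEXTS:
            raise ValueError(f"capture_context must be one of {CAPTURE_CONTEXTS}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def ok_mask(self) -> np.ndarray:
        return np.asarray(self.flags == "ok")

    @property
    def ok_positions(self) -> np.ndarray:
        return self.positions[self.ok_mask]

    @property
    def ok_ratios(self) -> np.ndarray:
        return self.ratios[self.ok_mask]

    @property
    def n_ok(self) -> int:
        return int(self.ok_mask.sum())

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0]) if len(self) else 0.0

    def validate(self) -> None:
        """Strict invariant check: ok points must carry finite, non-negative ratios."""
        ok = self.ok_ratios
        if np.isnan(ok).any():
            raise ValueError("ok-flagged point carries NaN ratio")
        if (ok < 0).any():
            raise ValueError("ok-flagged point carries a negative Sr:Ca ratio")

    def replace(self, **kwargs) -> "ElementProfile":
        data = dict(
            fish_id=self.fish_id, positions=self.positions, ratios=self.ratios,
            flags=self.flags, quality=self.quality, capture_context=self.capture_context,
        )
        data.update(kwargs)
        return ElementProfile(**data)


def write_profile(profile: ElementProfile, path: str | Path) -> None:
    """Serialize a profile to CSV with a ``#`` metadata header.

    Floats are written with ``repr`` (shortest round-trip form) so that
    ``read_profile(write_profile(p))`` reproduces positions and ratios
    bit-for-bit.
    """
    if len(profile) == 0:
        raise EmptyInputError("refusing to write an empty profile")
    buf = io.StringIO()
    buf.write(f"# fish_id: {profile.fish_id}\n")
    buf.write(f"# quality: {profile.quality if profile.quality is not None else ''}\n")
    buf.write(f"# capture_context: {profile.capture_context}\n")
    buf.write("position_um,sr_ca_mmol_mol,flag\n")
    for pos, ratio, flag in zip(profile.positions, profile.ratios, profile.flags):
        ratio_s = "" if np.isnan(ratio) else repr(float(ratio))
        buf.write(f"{float(pos)!r},{ratio_s},{flag}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_profile(path: str | Path) -> ElementProfile:
    """Read a profile CSV written by :func:`write_profile`."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise EmptyInputError(f"{path}: no data")
    table = pd.read_csv(io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    for col in ("position_um", "sr_ca_mmol_mol", "flag"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    quality = meta.get("quality") or None
    return ElementProfile(
        fish_id=meta.get("fish_id", path.stem),
        positions=table["position_um"].to_numpy(dtype=float),
        ratios=table["sr_ca_mmol_mol"].to_numpy(dtype=float),
        flags=table["flag"].astype(str).to_numpy(dtype=object),
        quality=quality,
        capture_context=meta.get("capture_context", "unknown"),
    )
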