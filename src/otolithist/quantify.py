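"""Raw counts → calibrated molar Sr:Ca transects.

The reduction chain mirrors standard LA-ICP-MS practice for otolith work:

1. average consecutive raw reads into data points (default 10 reads/point);
2. flag points below the blank-derived limit of detection, per isotope,
   on the *pre-correction* intensities;
3. subtract the pooled blank mean per isotope;
4. divide by natural isotopic abundance to get elemental intensities,
   form the raw Sr/Ca elemental ratio, and scale it by the bracketing
   reference-material measurements so the result is molar mmol Sr / mol Ca.

Standard brackets (a certified reference measured before and after each
block of otoliths) correct instrument drift: the calibration factor is
interpolated linearly between the pre- and post-block standards at the
run's position within its block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    CalibrationError,
    CoverageError,
    EmptyInputError,
    ParameterError,
    RoleError,
)
from .raw_io import ElementProfile, InstrumentConfig, RawRun

log = logging.getLogger(__name__)

__all__ = [
    "BlankStats",
    "StandardBracket",
    "block_average",
    "compute_blank_stats",
    "blank_correct",
    "lod_filter",
    "measure_standard",
    "bracket_from_runs",
    "to_molar_ratio",
    "quantify_block",
]


@dataclass
class BlankStats:
    """Pooled per-isotope blank statistics for one standard-bracketed block."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_blanks: int
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.n_blanks < 1:
            raise ValueError("n_blanks must be >= 1")
        for iso, s in self.sd.items():
            if s < 0:
                raise ValueError(f"sd of {iso} must be >= 0")

    def lod_threshold(self, isotope: str, multiplier: float, sign: int) -> float:
        return self.mean[isotope] + sign * multiplier * self.sd[isotope]


@dataclass
class StandardBracket:
    """Measured raw elemental Sr/Ca ratios of the reference material around one block.

    Either side of the bracket may be absent (``None``); at least one must be
    present. ``certified_mmol_mol`` is the certificate value in molar mmol/mol.
    """

    certified_mmol_mol: float
    pre: float | None = None
    post: float | None = None
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.pre is None and self.post is None:
            raise CalibrationError("standard bracket needs at least one of pre/post")
        for side, value in (("pre", self.pre), ("post", self.post)):
            if value is not None and value <= 0:
                raise CalibrationError(f"measured standard ratio ({side}) must be > 0, got {value}")
        if self.certified_mmol_mol <= 0:
            raise CalibrationError("certified ratio must be > 0")

    def factor_at(self, fraction: float) -> float:
        """Calibration factor (certified / measured) at a fractional position in the block."""
        pre = None if self.pre is None else self.certified_mmol_mol / self.pre
        post = None if self.post is None else self.certified_mmol_mol / self.post
        if pre is None:
            return post  # type: ignore[return-value]
        if post is None:
            return pre
        fraction = float(np.clip(fraction, 0.0, 1.0))
        return pre + fraction * (post - pre)


def block_average(run: RawRun, block_size: int) -> RawRun:
    """Average consecutive reads into data points.

    Each output point is the arithmetic mean of its block's non-missing
    reads; the block time is the mean of all block times. A trailing
    partial block is dropped. A block with no usable read becomes a
    flagged-missing point (NaN), never a silent drop.
    """
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    n_blocks = len(run) // block_size
    if n_blocks == 0:
        raise EmptyInputError(
            f"run {run.run_id!r} has {len(run)} reads, fewer than one block of {block_size}"
        )
    n_used = n_blocks * block_size
    times = run.times[:n_used].reshape(n_blocks, block_size).mean(axis=1)
    intensities = {}
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for iso, arr in run.intensities.items():
            blocks = arr[:n_used].reshape(n_blocks, block_size)
            # mean about a per-block baseline: exact for constant blocks,
            # and avoids large-magnitude accumulation in general
            finite = ~np.isnan(blocks)
            first = np.argmax(finite, axis=1)
            base = blocks[np.arange(n_blocks), first]
            base = np.where(finite.any(axis=1), base, np.nan)
            intensities[iso] = base + np.nanmean(blocks - base[:, None], axis=1)
    return run.replace(times=times, intensities=intensities, flags=None)


def compute_blank_stats(blanks: list[RawRun], block_id: int = 0) -> BlankStats:
    """Pool all reads of the bracket's blank runs into per-isotope mean and sample SD."""
    if not blanks:
        raise EmptyInputError("no blank runs supplied")
    for run in blanks:
        if run.role != "blank":
            raise RoleError(f"run {run.run_id!r} has role {run.role!r}, expected 'blank'")
    isotopes = blanks[0].isotopes
    for run in blanks[1:]:
        if set(run.isotopes) != set(isotopes):
            raise RoleError("blank runs disagree on the isotope set")
    mean, sd = {}, {}
    for iso in isotopes:
        reads = np.concatenate([run.intensities[iso] for run in blanks])
        reads = reads[~np.isnan(reads)]
        if reads.size == 0:
            raise EmptyInputError(f"no usable blank reads for isotope {iso}")
        mean[iso] = float(reads.mean())
        sd[iso] = float(reads.std(ddof=1)) if reads.size > 1 else 0.0
    return BlankStats(mean=mean, sd=sd, n_blanks=len(blanks), block_id=block_id)


def blank_correct(run: RawRun, stats: BlankStats) -> RawRun:
    """Subtract the per-isotope blank mean; values may legitimately go negative."""
    corrected = {}
    for iso, arr in run.intensities.items():
        if iso not in stats.mean:
            raise CoverageError(f"blank statistics do not cover isotope {iso}")
        corrected[iso] = arr - stats.mean[iso]
    # keep existing flags: post-correction negatives are expected near blank level
    return run.replace(intensities=corrected)


def lod_filter(
    run: RawRun,
    stats: BlankStats,
    multiplier: float = 3.0,
    sign: int = -1,
    isotopes: tuple[str, ...] | None = None,
) -> RawRun:
    """Flag points below the blank-derived limit of detection.

    The threshold for each isotope is ``blank_mean + sign·multiplier·blank_sd``
    evaluated on *pre-correction* intensities, so apply this before
    :func:`blank_correct`. A point failing on any checked isotope is flagged
    ``below_lod`` whole, because the ratio needs both isotopes. Increasing
    the multiplier (at the default sign) never flags more points.
    """
    if multiplier < 0:
        raise ParameterError("LOD multiplier must be >= 0 (direction is set by sign)")
    if sign not in (-1, 1):
        raise ParameterError("LOD sign must be -1 or +1")
    check = isotopes if isotopes is not None else run.isotopes
    flags = np.array(run.flags, dtype=object, copy=True)
    usable = run.usable_mask()
    for iso in check:
        if iso not in stats.mean:
            raise CoverageError(f"blank statistics do not cover isotope {iso}")
        threshold = stats.lod_threshold(iso, multiplier, sign)
        below = usable & (run.intensities[iso] < threshold)
        flags[below] = "below_lod"
    return run.replace(flags=flags)


def measure_standard(
    run: RawRun, config: InstrumentConfig, stats: BlankStats | None = None
) -> float:
    """Mean raw elemental Sr/Ca ratio of a standard run (optionally blank-corrected)."""
    if run.role != "standard":
        raise RoleError(f"run {run.run_id!r} has role {run.role!r}, expected 'standard'")
    if stats is not None:
        run = blank_correct(run, stats)
    usable = run.usable_mask()
    sr = run.intensities[config.sr_isotope][usable] / config.isotope_abundance[config.sr_isotope]
    ca = run.intensities[config.ca_isotope][usable] / config.isotope_abundance[config.ca_isotope]
    good = ca > 0
    if not good.any():
        raise CalibrationError(f"standard run {run.run_id!r} has no usable reads")
    measured = float(np.mean(sr[good] / ca[good]))
    if measured <= 0:
        raise CalibrationError(f"measured standard ratio must be > 0, got {measured}")
    return measured


def bracket_from_runs(
    config: InstrumentConfig,
    pre: RawRun | None = None,
    post: RawRun | None = None,
    stats: BlankStats | None = None,
    block_id: int = 0,
) -> StandardBracket:
    """Build a :class:`StandardBracket` from the bracketing standard runs."""
    return StandardBracket(
        certified_mmol_mol=config.certified_mmol_mol,
        pre=None if pre is None else measure_standard(pre, config, stats),
        post=None if post is None else measure_standard(post, config, stats),
        block_id=block_id,
    )


def to_molar_ratio(
    run: RawRun,
    bracket: StandardBracket,
    config: InstrumentConfig,
    block_fraction: float = 0.5,
) -> ElementProfile:
    """Convert a blank-corrected, LOD-flagged sample run into a molar Sr:Ca profile.

    Per point: elemental intensity = isotope intensity / natural abundance;
    raw ratio = elemental Sr / elemental Ca; calibrated molar ratio =
    raw ratio × (certified / measured standard ratio), the factor
    interpolated between the pre- and post-block standards at
    ``block_fraction`` (the run's order within its block, 0 = right after
    the pre-standard, 1 = right before the post-standard).

    Positions are ``time × scan_speed``. Points flagged missing or
    below-LOD carry NaN ratios and keep their flags.
    """
    if bracket is None:
        raise CalibrationError(f"no standard bracket for run {run.run_id!r}")
    factor = bracket.factor_at(block_fraction)
    sr = run.intensities[config.sr_isotope] / config.isotope_abundance[config.sr_isotope]
    ca = run.intensities[config.ca_isotope] / config.isotope_abundance[config.ca_isotope]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_ratio = np.where(ca != 0, sr / ca, np.nan)
    ratios = raw_ratio * factor

    flags = np.array(run.flags, dtype=object, copy=True)
    flags[np.isnan(ratios) & (flags == "ok")] = "missing"
    keep = np.isin(flags, ("ok", "negative"))
    out_flags = np.where(keep, "ok", flags).astype(object)
    ratios = np.where(keep, ratios, np.nan)
    return ElementProfile(
        fish_id=run.fish_id or run.run_id,
        positions=run.times * config.scan_speed,
        ratios=ratios,
        flags=out_flags,
    )


def quantify_block(
    samples: list[RawRun],
    blanks: list[RawRun],
    config: InstrumentConfig,
    pre_standard: RawRun | None = None,
    post_standard: RawRun | None = None,
    block_id: int = 0,
) -> list[ElementProfile]:
    """Full reduction of one standard-bracketed block of sample runs.

    Order of operations: block-average each sample, flag LOD on the averaged
    pre-correction intensities, subtract the blank means, then calibrate
    against the bracket. The fractional position of sample *i* of *k* within
    the block is ``(i + 1) / (k + 1)``.
    """
    stats = compute_blank_stats(blanks, block_id=block_id)
    bracket = bracket_from_runs(
        config, pre=pre_standard, post=post_standard, stats=stats, block_id=block_id
    )
    log.info(
        "block %d: calibration factor pre=%s post=%s; LOD thresholds %s",
        block_id,
        None if bracket.pre is None else f"{bracket.certified_mmol_mol / bracket.pre:.6g}",
        None if bracket.post is None else f"{bracket.certified_mmol_mol / bracket.post:.6g}",
        {
            iso: round(stats.lod_threshold(iso, config.lod_sd_multiplier, config.lod_sign), 4)
            for iso in (config.sr_isotope, config.ca_isotope)
        },
    )
    profiles = []
    k = len(samples)
    for i, run in enumerate(samples):
        averaged = block_average(run, config.block_size)
        flagged = lod_filter(
            averaged, stats, config.lod_sd_multiplier, config.lod_sign,
            isotopes=(config.sr_isotope, config.ca_isotope),
        )
        corrected = blank_correct(flagged, stats)
        profiles.append(
            to_molar_ratio(corrected, bracket, config, block_fraction=(i + 1) / (k + 1))
        )
    return profiles
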