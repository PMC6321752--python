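"""Transect cleaning and quality assessment.

Two concerns live here. First, removal of additive outliers — isolated
single-point excursions caused by recording errors, distinct from genuine
habitat shifts, which are steps that persist. Detection is a running-median
filter: a point is an outlier when its deviation from the windowed median
exceeds ``k`` robust standard deviations (global MAD of the residuals,
scaled by 1.4826). A step passes through a centred median window untouched,
so real transitions survive while single-point spikes do not.

Second, transect-quality coding. The ideal ablation path crosses the whole
otolith through the primordium (core), yielding an edge–core–edge "double
transect" with the life-history signal mirrored on either side of the core.
Imperfect paths are coded: F full, H half (edge–core), P partial (past the
core, short of the far edge), O off-core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, PreconditionError
from .raw_io import ElementProfile

__all__ = [
    "OutlierReport",
    "remove_additive_outliers",
    "assess_transect_quality",
    "mirror_halves",
    "orient_core_first",
    "suggest_core_position",
]

MAD_SCALE = 1.4826  # makes the MAD a consistent estimator of a Gaussian SD


@dataclass
class OutlierReport:
    """Record of an additive-outlier pass: who was removed and why."""

    removed_indices: np.ndarray
    scores: np.ndarray  # |residual| per ok point, aligned with ok_indices
    ok_indices: np.ndarray
    threshold: float
    k: float
    window: int
    warning: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def remove_additive_outliers(
    profile: ElementProfile,
    k: float = 5.0,
    window: int = 7,
    max_fraction: float = 0.05,
) -> tuple[ElementProfile, OutlierReport]:
    """Flag isolated spikes as ``outlier_removed``; retained values are untouched.

    A point (among ok-flagged points) is an additive outlier when
    ``|value − running_median(window)| > k × 1.4826 × MAD(residuals)``.
    Removing more than ``max_fraction`` of points raises a warning recorded
    on the report (and via :mod:`warnings`), since mass removal suggests the
    detector is eating signal.
    """
    if k <= 0:
        raise ParameterError("k must be > 0")
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be a positive odd count")
    ok_idx = np.flatnonzero(profile.ok_mask)
    values = profile.ratios[ok_idx]
    if len(values) < window:
        raise ParameterError(
            f"profile has {len(values)} ok points, fewer than the window of {window}"
        )
    residuals = values - _running_median(values, window)
    mad = float(np.median(np.abs(residuals - np.median(residuals))))
    threshold = k * MAD_SCALE * mad
    scores = np.abs(residuals)
    outlier = scores > threshold
    removed = ok_idx[outlier]

    warning = None
    frac = removed.size / len(values)
    if removed.size and frac > max_fraction:
        warning = (
            f"additive-outlier pass removed {removed.size}/{len(values)} points "
            f"({100 * frac:.1f}% > {100 * max_fraction:.0f}%)"
        )
        warnings.warn(warning, stacklevel=2)

    flags = np.array(profile.flags, dtype=object, copy=True)
    flags[removed] = "outlier_removed"
    ratios = np.array(profile.ratios, copy=True)
    ratios[removed] = np.nan
    cleaned = profile.replace(ratios=ratios, flags=flags)
    report = OutlierReport(
        removed_indices=removed,
        scores=scores,
        ok_indices=ok_idx,
        threshold=threshold,
        k=k,
        window=window,
        warning=warning,
        params={"max_fraction": max_fraction},
    )
    return cleaned, report


def assess_transect_quality(
    profile: ElementProfile,
    core_position: float | None,
    end_tolerance: float | None = None,
) -> str:
    """Assign the transect-quality code F/H/P/O and store it on the profile.

    F: the declared core lies in the central tercile of the covered span
    (both flanks covered). H: the transect ends at the core (within one
    median point spacing unless ``end_tolerance`` overrides). P: coverage
    extends past the core without reaching the far edge. O: no core
    declared, or the core lies outside the covered span.
    """
    if len(profile) == 0:
        raise PreconditionError("cannot assess an empty profile")
    if core_position is None:
        code = "O"
    else:
        p0, p1 = float(profile.positions[0]), float(profile.positions[-1])
        if end_tolerance is None:
            spacing = np.median(np.diff(profile.positions)) if len(profile) > 1 else 0.0
            end_tolerance = float(spacing)
        if core_position < p0 - end_tolerance or core_position > p1 + end_tolerance:
            code = "O"
        elif abs(core_position - p1) <= end_tolerance:
            code = "H"
        else:
            rel = (core_position - p0) / (p1 - p0) if p1 > p0 else 0.0
            code = "F" if (1 / 3) <= rel <= (2 / 3) else "P"
    profile.quality = code
    return code


def _half(profile: ElementProfile, idx: np.ndarray, reverse: bool) -> ElementProfile:
    pos = profile.positions[idx]
    core = pos[-1] if reverse else pos[0]
    rel = np.abs(pos - core)
    ratios = profile.ratios[idx]
    flags = profile.flags[idx]
    if reverse:
        rel, ratios, flags = rel[::-1], ratios[::-1], flags[::-1]
    return ElementProfile(
        fish_id=profile.fish_id,
        positions=rel,
        ratios=ratios,
        flags=flags,
        quality="H",
        capture_context=profile.capture_context,
    )


def mirror_halves(
    profile: ElementProfile, core_position: float
) -> tuple[ElementProfile, ElementProfile, float]:
    """Split a full transect at the core into two core→edge halves.

    Returns both halves (positions re-based to µm from the core) and a
    consistency score in [0, 1]: the Spearman rank correlation between the
    two halves after resampling onto a common relative-position grid,
    clipped at zero. A full edge–core–edge transect records the life
    history twice, so well-behaved data score near 1.
    """
    if profile.quality != "F":
        raise PreconditionError(
            f"mirror_halves needs a full (F) transect, got quality {profile.quality!r}"
        )
    left_idx = np.flatnonzero(profile.positions <= core_position)
    right_idx = np.flatnonzero(profile.positions >= core_position)
    if len(left_idx) < 2 or len(right_idx) < 2:
        raise PreconditionError("core position leaves fewer than 2 points on one side")
    left = _half(profile, left_idx, reverse=True)
    right = _half(profile, right_idx, reverse=False)
    consistency = _half_consistency(left, right)
    return left, right, consistency


def _half_consistency(left: ElementProfile, right: ElementProfile) -> float:
    lpos, lval = left.ok_positions, left.ok_ratios
    rpos, rval = right.ok_positions, right.ok_ratios
    if len(lval) < 2 or len(rval) < 2:
        return 0.0
    n = min(len(lval), len(rval))
    grid = np.linspace(0.0, 1.0, n)
    lg = np.interp(grid, lpos / lpos[-1] if lpos[-1] > 0 else lpos, lval)
    rg = np.interp(grid, rpos / rpos[-1] if rpos[-1] > 0 else rpos, rval)
    if np.ptp(lg) == 0 and np.ptp(rg) == 0:
        # both halves flat: consistent iff at the same level
        scale = max(abs(lg[0]), abs(rg[0]), 1e-12)
        return 1.0 if abs(lg[0] - rg[0]) / scale < 1e-6 else 0.0
    if np.ptp(lg) == 0 or np.ptp(rg) == 0:
        return 0.0
    rho = sps.spearmanr(lg, rg).statistic
    if np.isnan(rho):
        return 0.0
    return float(np.clip(rho, 0.0, 1.0))


def suggest_core_position(
    profile: ElementProfile, search_band: tuple[float, float] = (0.25, 0.75)
) -> float | None:
    """Optional helper: propose a core position by maximal local mirror symmetry.

    Scans candidate positions in the central ``search_band`` of the span and
    scores each by the mean squared difference between the two flanks after
    mirroring (lower is better). This is a convenience for eyeballing
    un-annotated full transects; it is never applied automatically — the
    pipeline takes the core position from operator annotation.
    """
    pos, val = profile.ok_positions, profile.ok_ratios
    n = len(val)
    if n < 9:
        return None
    lo, hi = int(search_band[0] * n), int(search_band[1] * n)
    best_i, best_score = None, np.inf
    for i in range(max(lo, 4), min(hi, n - 4)):
        m = min(i, n - 1 - i)
        left = val[i - m:i][::-1]
        right = val[i + 1:i + 1 + m]
        score = float(np.mean((left - right) ** 2))
        if score < best_score:
            best_i, best_score = i, score
    return None if best_i is None else float(pos[best_i])


def orient_core_first(profile: ElementProfile, core_position: float | None) -> ElementProfile:
    """Return a chronological (core→edge) view of a transect for classification.

    Full transects are split at the core and the longer half is used; half
    transects (edge–core) are reversed; anything else is returned as-is on
    the assumption that positions already run from core to edge.
    """
    if core_position is None or profile.quality in (None, "O"):
        return profile
    if profile.quality == "F":
        left, right, _ = mirror_halves(profile, core_position)
        return left if left.n_ok >= right.n_ok else right
    if profile.quality == "H":
        return _half(profile, np.arange(len(profile)), reverse=True)
    return profile
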