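"""Ground-truthed synthetic otolith data at two levels.

Level 1 — calibrated profiles: piecewise-constant Sr:Ca signals following
the idealized life-history templates (freshwater resident: low throughout;
brackish resident: intermediate throughout; anadromous: low→high→low;
catadromous: high→low, optionally rising again; amphidromous:
intermediate→high→low), plus an optional maternal core spike, independent
Gaussian noise, and sporadic additive outliers. The truth object records
the exact breakpoint positions and the generating category.

Level 2 — raw instrument datasets: the quantification model run backwards.
Elemental intensities are chosen so that their calibrated ratio equals the
(noisy) template, multiplied by isotopic abundances, offset by a blank
background; bracketing standard and blank runs consistent with a known
calibration factor (with optional linear drift) are emitted alongside.
Running the quantification chain on such a dataset recovers the template —
exactly when all noise terms are zero.

Default band levels (0.7, 2.0, 4.0 mmol/mol) bracket the dynamic range
observed across real freshwater-to-marine species contrasts, so synthetic
profiles occupy a realistic scale. Every draw is reproducible from the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .raw_io import ElementProfile, InstrumentConfig, RawRun

__all__ = [
    "SyntheticSpec",
    "ProfileTruth",
    "RawDataset",
    "generate_profile",
    "generate_raw_dataset",
    "STRATEGIES",
    "DEFAULT_BAND_LEVELS",
    "SYNTHETIC_CERTIFIED_RATIO",
]

STRATEGIES = ("FW", "B", "ANA", "CAT", "AMPH")
DEFAULT_BAND_LEVELS = (0.7, 2.0, 4.0)

#: Synthetic stand-in for a reference-material certificate value (mmol/mol).
#: Not a real certificate; fixtures only.
SYNTHETIC_CERTIFIED_RATIO = 2.0

#: Default habitat-shift positions (fractions of the transect) per strategy.
DEFAULT_BREAKPOINTS = {
    "FW": (),
    "B": (),
    "ANA": (0.3, 0.7),
    "CAT": (0.4,),
    "AMPH": (0.25, 0.75),
}

#: Capture context each template implies (where such a fish would be caught).
CAPTURE_FOR_STRATEGY = {
    "FW": "freshwater",
    "B": "estuary",
    "ANA": "freshwater",
    "CAT": "estuary",
    "AMPH": "freshwater",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic transect.

    ``band_levels`` are the (low, intermediate, high) Sr:Ca plateaus in
    mmol/mol; ``breakpoint_fractions`` the habitat-shift positions as
    fractions of the transect (defaults depend on the strategy);
    ``maternal_spike`` an optional ``(level, core_fraction)`` pair raising
    the first ``core_fraction`` of the transect to ``level``;
    ``outlier_rate`` the per-point probability of an additive recording
    error with magnitude 3–10 × ``noise_sd``. ``spacing_um`` is the µm per
    data point — 5 µm at the reference acquisition geometry (10 reads at
    10 Hz per point, 5 µm/s scan).
    """

    strategy: str
    n_points: int = 500
    band_levels: tuple[float, float, float] = DEFAULT_BAND_LEVELS
    breakpoint_fractions: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    maternal_spike: tuple[float, float] | None = None
    outlier_rate: float = 0.0
    seed: int = 0
    spacing_um: float = 5.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")
        low, mid, high = self.band_levels
        if not (0 <= low < mid < high):
            raise ParameterError("band_levels must be ordered 0 <= low < intermediate < high")
        fracs = self.fractions
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ParameterError("breakpoint fractions must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ParameterError("breakpoint fractions must be strictly increasing")
        n_levels = len(self._levels())
        if len(fracs) != n_levels - 1:
            raise ParameterError(
                f"strategy {self.strategy} needs {n_levels - 1} breakpoints, got {len(fracs)}"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ParameterError("outlier_rate must be in [0, 1)")
        if self.maternal_spike is not None:
            level, frac = self.maternal_spike
            if level <= 0 or not (0.0 < frac < 1.0):
                raise ParameterError("maternal_spike must be (level > 0, fraction in (0, 1))")

    @property
    def fractions(self) -> tuple[float, ...]:
        if self.breakpoint_fractions is not None:
            return self.breakpoint_fractions
        return DEFAULT_BREAKPOINTS[self.strategy]

    def _levels(self) -> tuple[float, ...]:
        low, mid, high = self.band_levels
        if self.strategy == "FW":
            return (low,)
        if self.strategy == "B":
            return (mid,)
        if self.strategy == "ANA":
            return (low, high, low)
        if self.strategy == "AMPH":
            return (mid, high, low)
        # CAT: high→low, with an optional return seaward when 2 fractions given
        n_breaks = len(
            self.breakpoint_fractions if self.breakpoint_fractions is not None
            else DEFAULT_BREAKPOINTS["CAT"]
        )
        return (high, low, high)[: n_breaks + 1]


@dataclass
class ProfileTruth:
    """What the generator actually put into a profile."""

    category: str
    breakpoints_um: np.ndarray
    break_indices: np.ndarray
    signal: np.ndarray          # noise-free piecewise-constant ratio
    outlier_indices: np.ndarray
    capture_context: str
    spec: SyntheticSpec


def _template_signal(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free signal and the indices where it jumps (first index of new level)."""
    levels = spec._levels()
    cuts = [int(round(f * spec.n_points)) for f in spec.fractions]
    signal = np.empty(spec.n_points)
    bounds = [0, *cuts, spec.n_points]
    for level, lo, hi in zip(levels, bounds, bounds[1:]):
        signal[lo:hi] = level
    if spec.maternal_spike is not None:
        level, frac = spec.maternal_spike
        k = max(1, int(round(frac * spec.n_points)))
        signal[:k] = level
    # truth = every discontinuity of the noise-free signal (incl. spike edge)
    jumps = np.flatnonzero(np.diff(signal) != 0) + 1
    return signal, jumps


def generate_profile(spec: SyntheticSpec) -> tuple[ElementProfile, ProfileTruth]:
    """Draw one calibrated synthetic transect plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    signal, jumps = _template_signal(spec)
    positions = np.arange(spec.n_points) * spec.spacing_um

    ratios = signal + rng.normal(0.0, spec.noise_sd, spec.n_points)
    outlier_idx = np.array([], dtype=int)
    if spec.outlier_rate > 0 and spec.noise_sd > 0:
        hit = rng.random(spec.n_points) < spec.outlier_rate
        outlier_idx = np.flatnonzero(hit)
        magnitude = rng.uniform(3.0, 10.0, outlier_idx.size) * spec.noise_sd
        sign = rng.choice([-1.0, 1.0], outlier_idx.size)
        ratios[outlier_idx] += sign * magnitude
    ratios = np.clip(ratios, 0.0, None)

    capture = CAPTURE_FOR_STRATEGY[spec.strategy]
    profile = ElementProfile(
        fish_id=f"sim-{spec.strategy}-{spec.seed}",
        positions=positions,
        ratios=ratios,
        quality="H",  # core→edge chronological by construction
        capture_context=capture,
    )
    truth = ProfileTruth(
        category=spec.strategy,
        breakpoints_um=(jumps - 0.5) * spec.spacing_um,
        break_indices=jumps,
        signal=signal,
        outlier_indices=outlier_idx,
        capture_context=capture,
        spec=spec,
    )
    return profile, truth


@dataclass
class RawDataset:
    """One synthetic standard-bracketed block: a sample with its blanks and standards."""

    samples: list[RawRun]
    blanks: list[RawRun]
    pre_standard: RawRun
    post_standard: RawRun
    truth: ProfileTruth
    config: InstrumentConfig


def default_instrument_config(**overrides) -> InstrumentConfig:
    """Instrument config used by the generator (synthetic certificate value)."""
    defaults = dict(standard_certified_ratio=SYNTHETIC_CERTIFIED_RATIO)
    defaults.update(overrides)
    return InstrumentConfig(**defaults)


def generate_raw_dataset(
    spec: SyntheticSpec,
    instrument: InstrumentConfig | None = None,
    blank_level: float = 100.0,
    blank_sd: float = 0.0,
    drift: float = 0.0,
    ca_elemental: float = 1.0e6,
    sensitivity_ratio: float = 1.2e-3,
    n_blank_reads: int = 200,
    n_standard_reads: int = 100,
    count_noise_cv: float = 0.0,
) -> RawDataset:
    """Invert the quantification model into a raw instrument dataset.

    The sample's true ratio series is the (noisy) template profile; per-read
    isotope counts are built as ``elemental × abundance + blank background``
    with the sensitivity ratio ``g`` drifting linearly by ``drift`` across
    the block (standards at block fractions 0 and 1, the sample at 0.5).
    ``count_noise_cv`` adds proportional Gaussian read noise on top.
    Quantifying the result with :func:`otolithist.quantify.quantify_block`
    reproduces the template ratios — exactly when ``noise_sd``, ``blank_sd``,
    ``drift`` and ``count_noise_cv`` are all zero.
    """
    if instrument is None:
        instrument = default_instrument_config()
    profile, truth = generate_profile(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 987654321]))

    ab_sr = instrument.isotope_abundance[instrument.sr_isotope]
    ab_ca = instrument.isotope_abundance[instrument.ca_isotope]
    certified = instrument.certified_mmol_mol
    bs = instrument.block_size
    read_dt = 1.0 / (bs * instrument.scan_speed / spec.spacing_um)  # s per read

    def counts(ratio_series: np.ndarray, g: float | np.ndarray, noisy: bool) -> dict[str, np.ndarray]:
        el_ca = np.full_like(ratio_series, ca_elemental, dtype=float)
        el_sr = el_ca * ratio_series * g
        out = {
            instrument.sr_isotope: el_sr * ab_sr + blank_level,
            instrument.ca_isotope: el_ca * ab_ca + blank_level,
        }
        if noisy and count_noise_cv > 0:
            for iso in out:
                out[iso] = out[iso] * (1 + rng.normal(0.0, count_noise_cv, out[iso].shape))
        return out

    # sample: each data point expanded into block_size identical-ratio reads
    ratio_reads = np.repeat(profile.ratios, bs)
    g_sample = sensitivity_ratio * (1.0 + drift * 0.5)
    sample_times = (np.arange(ratio_reads.size) + 0.5) * read_dt
    # align block-average times with the template positions
    sample_times = sample_times - sample_times[:bs].mean() + profile.positions[0] / instrument.scan_speed
    sample = RawRun(
        run_id=f"sim-sample-{spec.strategy}-{spec.seed}",
        role="sample",
        fish_id=profile.fish_id,
        times=sample_times,
        intensities=counts(ratio_reads, g_sample, noisy=True),
    )

    blank_times = np.arange(n_blank_reads) * read_dt
    blank_reads = {
        iso: blank_level + rng.normal(0.0, blank_sd, n_blank_reads)
        for iso in (instrument.sr_isotope, instrument.ca_isotope)
    }
    blank = RawRun(
        run_id=f"sim-blank-{spec.seed}", role="blank",
        times=blank_times, intensities=blank_reads,
    )

    std_times = np.arange(n_standard_reads) * read_dt
    standards = []
    for side, frac in (("pre", 0.0), ("post", 1.0)):
        g = sensitivity_ratio * (1.0 + drift * frac)
        standards.append(
            RawRun(
                run_id=f"sim-standard-{side}-{spec.seed}", role="standard",
                times=std_times,
                intensities=counts(np.full(n_standard_reads, certified), g, noisy=False),
            )
        )

    return RawDataset(
        samples=[sample], blanks=[blank],
        pre_standard=standards[0], post_standard=standards[1],
        truth=truth, config=instrument,
    )


def template_suite(
    noise_sd: float = 0.0, seed: int = 0, n_points: int = 500, **overrides
) -> dict[str, tuple[ElementProfile, ProfileTruth]]:
    """One profile per strategy, sharing noise level and seed stream."""
    suite = {}
    for i, strategy in enumerate(STRATEGIES):
        spec = SyntheticSpec(
            strategy=strategy, n_points=n_points, noise_sd=noise_sd,
            seed=seed * 1000 + i, **overrides,
        )
        suite[strategy] = generate_profile(spec)
    return suite
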