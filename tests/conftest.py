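import numpy as np
import pytest

from otolithist import ElementProfile, InstrumentConfig, RawRun


@pytest.fixture
def config() -> InstrumentConfig:
    # synthetic certificate value; real work must supply the actual certificate
    return InstrumentConfig(standard_certified_ratio=2.0)


@pytest.fixture
def make_profile():
    """Build an ElementProfile from a value array with unit spacing."""

    def _make(values, fish_id="fish", **kwargs) -> ElementProfile:
        values = np.asarray(values, dtype=float)
        return ElementProfile(
            fish_id=fish_id,
            positions=np.arange(len(values), dtype=float),
            ratios=values,
            **kwargs,
        )

    return _make


@pytest.fixture
def make_run():
    """Build a RawRun from per-isotope value arrays with unit time spacing."""

    def _make(role="sample", fish_id="fish", **streams) -> RawRun:
        n = len(next(iter(streams.values())))
        return RawRun(
            run_id="run",
            role=role,
            fish_id=fish_id if role == "sample" else None,
            times=np.arange(n, dtype=float),
            intensities={k: np.asarray(v, dtype=float) for k, v in streams.items()},
        )

    return _make


def step_values(levels, lengths) -> np.ndarray:
    """Piecewise-constant array: each level repeated for its length."""
    return np.concatenate([np.full(n, lv, dtype=float) for lv, n in zip(levels, lengths)])
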