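"""Shared fixtures: analyzed reference traces and phantoms are expensive, so
they are built once per session at zero noise and reused."""

from __future__ import annotations

import numpy as np
import pytest

from ligcect.mechanics import analyze_test
from ligcect.synthetic import (
    CTGroundTruth,
    MechGroundTruth,
    Protocol,
    gen_ct_phantom,
    gen_tensile_test,
)

PHANTOM_SHAPE = (12, 128, 128)


@pytest.fixture(scope="session")
def reference_truth() -> MechGroundTruth:
    return MechGroundTruth()


@pytest.fixture(scope="session")
def damaged_trace_clean(reference_truth):
    """Zero-noise damaged-protocol trace at the healthy reference truth."""
    return gen_tensile_test(
        reference_truth, Protocol(damaged=True), noise_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def damaged_analysis_clean(damaged_trace_clean):
    test, _ = damaged_trace_clean
    return analyze_test(test)


@pytest.fixture(scope="session")
def control_trace_small():
    """A short control trace (reduced protocol) for I/O round-trip tests."""
    proto = Protocol(
        precondition_blocks=1, precondition_cycles=2, hold_s=30.0,
        sinusoid_cycles=5, frequencies=(0.5, 2.0),
    )
    test, truth = gen_tensile_test(MechGroundTruth(), proto, noise_sd=0.01, seed=7)
    return test, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Nanoparticle phantom series at the reference regional attenuations."""
    truth = CTGroundTruth()  # 603/795 HU, noise 22 HU
    return gen_ct_phantom(shape=PHANTOM_SHAPE, truth=truth, seed=11)


@pytest.fixture(scope="session")
def clean_phantom():
    truth = CTGroundTruth(noise_sd_HU=0.0)
    return gen_ct_phantom(shape=PHANTOM_SHAPE, truth=truth, seed=11)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0
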