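import numpy as np
import pandas as pd
import pytest

from sdtms.membrane import WaveformSpec, generate_waveform, waveform_family
from sdtms.synthetic import DrugEffect, SimulationConfig


@pytest.fixture(scope="session")
def rect_family():
    """Rectangular pulses at the three study widths (closed-form oracle exists)."""
    return waveform_family([30, 60, 120], shape="rectangular", dt_us=0.5)


@pytest.fixture(scope="session")
def ctms_family():
    """Default pseudorectangular cTMS pulses at the three study widths."""
    return waveform_family([30, 60, 120], shape="ctms_pseudorect")


@pytest.fixture(scope="session")
def rect_wf60():
    return generate_waveform(WaveformSpec(shape="rectangular", tp_us=60.0, dt_us=1.0))


@pytest.fixture
def null_effects():
    """Drug-effect map with every condition at identity (no true effect)."""
    return {c: DrugEffect() for c in ("placebo", "carbamazepine", "lacosamide")}


@pytest.fixture
def small_config():
    """Reduced cohort for fast end-to-end tests."""
    return SimulationConfig(n_subjects=6, seed=7)


def make_trials(
    subject_id="S01",
    condition="placebo",
    pulse_width_us=60,
    intensities=(40, 45, 50, 55, 60),
    mep=1.0,
    noise=0.01,
    n=10,
):
    """Hand-built trial table in the mandated schema."""
    rows = []
    mep = np.broadcast_to(np.asarray(mep, dtype=float), (len(intensities), n))
    for i, x in enumerate(intensities):
        for j in range(n):
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "pulse_width_us": pulse_width_us,
                    "intensity_pct_mso": float(x),
                    "nominal_level_pct_rmt": np.nan,
                    "mep_pp_mv": float(mep[i, j]),
                    "noise_pp_mv": float(noise),
                }
            )
    return pd.DataFrame(rows)
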