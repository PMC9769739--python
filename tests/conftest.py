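import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cellcomp import ElementalComposition

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def electrode_composition() -> ElementalComposition:
    """Electrode-grown G. sulfurreducens elemental analysis (% dry weight)."""
    return ElementalComposition(pctC=47.0, pctH=7.2, pctN=9.5, pctAsh=9.9)


@pytest.fixture
def fumarate_composition() -> ElementalComposition:
    """Fumarate-grown G. sulfurreducens elemental analysis (% dry weight).

    The reported O (28.6) differs from O-by-difference (28.5) by a
    rounding residual; the reported value takes precedence.
    """
    return ElementalComposition(pctC=46.8, pctH=7.4, pctN=8.3, pctAsh=9.0, pctO=28.6)


@pytest.fixture
def write_csv(tmp_path):
    """Write rows (list of tuples) to a temp CSV with the sample-table header."""

    def _write(rows, columns=("condition", "replicate", "analyte", "value", "units"), name="samples.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return _write
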