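import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oxphoskit.ck_clamp import ClampComposition, ThermoParameterSet


@pytest.fixture
def methods_composition() -> ClampComposition:
    """The standard clamp assay mixture (mM): ATP 5, Cr 5, Pi 10, Mg 5."""
    return ClampComposition.from_millimolar(
        atp_total=5.0, pcr=1.0, cr=5.0, pi_total=10.0, mg_total=5.0,
        ph=7.2, temperature=310.15,
    )


@pytest.fixture
def identity_params() -> ThermoParameterSet:
    """Parameter set whose reference conditions match the test compositions."""
    return ThermoParameterSet(
        k_ck_ref=100.0, ref_ph=7.2, ref_mg_free=1e-3, ref_temperature=310.15
    )
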