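import numpy as np
import pytest

from gatekit import DoseResponseCurve, DoseResponsePoint, HillParams, hill_response
from gatekit.synthetic import SimulationScenario


@pytest.fixture
def hill_curve():
    """Noiseless Hill curve from (ec50 = 0.3 µM, h = 2.5)."""
    params = HillParams(0.3, 2.5)
    ca = np.geomspace(0.02, 20.0, 13)
    points = [DoseResponsePoint(c, float(hill_response(c, params))) for c in ca]
    return DoseResponseCurve("synthetic", points), params


@pytest.fixture
def scenario():
    return SimulationScenario(seed=42)


@pytest.fixture
def dose_csv(tmp_path):
    path = tmp_path / "curves.csv"
    path.write_text(
        "mutant_id,ca_uM,response,sem,n_patches\n"
        "WT,0.1,0.02,0.01,5\n"
        "WT,1.0,0.30,0.02,5\n"
        "WT,3.0,0.70,0.02,5\n"
        "WT,10.0,0.95,0.01,5\n"
        "I551A,0.01,0.40,0.03,6\n"
        "I551A,0.1,0.75,0.02,6\n"
        "I551A,1.0,0.97,0.01,6\n"
        "I551A,0.03,0.55,0.02,6\n"
    )
    return path
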