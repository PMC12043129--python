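import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qgcmix as qm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with a clearly negative joint effect, for unit tests."""
    truth = qm.MixtureTruth.from_psi_weights(
        beta0=float(np.log(0.35 / 0.65)), psi=-0.4, link="logit"
    )
    return qm.generate_cohort(1500, truths={"imp_language": truth}, seed=42)


@pytest.fixture(scope="session")
def norms():
    return qm.synthetic_norms(qm.default_item_banks())
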