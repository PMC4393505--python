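import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cimidx.phantom import Lesion, PhantomSpec, PlantedRule, TransactionCohortSpec


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * float((a & b).sum()) / max(float(a.sum() + b.sum()), 1.0)


@pytest.fixture
def clean_spec() -> PhantomSpec:
    """Noise- and bias-free phantom with one circumscribed lesion."""
    return PhantomSpec(
        width=192, height=192, breast_profile=(170.0, 110.0),
        pectoral_angle=30.0,
        lesions=(Lesion(center=(110, 55), radius=15.0, contrast=50.0,
                        margin="circumscribed"),),
        bias_amplitude=0.0, noise_sigma=0.0, seed=7,
    )


@pytest.fixture
def noisy_spec(clean_spec) -> PhantomSpec:
    from dataclasses import replace
    return replace(clean_spec, noise_sigma=4.0, bias_amplitude=6.0)


#: four disjoint planted rules over a 12-item universe with vocabulary heads
PLANTED = (
    PlantedRule(body=frozenset({0, 1, 2}), head=frozenset({"Circum", "Benign"})),
    PlantedRule(body=frozenset({3, 4, 5}), head=frozenset({"Spicul", "Malignant"})),
    PlantedRule(body=frozenset({6, 7, 8}), head=frozenset({"Indist", "Malignant"})),
    PlantedRule(body=frozenset({9, 10, 11}), head=frozenset({"Normal"})),
)

KEYWORDS = frozenset({"Circum", "Benign", "Spicul", "Indist", "Malignant", "Normal"})


def cohort_spec(n: int, noise_rate: float, seed: int) -> TransactionCohortSpec:
    return TransactionCohortSpec(
        n_transactions=n, item_universe=12, keyword_universe=KEYWORDS,
        planted_rules=PLANTED, noise_rate=noise_rate, seed=seed,
    )
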