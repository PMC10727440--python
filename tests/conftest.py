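import numpy as np
import pytest

from kanopr import respondents_to_frame, simulate_cohort
from kanopr.kano import CATEGORY_PREIMAGE, KanoCategory
from kanopr.reference import REFERENCE_TALLIES


@pytest.fixture(scope="session")
def table3_counts():
    """Published per-attribute tallies of the reference cohort (N=237)."""
    return dict(REFERENCE_TALLIES)


@pytest.fixture(scope="session")
def reference_pairs(table3_counts):
    """Per-attribute response-pair lists exactly realizing the published tallies.

    Each category's count is expanded into concrete (functional,
    dysfunctional) answers drawn round-robin from the category's preimage in
    the evaluation grid, then shuffled deterministically.
    """
    rng = np.random.default_rng(20201030)
    pairs_by_attr = {}
    for aid, counts in table3_counts.items():
        pairs = []
        for cat in KanoCategory:
            preimage = CATEGORY_PREIMAGE[cat]
            for k in range(counts[cat]):
                f, d = preimage[k % len(preimage)]
                pairs.append((f.value, d.value))
        rng.shuffle(pairs)
        pairs_by_attr[aid] = pairs
    return pairs_by_attr


@pytest.fixture(scope="session")
def reference_frame(reference_pairs):
    """Wide survey DataFrame whose tallies equal the published ones."""
    import pandas as pd

    n = len(next(iter(reference_pairs.values())))
    data = {}
    for aid, pairs in reference_pairs.items():
        data[f"F{aid:02d}"] = [f for f, _ in pairs]
        data[f"D{aid:02d}"] = [d for _, d in pairs]
    return pd.DataFrame(data, index=range(n))


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (N=237, calibrated to the published tallies)."""
    return simulate_cohort(n_respondents=237, seed=42)


@pytest.fixture(scope="session")
def cohort_frame(cohort):
    return respondents_to_frame(cohort)
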