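import numpy as np
import pytest

from ledgerfed import cohort as ch
from ledgerfed import preprocess as prep


@pytest.fixture(scope="session")
def tiny_variables():
    """Three fast variables with distinct dynamics for unit tests."""
    return [
        ch.VariableSpec("hr", 85.0, 14.0, 12.0, 0.9, 0.8),
        ch.VariableSpec("sbp", 120.0, 18.0, -15.0, 0.6, 0.8),
        ch.VariableSpec("lact", 1.8, 1.0, 1.2, 0.2, 0.7),
    ]


@pytest.fixture(scope="session")
def small_cohort(tiny_variables):
    """Single-site 80-patient cohort shared across unit tests."""
    site = ch.single_site(80, n_variables=3)
    return ch.generate_cohort(tiny_variables, [site], seed=5)


@pytest.fixture(scope="session")
def small_episodes(small_cohort):
    """Gridded + split + transformed episodes of the small cohort."""
    eligible, _ = prep.filter_eligible(small_cohort)
    split = prep.split_cohort(eligible.patient_ids(), seed=5)
    vids = sorted(eligible.measurements["variable_id"].unique())
    gridded = prep.hourly_aggregate(eligible, vids)
    by_id = {e.patient_id: e for e in gridded}
    train = [by_id[p] for p in sorted(split.patients("train"))]
    state = prep.fit_preprocessor(train, vids)
    tensors = prep.transform(state, gridded)
    return dict(split=split, vids=vids, gridded=gridded, state=state,
                tensors=tensors, by_id=by_id)


def median_auroc(reports):
    return float(np.median([r.auroc for r in reports]))
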