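import numpy as np
import pandas as pd
import pytest

import lymphomir as lm


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that keeps every structural feature of the design:
    five classes in both cohorts, three validation sites, planted markers,
    engineered dropout, spike-ins, standards and duplicates."""
    return lm.SimulationConfig(
        n_mirnas=140,
        n_samples_discovery={c: 8 for c in lm.CLASSES},
        n_samples_validation={c: 12 for c in lm.CLASSES},
        n_markers_per_class=4,
        dropout_fraction=0.10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return lm.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_quant(small_cohort):
    plates, _, _ = small_cohort
    return lm.quantify_plateset(plates)


@pytest.fixture(scope="session")
def discovery_normalized(small_cohort, small_quant):
    """Detection-filtered, globally normalized, Z-scored discovery values."""
    _, annotation, _ = small_cohort
    em, _ = small_quant
    disc = annotation.index[annotation["cohort"] == "discovery"]
    filtered = lm.filter_detection(
        lm.ExpressionMatrix(em.values.loc[disc], em.mask.loc[disc]))
    return lm.zscore_standardize(lm.global_mean_normalize(filtered.values))


@pytest.fixture(scope="session")
def marker_panel(small_cohort, discovery_normalized):
    _, annotation, _ = small_cohort
    return lm.build_marker_panel(discovery_normalized,
                                 annotation["diagnosis"])


def gaussian_classes(n_per_class, n_features, effect, classes=("a", "b"),
                     n_informative=None, seed=0):
    """Well-separated Gaussian feature table for classifier tests."""
    rng = np.random.default_rng(seed)
    if n_informative is None:
        n_informative = n_features
    X, y = [], []
    for i, c in enumerate(classes):
        block = rng.normal(0.0, 1.0, (n_per_class, n_features))
        block[:, :n_informative] += i * effect
        X.append(block)
        y += [c] * n_per_class
    X = np.vstack(X)
    idx = [f"s{i}" for i in range(len(y))]
    cols = [f"f{j}" for j in range(n_features)]
    return (pd.DataFrame(X, index=idx, columns=cols),
            pd.Series(y, index=idx, name="label"))
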