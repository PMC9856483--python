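"""Shared synthetic feature builder for the example scripts."""

import numpy as np
import pandas as pd


def make_screen_features(n_per_class=40, n_features=30, n_informative=8,
                         effect=1.5, seed=0):
    """Binary screen features: a handful of informative markers among
    noise, mimicking a reduced candidate panel."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, cls in enumerate(("RL", "lymphoma")):
        block = rng.normal(0.0, 1.0, (n_per_class, n_features))
        block[:, :n_informative] += i * effect
        X.append(block)
        y += [cls] * n_per_class
    idx = [f"s{i}" for i in range(2 * n_per_class)]
    cols = [f"miR-{j + 1:03d}" for j in range(n_features)]
    return (pd.DataFrame(np.vstack(X), index=idx, columns=cols),
            pd.Series(y, index=idx, name="label"))
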