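import numpy as np
import pytest

import acinotrack as at


@pytest.fixture(scope="session")
def toy_dataset():
    """Small simulated 3-class composite dataset shared across classifier tests."""
    return at.make_labeled_composite_dataset(n_per_class=40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def simulate_null_calls(rng, mixtures, n_experiments=3, wells=3, acini=100):
    """Phenotype-call proportion table drawn from per-condition mixtures.

    ``mixtures`` maps condition -> (p_round, p_spread, p_tunnel).  Labels per
    well are multinomial draws — the sampling distribution the stratified
    tests see, without the cost of rasterizing movies.
    """
    import pandas as pd

    classes = ("round", "spread", "tunnel")
    rows = []
    for e in range(n_experiments):
        for cond, probs in mixtures.items():
            for w in range(wells):
                counts = rng.multinomial(acini, probs)
                row = {
                    "experiment": f"exp{e}",
                    "condition": cond,
                    "well": f"{cond}_w{w}",
                    "interval": 0,
                    "n": int(counts.sum()),
                }
                for c, k in zip(classes, counts):
                    row[f"count_{c}"] = int(k)
                    row[f"frac_{c}"] = k / counts.sum()
                row["mean_area_um2"] = float(rng.normal(5000, 300))
                rows.append(row)
    return pd.DataFrame(rows)
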