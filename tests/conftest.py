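import numpy as np
import pandas as pd
import pytest


def mk_matrix(values, features=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    features = features or [f"F{i}" for i in range(nf)]
    samples = samples or [f"s{j}" for j in range(ns)]
    return pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                        columns=samples)


def mk_annotation(samples, batches, is_gis=None, **traits) -> pd.DataFrame:
    ann = pd.DataFrame(
        {
            "batch": [str(b) for b in batches],
            "is_gis": [False] * len(samples) if is_gis is None else list(is_gis),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    for k, v in traits.items():
        ann[k] = v
    return ann


def random_dataset(rng, n_features=20, n_batches=3, per_batch=5, n_gis=1,
                   missing_frac=0.0, log2_scale=2.0):
    """Small positive matrix with batch structure for property tests."""
    ns = n_batches * (per_batch + n_gis)
    batches = np.repeat([f"b{k}" for k in range(n_batches)], per_batch + n_gis)
    gis = np.tile([False] * per_batch + [True] * n_gis, n_batches)
    base = rng.normal(15, 3, n_features)
    vals = 2.0 ** (base[:, None] + rng.normal(0, log2_scale, (n_features, ns)))
    if missing_frac:
        mask = rng.random(vals.shape) < missing_frac
        # keep at least one GIS value per (row, batch) so denominators exist
        vals = np.where(mask, np.nan, vals)
        for k in range(n_batches):
            cols = np.flatnonzero((batches == f"b{k}") & gis)
            vals[:, cols[0]] = np.where(np.isnan(vals[:, cols[0]]),
                                        2.0 ** base, vals[:, cols[0]])
    samples = [f"s{j}" for j in range(ns)]
    return mk_matrix(vals, samples=samples), mk_annotation(samples, batches, gis)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
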