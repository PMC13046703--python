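import numpy as np
import pytest

from chemorigin.registry import ClassProfile
from chemorigin.synthesis import ChemTable, GeneratorConfig, generate_dataset


def make_table(values, region, country=None, names=None) -> ChemTable:
    values = np.asarray(values, dtype=float)
    region = np.asarray(region, dtype=object)
    country = np.asarray(country if country is not None else region, dtype=object)
    names = names or [f"comp_{j + 1}" for j in range(values.shape[1])]
    return ChemTable(values, list(names), region, country)


def blob_config(means, sds, n_per_class=60, seed=0, **kwargs) -> GeneratorConfig:
    """Gaussian-blob generator config from per-class mean vectors."""
    profiles = []
    counts = {}
    for i, mean in enumerate(means):
        label = chr(ord("A") + i)
        profiles.append(ClassProfile(label, n_per_class, np.asarray(mean, float),
                                     np.broadcast_to(np.asarray(sds, float),
                                                     np.shape(mean)).copy()))
        counts[label] = (label, n_per_class)
    kwargs.setdefault("truncate_at_zero", False)
    return GeneratorConfig(profiles=profiles, region_counts=counts, seed=seed, **kwargs)


@pytest.fixture
def blobs3():
    """Three well-separated 5-feature Gaussian blobs, 60 samples each."""
    cfg = blob_config(
        means=[[0, 0, 0, 0, 0], [6, 6, 0, 0, 0], [0, 0, 6, 6, 0]],
        sds=1.0, n_per_class=60, seed=11)
    return generate_dataset(cfg)
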