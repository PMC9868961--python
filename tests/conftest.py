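import warnings

import pytest

import cleavesite as cs


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (379 sites), featurized once per session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = cs.generate_dataset(cs.default_profile(seed=11))
        cs.featurize_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def default_split(default_dataset):
    ds = cs.split_dataset(default_dataset, train_fraction=0.7, seed=11)
    train = [s for s, v in ds.split_assignment.items() if v == "train"]
    test = [s for s, v in ds.split_assignment.items() if v == "test"]
    return train, test


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two guides, four labeled sites, built by hand."""
    import numpy as np

    rng = np.random.default_rng(2)
    prof = cs.default_profile()
    g1 = cs.generate_guide(rng, 20, "gA", "Rice")
    g2 = cs.generate_guide(rng, 18, "gB", "Wheat")
    sites = [
        cs.embed_on_target(g1, rng, prof, "s1"),
        cs.embed_on_target(g2, rng, prof, "s2"),
        cs.mutate_off_target(g1, rng, prof, "s3"),
        cs.mutate_off_target(g2, rng, prof, "s4"),
    ]
    return cs.LabeledDataset(guides=[g1, g2], sites=sites)
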