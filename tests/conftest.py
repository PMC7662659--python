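import numpy as np
import pytest

import walnutmir as wm
from walnutmir.classifiers import ClassifierSpec
from walnutmir.synthetic_data import train_sizes


@pytest.fixture
def tiny_ds():
    """3 samples x 5 variables, two origins, nested varieties."""
    return wm.SpectralDataset(
        absorbance=np.arange(15, dtype=float).reshape(3, 5),
        wavenumbers=np.array([700.0, 800.0, 900.0, 1000.0, 1100.0]),
        origin=np.array(["A", "A", "B"], dtype=object),
        variety=np.array(["a1", "a1", "b1"], dtype=object),
        sample_id=np.array(["s1", "s2", "s3"], dtype=object),
    )


@pytest.fixture(scope="session")
def easy_task():
    """Easy 4-origin problem: denoised data, split, and an SPA subset."""
    spec = wm.easy_spec()
    ds = wm.denoise_dataset(wm.generate(spec))
    part = wm.stratified_split(ds, seed=0)
    tr = ds.select_ids(part.train_index)
    te = ds.select_ids(part.test_index)
    classes = sorted(set(map(str, tr.origin)))
    T = np.zeros((tr.n_samples, len(classes)))
    for i, o in enumerate(tr.origin):
        T[i, classes.index(str(o))] = 1.0
    sel = wm.spa_select(tr.absorbance, T, 5, 15).selected_index
    return {"spec": spec, "ds": ds, "part": part, "train": tr, "test": te,
            "selected": sel}


@pytest.fixture(scope="session")
def coarse_ds():
    """Study design at 4 cm^-1 spacing (688 points) with default noise."""
    spec = wm.default_spec(step=4.0)
    ds = wm.generate(spec)
    part = wm.stratified_split(ds, seed=0, train_sizes=train_sizes(spec))
    return {"spec": spec, "ds": ds, "part": part}


@pytest.fixture(scope="session")
def classifier_specs():
    return [ClassifierSpec("ELM", 20, seed=0),
            ClassifierSpec("RF", 40, seed=0),
            ClassifierSpec("RBF", 15, seed=0),
            ClassifierSpec("PLSDA", 5),
            ClassifierSpec("BPNN", 10, seed=0)]
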