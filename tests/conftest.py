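import numpy as np
import pandas as pd
import pytest

from crossarray.io import ExpressionMatrix


def make_matrix(values, probe_ids=None, sample_ids=None, groups=None, present=None):
    """Build an ExpressionMatrix from a 2-D array plus optional labels.

    ``groups`` may be a dict sample->label or a list aligned with samples;
    default: first half group 'a', second half group 'b'.
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i+1}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = ["a"] * half + ["b"] * (n_samples - half)
    if isinstance(groups, dict):
        gser = pd.Series(groups)
    else:
        gser = pd.Series(list(groups), index=sample_ids)
    ints = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    if present is None:
        pres = pd.DataFrame(True, index=probe_ids, columns=sample_ids)
    else:
        pres = pd.DataFrame(np.asarray(present, dtype=bool), index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(intensities=ints, present=pres, groups=gser)


def make_group_matrix(group_values, reps, noise_sd=0.0, seed=0, offset=100.0):
    """Matrix with per-group probe means ``offset + group_values[g]`` and gaussian noise.

    ``group_values``: dict label -> per-probe mean shifts (1-D arrays of equal
    length). Intensities are clipped at 0 to stay valid.
    """
    rng = np.random.default_rng(seed)
    labels = list(group_values)
    n_probes = len(next(iter(group_values.values())))
    cols, sample_ids, groups = [], [], []
    for label in labels:
        base = offset + np.asarray(group_values[label], dtype=float)
        for r in range(reps):
            cols.append(np.clip(base + rng.normal(0, noise_sd, n_probes), 0, None))
            sample_ids.append(f"{label}{r+1}")
            groups.append(label)
    return make_matrix(np.column_stack(cols), sample_ids=sample_ids, groups=groups)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], groups=["a", "b"])
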