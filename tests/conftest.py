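import numpy as np
import pytest

import sepsiscreen as ss


@pytest.fixture(scope="session")
def builtin_specs():
    return ss.builtin_cohort_specs(0)


@pytest.fixture(scope="session")
def planted_cohort(builtin_specs):
    """A strongly separated synthetic cohort: MDW carries a 3-SD signal."""
    spec = builtin_specs["PA-ED"].replace(
        n=2000,
        effect_sizes={"mdw": 3.0, "crp": 1.5, "neutrophils": 1.0, "lymphocytes": -0.5},
        seed=123,
    )
    return ss.generate_cohort(spec)


def make_noise_table(n: int, seed: int, n_pos: int | None = None) -> ss.FeatureTable:
    """A label-independent table: all features pure noise (standard normal,
    shifted positive), labels balanced — nothing to learn."""
    rng = np.random.default_rng(seed)
    p = len(ss.FEATURE_NAMES)
    values = rng.normal(10.0, 1.0, size=(n, p))
    values[:, ss.FEATURE_NAMES.index("sex")] = rng.integers(0, 2, n)
    j_n = ss.FEATURE_NAMES.index("neutrophils")
    j_l = ss.FEATURE_NAMES.index("lymphocytes")
    values[:, ss.FEATURE_NAMES.index("nlr")] = values[:, j_n] / values[:, j_l]
    labels = np.zeros(n, dtype=int)
    k = n // 2 if n_pos is None else n_pos
    labels[rng.permutation(n)[:k]] = 1
    return ss.FeatureTable(
        ids=np.arange(n), columns=ss.FEATURE_NAMES, values=values,
        mask=np.zeros((n, p), dtype=bool), labels=labels)
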