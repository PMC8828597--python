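import pytest

import lipidtraffic as lt


@pytest.fixture(scope="session")
def small_dataset():
    """Small four-group synthetic study (default planted design, n=4)."""
    spec = lt.default_study_spec(seed=20260929, n_samples_per_group=4)
    return lt.generate(spec)


@pytest.fixture(scope="session")
def nn_profile(small_dataset):
    return lt.build_profile(small_dataset.tables_for("NN").values())


@pytest.fixture(scope="session")
def profiles(small_dataset):
    return {
        ph: lt.build_profile(small_dataset.tables_for(ph).values())
        for ph in small_dataset.spec.phenotypes
    }


def make_vars(n, lipid_class="TG"):
    """n distinct lipid variables of one class, canonical order."""
    out = []
    for i in range(n):
        c = 40 + 2 * (i // 7)
        d = i % 7
        out.append(lt.parse_lipid_name(f"{lipid_class}({c}:{d})"))
    return out
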