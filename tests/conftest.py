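import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def germline_set():
    from rabmab.synthetic import generate_germline_set

    return generate_germline_set(n_heavy=2, n_light=2, seed=1)


@pytest.fixture(scope="session")
def small_repertoire(germline_set):
    """120-clone synthetic repertoire with ground truth, plus annotations."""
    from rabmab.annotation import annotate_repertoire
    from rabmab.synthetic import RepertoireSimConfig, generate_repertoire

    config = RepertoireSimConfig(n_clones=120, shm_rate=8.0, seed=5)
    table = generate_repertoire(config, germline_set)
    clones = annotate_repertoire(table.to_dict("records"), germline_set)
    return config, table, clones
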