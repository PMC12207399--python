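import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_libs():
    from splintstore.fixtures import make_demo_libraries

    return make_demo_libraries(seed=42)


@pytest.fixture(scope="session")
def small_linker_library():
    from splintstore.library_design import LibraryDesignParams, design_linker_pairs

    return design_linker_pairs(LibraryDesignParams(n_linker_pairs=5, seed=7))
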