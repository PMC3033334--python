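import numpy as np
import pytest

import stageset as ss
from stageset.simulate import CategorySpec, PlantedBlock, SyntheticSpec


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast two-block design used by most unit tests."""
    return SyntheticSpec(
        n_genes=120,
        planted_blocks=(
            PlantedBlock("G9_sel", ("G9",), 10, 2.0),
            PlantedBlock("S9_sel", ("S9",), 10, 2.0),
        ),
        categories=(
            CategorySpec("cat_G9", 20, "G9_sel"),
            CategorySpec("null_01", 20, None),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return ss.generate(small_spec)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the reference study design (seed 1)."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = ss.PipelineConfig(out_dir=out, seed=1, synthetic=ss.default_spec(seed=1))
    manifest = ss.run(cfg)
    return cfg, manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
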