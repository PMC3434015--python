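import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedpack import container, ped_io, simulator

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# 3 subjects x 4 markers; header line of marker names, then six pedigree
# columns and two allele columns per marker. M3 contains a missing "0 0".
TOY_PED = """\
M1 M2 M3 M4
FAM1 ID1 0 0 1 2 1 2 2 2 1 2 1 1
FAM1 ID2 0 0 2 1 2 2 1 2 0 0 1 2
FAM2 ID3 0 0 1 1 1 2 2 2 1 2 2 2
"""

# minor allele resolves to 1 at every toy marker (tie-break at M1, M3, M4)
TOY_CODES = np.array(
    [
        [1, 0, 1, 2],
        [0, 1, 3, 1],
        [1, 0, 1, 0],
    ],
    dtype=np.uint8,
)


@pytest.fixture
def toy_ped_text() -> str:
    return TOY_PED


@pytest.fixture
def toy_ped_path(tmp_path):
    path = tmp_path / "toy.ped"
    path.write_text(TOY_PED)
    return path


@pytest.fixture
def toy_scan():
    return ped_io.scan_ped(io.StringIO(TOY_PED))


def make_random_ped(tmp_path, *, n=60, m=25, missing_rate=0.02, seed=11, name="rand"):
    """Seeded mixed-spectrum PED fixture written under tmp_path."""
    rng = np.random.default_rng(seed)
    mafs = np.concatenate(
        [
            rng.uniform(0.3, 0.5, m // 3),
            rng.uniform(0.05, 0.3, m // 3),
            rng.uniform(0.01, 0.05, m - 2 * (m // 3)),
        ]
    )
    config = simulator.SimConfig(
        n_subjects=n,
        n_markers=m,
        maf_spec=mafs.tolist(),
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulator.simulate_ped(config, tmp_path / name)


@pytest.fixture
def random_ped(tmp_path):
    return make_random_ped(tmp_path)


@pytest.fixture
def compressed_prefix(tmp_path, random_ped):
    ped_path, _ = random_ped
    prefix = tmp_path / "store"
    summary = container.compress_ped(ped_path, prefix)
    return prefix, ped_path, summary
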