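import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibnp import FibrilSpec, NPSpec, build_fibril, build_nanoparticle
from fibnp.model import NonbondedParams, StructureModel

settings.register_profile(
    "fibnp", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fibnp")


@pytest.fixture(scope="session")
def fibril_6p48():
    """Noiseless standard fibril with a 6.48 deg/peptide imposed twist."""
    return build_fibril(FibrilSpec(imposed_twist=6.48))


@pytest.fixture(scope="session")
def fibril_small():
    """Small noiseless fibril (8 peptides/protofilament) for cheap tests."""
    return build_fibril(FibrilSpec(n_peptides_per_protofilament=8,
                                   imposed_twist=6.48))


@pytest.fixture(scope="session")
def pos_np():
    return build_nanoparticle(NPSpec.from_recipe("Pos"))


@pytest.fixture()
def params():
    return NonbondedParams(rng_seed=11)


def toy_model(positions, charges=None, elements=None, names=None,
              res_seq=None, chain_ids=None, res_names=None,
              lj_epsilon=None, lj_rmin_half=None, vdw_radii=None,
              **kwargs) -> StructureModel:
    """Small ad-hoc structure for unit tests."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    return StructureModel.from_arrays(
        names=names or ["X"] * n,
        elements=elements or ["C"] * n,
        res_names=res_names or ["UNK"] * n,
        res_seq=res_seq if res_seq is not None else list(range(1, n + 1)),
        chain_ids=chain_ids or ["A"] * n,
        positions=positions,
        charges=charges,
        lj_epsilon=lj_epsilon,
        lj_rmin_half=lj_rmin_half,
        vdw_radii=vdw_radii,
        **kwargs,
    )
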