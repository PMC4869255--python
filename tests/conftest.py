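import numpy as np
import pytest

from prlrkit import coil_ensemble as coil
from prlrkit import geometry as geo
from prlrkit import synthetic_data as synth

#: master seed for the expensive shared ensembles; all derived randomness is
#: spawned from it deterministically
SESSION_SEED = 11

ICD_LENGTH = 363


@pytest.fixture(scope="session")
def ideal_helix():
    """24-residue ideal alpha-helix numbered 210-233."""
    return geo.build_backbone(["LEU"] * 24, geo.DihedralSet.uniform(24, -57, -47),
                              start_id=210)


@pytest.fixture(scope="session")
def icd_sequence():
    return coil.surrogate_sequence(ICD_LENGTH)


@pytest.fixture(scope="session")
def coil_ensemble_363(icd_sequence):
    """Shared 200-conformer statistical-coil ensemble of the 363-residue
    surrogate chain (the expensive fixture; generated once per session)."""
    return coil.generate_ensemble(icd_sequence, n=200, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def toy_assembly():
    """Toy ECD/TMD domains, assembly spec and a small pinned-overlap ICD ensemble."""
    ecd, tmd, spec = synth.gen_toy_domains(seed=1)
    icd = synth.gen_toy_icd_ensemble(seed=1, n=20, length=45)
    return ecd, tmd, icd, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(SESSION_SEED)
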