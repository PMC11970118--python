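import warnings

import pytest

import blockpol as bp
from blockpol.residues import GLUCAGON_SEQUENCE


@pytest.fixture(scope="session")
def db42():
    return bp.synthesize_db(seed=42)


@pytest.fixture(scope="session")
def helix3_pdb():
    return bp.make_fixture("helix", 3)


@pytest.fixture(scope="session")
def glucagon_pdb():
    """29-residue helix with glucagon's ionizable composition, no ions."""
    return bp.make_fixture("helix", 29, sequence=GLUCAGON_SEQUENCE)


@pytest.fixture(scope="session")
def saltbox_pdb():
    """Charge-separated 20-residue helix with all 8 ion positions occupied."""
    return bp.make_fixture("saltbox", 20, pairs=4)


@pytest.fixture(scope="session")
def saltbox_sweep(saltbox_pdb, db42):
    """All 70 ion-configuration predictions on the salt fixture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # residual non-neutrality is expected
        return bp.sweep_configurations(saltbox_pdb, db42)
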