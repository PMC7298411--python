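import numpy as np
import pytest

from qsar3d.fields import assemble_descriptor_matrix, build_grid, stack_blocks
from qsar3d.molecule import Molecule
from qsar3d.synth import SyntheticSeriesSpec, make_series_bundle


def make_atom_molecule(
    name="probe_target",
    symbols=("C",),
    coords=((0.0, 0.0, 0.0),),
    charges=None,
    vdw=None,
    hydrophobic=None,
    donors=None,
    acceptors=None,
):
    """Hand-built Molecule for analytic field checks (no RDKit round trip)."""
    n = len(symbols)
    return Molecule(
        name=name,
        symbols=list(symbols),
        coords=np.asarray(coords, dtype=float),
        charges=np.asarray(charges if charges is not None else np.zeros(n)),
        vdw_radii=np.asarray(vdw if vdw is not None else np.full(n, 1.7)),
        hydrophobic=np.asarray(hydrophobic if hydrophobic is not None else np.zeros(n)),
        is_donor=np.asarray(donors if donors is not None else np.zeros(n, bool)),
        is_acceptor=np.asarray(acceptors if acceptors is not None else np.zeros(n, bool)),
    )


@pytest.fixture(scope="session")
def atom_factory():
    return make_atom_molecule


def _bundle(n, seed, noise_sd):
    spec = SyntheticSeriesSpec(n_compounds=n, seed=seed, noise_sd=noise_sd)
    molecules, records, truth = make_series_bundle(spec)
    grid = build_grid(molecules, spec.grid_margin, spec.grid_spacing)
    blocks = assemble_descriptor_matrix(molecules, grid, method="comfa")
    X, block_index = stack_blocks(blocks)
    y = np.array([r.pic50 for r in records])
    return {
        "spec": spec,
        "molecules": molecules,
        "records": records,
        "truth": truth,
        "grid": grid,
        "blocks": blocks,
        "X": X,
        "block_index": block_index,
        "y": y,
    }


@pytest.fixture(scope="session")
def series12():
    """Small synthetic series for fast structural tests."""
    return _bundle(n=12, seed=3, noise_sd=0.1)


@pytest.fixture(scope="session")
def series35():
    """Training-set sized synthetic series used for recovery experiments."""
    return _bundle(n=35, seed=11, noise_sd=0.1)
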