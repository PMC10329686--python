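import numpy as np
import pytest

import spotloc as sl


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gradient_spec():
    """Small tissue with row/col gradients plus null genes."""
    genes = (
        [(f"gr_r{i}", sl.LinearGradient("row", 2.0)) for i in range(8)]
        + [(f"gr_c{i}", sl.LinearGradient("col", 2.0)) for i in range(8)]
        + [(f"null{i}", sl.NullGene()) for i in range(5)]
    )
    return sl.TissueSpec(grid=(16, 16), hole_fraction=0.1, n_layers=4,
                         genes=genes, seed=3)


@pytest.fixture(scope="session")
def gradient_reference(gradient_spec):
    return sl.normalize_expression(sl.make_reference(gradient_spec))


@pytest.fixture(scope="session")
def layered_spec():
    """5 marker genes per band over 4 bands."""
    genes = [(f"mk{layer}_{i}", sl.LayerMarker(layer, 2.0))
             for layer in range(1, 5) for i in range(5)]
    return sl.TissueSpec(grid=(16, 12), hole_fraction=0.1, n_layers=4,
                         genes=genes, seed=9)


@pytest.fixture(scope="session")
def layered_reference(layered_spec):
    return sl.normalize_expression(sl.make_reference(layered_spec))


@pytest.fixture()
def tiny_spots():
    """3 spots x 2 genes, hand-written."""
    return sl.SpotExpression(
        matrix=np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        gene_ids=["gA", "gB"],
        spot_ids=["s0", "s1", "s2"],
        spatial_coords=np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]]),
        array_coords=np.array([[0, 0], [0, 1], [1, 0]]),
        labels=np.array(["L1", "L1", "L2"]),
    )
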