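import numpy as np
import pytest

from pcskit.connectome_fc import edge_index_pairs
from pcskit.pcs_scoring import CSSTemplate
from pcskit.synthetic_data import SimulationConfig, generate_template


@pytest.fixture
def tiny_template():
    """3-parcel template with weights [2, 0, -1] over two networks."""
    labels = ["roiA", "roiB", "roiC"]
    return CSSTemplate(
        template_id="tiny",
        atlas_id="atlas3",
        weights=np.array([2.0, 0.0, -1.0]),
        edge_index=edge_index_pairs(3),
        parcel_labels=labels,
        network_partition={"roiA": "net1", "roiB": "net1", "roiC": "net2"},
    )


@pytest.fixture
def small_template():
    """Synthetic 20-parcel template with the default block structure."""
    return generate_template(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
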