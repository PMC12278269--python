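import numpy as np
import pytest

from symcell.embed import ClusterConfig, cluster_workflow
from symcell.qc import qc_filter, remove_flagged_doublets
from symcell.simulate import SimConfig, generate_dataset

#: compact study conditions used by most tests: four clusters (hosting,
#: effect, null, plain), a 30-gene immune set, ~200 cells per cluster.
SMALL = SimConfig(
    n_cells_per_state=400,
    n_host_genes=400,
    n_symbiont_genes=60,
    n_clusters=4,
    cluster_marker_genes=15,
    immune_geneset_size=30,
    marker_geneset_size=5,
    seed=11,
)

SMALL_CLUSTERING = ClusterConfig(hvg_n=300)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def prepared(small_dataset):
    """Doublet-removed, QC-filtered matrix with aligned truth rows."""
    ds = small_dataset
    m = remove_flagged_doublets(ds.matrix, ds.cells["is_doublet"].to_numpy())
    m, _ = qc_filter(m)
    truth = ds.truth.cells.reindex(m.cell_ids)
    return m, truth


@pytest.fixture(scope="session")
def clustered(prepared):
    """Host-gene embedding and Leiden labels for the small fixture."""
    m, truth = prepared
    host = m.host_view()
    norm, emb, labels = cluster_workflow(host, SMALL_CLUSTERING, seed=5)
    return host, norm, emb, labels, truth


def majority_map(detected, truth_clusters):
    out = {}
    detected = np.asarray(detected)
    truth_clusters = np.asarray(truth_clusters)
    for c in np.unique(detected):
        vals, counts = np.unique(truth_clusters[detected == c],
                                 return_counts=True)
        out[int(c)] = int(vals[np.argmax(counts)])
    return out
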