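import pandas as pd
import pytest

from nsnet.pipeline import PipelineConfig, run_all
from nsnet.ppi_network import Network


def make_network(edges, extra_nodes=()):
    """Network from (a, b, weight) tuples plus optional isolated nodes."""
    net = Network()
    for n in extra_nodes:
        net.add_node(n)
    for a, b, w in edges:
        net.add_node(a)
        net.add_node(b)
        net.add_edge(a, b, w)
    return net


def edge_df(edges):
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence"])


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full synthetic pipeline run (seed 1) shared across tests."""
    outdir = tmp_path_factory.mktemp("e2e")
    cfg = PipelineConfig(outdir=str(outdir), seed=1)
    results = run_all(cfg)
    results["outdir"] = outdir
    return results


def majority_map(found_membership, planted_of_gene):
    """Map each found community to the planted label of most of its genes."""
    votes = {}
    for g, c in found_membership.items():
        votes.setdefault(c, []).append(planted_of_gene[g])
    return {c: max(set(v), key=v.count) for c, v in votes.items()}
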