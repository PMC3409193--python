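import pytest

from paralogy.msa import Msa, Region


def random_binary_newick(labels, rng) -> str:
    """Random unrooted-shape binary topology by sequential joining."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture
def four_taxa_msa():
    labels = ["s1", "s2", "s3", "s4"]
    rows = [
        "ACGTACGTAC",
        "ACGTACGTAC",
        "ACGTTCGAAC",
        "ACGTTCGAAC",
    ]
    return Msa(labels, rows, [], {l: "X" for l in labels})


@pytest.fixture
def two_region_msa():
    labels = ["X_a", "X_b", "Y_a"]
    rows = [
        "ACGTACGTACGTACGTACGT",
        "ACGTACGAACGTACGTACGA",
        "TCGTACGTACGAACGTACGT",
    ]
    regions = [Region("r1", 0, 10), Region("r2", 10, 20)]
    return Msa(labels, rows, regions)
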