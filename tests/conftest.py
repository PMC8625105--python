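import numpy as np
import pandas as pd
import pytest

from ecomandala import CommunityTable, TaxonomyTable


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def small_community():
    counts = pd.DataFrame(
        [[5, 7, 9, 11], [3, 1, 4, 1], [10, 0, 2, 8]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CommunityTable(site_id="demo", habitat="lagoon", counts=counts)


@pytest.fixture
def small_taxonomy():
    rows = {
        "OTU_1": ["Bacteria", "Proteobacteria", "Alpha", "O1", "F1", "G1"],
        "OTU_2": ["Bacteria", "Proteobacteria", "Alpha", "O1", "F1", "G1"],
        "OTU_3": ["Bacteria", "Bacteroidetes", "B1", "O2", "F2", "G2"],
        "OTU_4": ["Bacteria", "Bacteroidetes", "B1", "O2", "F2", ""],
        "OTU_5": ["Archaea", "Euryarchaeota", "E1", "O3", "F3", "G3"],
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus"],
    )
    return TaxonomyTable(assignments=df)


def write_abundance_tsv(path, counts, otu_ids, times):
    lines = ["otu_id\t" + "\t".join(times)]
    for otu, row in zip(otu_ids, counts):
        lines.append(otu + "\t" + "\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
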