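import pandas as pd
import pytest

from pleionet import io as pio


def write(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def assoc_file(tmp_path):
    return write(tmp_path / "assoc.tsv",
                 "G1\tD1\nG2\tD1\nG2\tD2\n")


@pytest.fixture
def toy_assoc():
    return pio.DiseaseAssociationTable(pd.DataFrame(
        [("G1", "D1", ""), ("G2", "D1", ""), ("G2", "D2", ""),
         ("G3", "D3", ""), ("G4", "D1", ""), ("G4", "D2", ""), ("G4", "D4", "")],
        columns=["gene_id", "disease_id", "disease_name"]))


@pytest.fixture
def toy_sims():
    return pio.SimilarityTable.from_records([
        ("D1", "D2", 0.5), ("D1", "D4", 0.2), ("D2", "D4", 0.9),
    ])


@pytest.fixture
def small_sim_config():
    from pleionet.simulate import SimulationConfig
    return SimulationConfig(seed=11, n_genes=300, n_edges_target=1200)
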