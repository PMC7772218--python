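import numpy as np
import pandas as pd
import pytest

from bogdiv.genotype_io import GenotypeMatrix, PanelMetadata
from bogdiv.synthetic_data import fixture_config, simulate_panel, write_panel


@pytest.fixture(scope="session")
def fixture_panel():
    """Tiny deterministic four-stage panel (n=40, L=200)."""
    return simulate_panel(fixture_config(seed=2026))


@pytest.fixture(scope="session")
def fixture_paths(fixture_panel, tmp_path_factory):
    """The same panel written to disk in every emitted dialect."""
    out = tmp_path_factory.mktemp("panel")
    return write_panel(fixture_panel, out)


def toy_matrix(dosages, positions=None, chrom="chr1", ids=None):
    """Small GenotypeMatrix helper; dosages is (n, L) with -1 = missing."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * L, 1000))
    if ids is None:
        ids = [f"A{i}" for i in range(n)]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "C"}
    )
    return GenotypeMatrix(dosages, ids, markers)


def toy_metadata(ids, subgroups):
    return PanelMetadata(
        pd.DataFrame(
            {"accession_id": ids, "subgroup": subgroups, "origin": "toy"}
        )
    )
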