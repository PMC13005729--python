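import pathlib

import pandas as pd
import pytest

from enrichclust import GeneSetLibrary, generate_fixture
from enrichclust.io import write_gmt


@pytest.fixture
def toy_library() -> GeneSetLibrary:
    """Four small terms with partial overlaps; background = 10 genes."""
    return GeneSetLibrary(
        name="toy",
        sets={
            "T1": frozenset({"G1", "G2", "G3"}),
            "T2": frozenset({"G3", "G4"}),
            "T3": frozenset({"G5", "G6", "G7"}),
            "T4": frozenset({"G8", "G9", "G10"}),
        },
    )


@pytest.fixture
def toy_gmt(tmp_path, toy_library) -> pathlib.Path:
    path = tmp_path / "toy.gmt"
    write_gmt(toy_library, path)
    return path


@pytest.fixture
def planted():
    """Default planted-block fixture: 3 blocks x 4 terms, 4 conditions."""
    return generate_fixture(seed=11)


@pytest.fixture
def planted_files(tmp_path, planted):
    """Planted fixture written to disk (GMT + condition CSV)."""
    library, table, truth = planted
    gmt = tmp_path / "library.gmt"
    write_gmt(library, gmt)
    csv = tmp_path / "conditions.csv"
    table.to_csv(csv, index=False)
    return gmt, csv, truth
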