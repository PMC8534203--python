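from pathlib import Path

import pytest

from uhfdep import DielectricMaterial, ShelledCell

DATA = Path(__file__).resolve().parents[1] / "src" / "uhfdep" / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def reference_cell() -> ShelledCell:
    """Single-shell reference cell (x100-scaled membrane pair)."""
    return ShelledCell.from_json(DATA / "reference_cell.json")


@pytest.fixture(scope="session")
def reference_medium() -> DielectricMaterial:
    """Low-conductivity reference medium: eps_r 78, 20 mS/m."""
    return DielectricMaterial.from_json(DATA / "medium_reference.json")


@pytest.fixture(scope="session")
def dep_medium() -> DielectricMaterial:
    """Bench DEP suspension medium: eps_r 78, 26 mS/m."""
    return DielectricMaterial.from_json(DATA / "medium_dep.json")
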