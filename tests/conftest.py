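import numpy as np
import pytest

from chemmultiverse.dataio import ActivityMatrix, RawDataset
from chemmultiverse.synthdata import SynthConfig, generate


@pytest.fixture(scope="session")
def panel_dataset() -> RawDataset:
    """The 60-compound x 5-target scaffold-clustered fixture panel."""
    return generate(SynthConfig(seed=7))


@pytest.fixture()
def tiny_dataset() -> RawDataset:
    """Four hand-written compounds with one activity column.

    Row 2 carries a disallowed element (uranium) and row 3 is a SMILES
    respelling of row 0's ethanol, so curation must reject exactly two.
    """
    values = np.array([[6.5], [np.nan], [4.0], [7.2]])
    mask = np.isnan(values)
    return RawDataset(
        records=[("a", "CCO"), ("b", "CCN"), ("c", "[U]"), ("d", "OCC")],
        activities=ActivityMatrix(values=values, endpoint_names=["pKI_A"], missing_mask=mask),
    )


def write_csv(path, text: str) -> str:
    path.write_text(text, encoding="utf-8")
    return str(path)
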