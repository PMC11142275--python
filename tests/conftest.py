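import numpy as np
import pandas as pd
import pytest

import cytosar as cs


@pytest.fixture(scope="session")
def panel():
    return cs.default_panel()


@pytest.fixture(scope="session")
def small_plate():
    return cs.rocaglate_plate_map()


@pytest.fixture(scope="session")
def scheme():
    return cs.default_scheme()


@pytest.fixture()
def vehicle_table(panel):
    """2000 untreated cells, arcsinh-scaled."""
    tab = cs.generate_well_events(panel, cs.EffectSignature(), 2000, seed=11)
    return cs.arcsinh_scale(tab, panel.cofactors)


def make_table(values: dict[str, np.ndarray], role: str = "functional",
               scaled: bool = True) -> cs.EventTable:
    """Tiny hand-built EventTable with every channel given one role."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()})
    channels = {k: cs.ChannelInfo(role, 1.0 if role == "functional" else None)
                for k in data.columns}
    return cs.EventTable(data, channels,
                         scaled=set(data.columns) if scaled else set())
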