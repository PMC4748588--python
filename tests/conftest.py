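import numpy as np
import pandas as pd
import pytest

from hcscreen.pipeline import simulate_and_measure
from hcscreen.simulate import Geometry, SimulationConfig


def small_geometry() -> Geometry:
    return Geometry(fields_per_well=4, grid=(2, 2), image_size_px=320)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced plate: 2 replicate wells + control, 4 fields of 320 px."""
    return SimulationConfig(cells_per_well=150, wells_per_condition=2,
                            geometry=small_geometry())


@pytest.fixture(scope="session")
def small_run(small_config):
    """One simulated-and-segmented small plate shared across tests."""
    cells, truth, layout = simulate_and_measure(small_config, seed=11)
    return cells, truth, layout


def match_cells_to_truth(cells: pd.DataFrame, truth: pd.DataFrame,
                         max_dist: float = 3.0) -> pd.DataFrame:
    """Greedy nearest-centroid matching of segmented cells to ground truth."""
    rows = []
    for (well, field), grp in cells.groupby(["well", "field"]):
        tg = truth[(truth["well"] == well) & (truth["field"] == field)]
        if tg.empty:
            continue
        tx = tg["x"].to_numpy()
        ty = tg["y"].to_numpy()
        for _, rec in grp.iterrows():
            d = np.hypot(tx - rec["x"], ty - rec["y"])
            k = int(np.argmin(d))
            if d[k] <= max_dist:
                merged = {f"seg_{c}": rec[c] for c in rec.index}
                merged.update({f"t_{c}": tg.iloc[k][c] for c in tg.columns})
                merged["match_dist"] = float(d[k])
                rows.append(merged)
    return pd.DataFrame(rows)
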