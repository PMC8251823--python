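import numpy as np
import pandas as pd
import pytest

from isoassign.basemaps import Basemap, StudyPlots


@pytest.fixture()
def toy_basemap():
    """Five cells on a latitudinal line, 30 km apart, graded markers."""
    lat = np.array([36.0, 36.27, 36.54, 36.81, 37.08])
    return Basemap.from_layers(
        lon=np.full(5, -86.0), lat=lat,
        expected_isotope=np.array([-50.0, -55.0, -60.0, -65.0, -70.0]),
        expected_wing=np.array([102.0, 103.0, 104.0, 105.0, 106.0]),
        abundance=np.array([1.0, 2.0, 4.0, 2.0, 1.0]),
        cell_size_km=30.0)


@pytest.fixture()
def toy_plots():
    return StudyPlots(table=pd.DataFrame(
        {"plot_id": ["A"], "lon": [-86.0], "lat": [36.0]}))
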