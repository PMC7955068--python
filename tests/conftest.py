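import numpy as np
import pandas as pd
import pytest

from hifquant import catalog, synth
from hifquant.slides import SlideMap


@pytest.fixture(scope="session")
def manifest():
    return catalog.enumerate_catalog()


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic synthetic slide with all four tissue codes and
    a few hundred cells."""
    return synth.generate_scene(
        synth.SceneParams(shape=(120, 120), geometry_seed=3, point_seed=4),
        slide_id="S-small", patient_id="P-small", site_id="siteA")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_slide(raster, mpp=4.0, cells=None, slide_id="S1", patient_id="P1",
               site_id="site1"):
    if cells is None:
        cells = pd.DataFrame({"x_um": pd.Series(dtype=float),
                              "y_um": pd.Series(dtype=float),
                              "cell_class": pd.Series(dtype=str)})
    return SlideMap(slide_id=slide_id, patient_id=patient_id, site_id=site_id,
                    cancer_type="SYN", tissue_raster=np.asarray(raster, np.uint8),
                    tissue_mpp=mpp, cells=cells)
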