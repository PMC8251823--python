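"""Packaged datasets."""

from importlib import resources

import pandas as pd


def load_table1() -> pd.DataFrame:
    """Observed covariates for the 12 Indiana study plots.

    Columns: ``plot_id``; ``R`` self-recruitment rate (expected population
    growth absent immigration, the patch-quality measure); ``habitat_ha``
    deciduous forest within a 2 km radius (ha); ``density`` mean conspecific
    density (birds/ha); ``n`` second-year individuals sampled.
    """
    with resources.files(__name__).joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
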