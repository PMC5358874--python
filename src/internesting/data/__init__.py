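"""Small packaged reference tables."""

from importlib.resources import files

import pandas as pd


def load_multi_centroid_reference() -> pd.DataFrame:
    """Published successive-centroid distance table for a satellite-tracked
    Kemp's ridley nesting cohort: the 11 females with multiple inter-nesting
    home-range centroids in one season, with distances (km) between MCP
    centroids 1-2, 2-3 and 3-4 where present."""
    path = files(__package__) / "multi_centroid_reference.csv"
    with path.open() as fh:
        return pd.read_csv(fh, dtype={"turtle_id": str})
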