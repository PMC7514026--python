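"""Published reference summaries shipped with the package.

``uk_city_cv_reference`` is the ten-city cross-validation summary from
the original urban-violence study this method reproduces: per-city mean
(and sd) test R^2 of the alcohol-outlet-only baseline and the sparse
POI model over 100 random 50/50 point splits, plus the published
integer improvement percentages.  It validates the improvement
arithmetic without requiring the licensed source data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["uk_city_cv_reference", "LIVERPOOL"]

#: The city the published summary treats as the outlier when averaging.
LIVERPOOL = "Liverpool"


def uk_city_cv_reference() -> pd.DataFrame:
    """Ten-city baseline/model mean-R^2 reference table."""
    with resources.files("poicrime").joinpath(
            "data/uk_city_cv_reference.csv").open() as fh:
        return pd.read_csv(fh)
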