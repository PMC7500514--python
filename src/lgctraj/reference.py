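"""Published per-region slope estimates used as reference inputs.

The table holds, for 44 bilateral brain structures, the annual volumetric
slope at age 65 (percent of the age-65 volume per year), the slope-by-entry-age
interaction, the tabulated expected 20-year loss, the random-slope standard
deviation, and the p-values of the random-slope and sex likelihood-ratio
tests, as estimated on the LHAB healthy-aging cohort (N = 231, four waves
over four years).  They serve two purposes here: desk-scale inputs for the
piecewise extrapolation identity, and realistic presets for the synthetic
cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_slopes"]


def load_reference_slopes() -> pd.DataFrame:
    """Return the reference table indexed by snake_case region id.

    Columns: ``label``, ``slope`` (%/yr at age 65), ``slope_x_entry_age``
    (%/yr per year of entry age), ``loss20`` (% of age-65 volume),
    ``random_slope_sd`` (%/yr), ``random_slope_p``, ``sex_p``.
    """
    with resources.files("lgctraj.data").joinpath("regional_slopes.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("region")
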