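"""Packaged reference data."""

from importlib import resources

import pandas as pd


def load_md_cohort() -> pd.DataFrame:
    """Demographic and ophthalmic reference table for a 20-participant
    macular-degeneration cohort (6 early-onset, 14 late-onset).

    Columns include onset group (``EO``/``LO``), best-corrected binocular
    acuity in logMAR, and the PRL eccentricity in degrees measured by
    microperimetry.
    """
    with resources.files("prlcortex.data").joinpath("md_cohort.csv").open() as fh:
        return pd.read_csv(fh)
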