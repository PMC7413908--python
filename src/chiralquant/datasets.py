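"""Bundled worked-example data.

``influent_enantiomer_means`` ships mean enantiomer concentrations (ng/L,
n = 6 injections) of six chiral pharmaceuticals measured in influent
wastewater by a published chiral SFC-MS/MS environmental survey, as
transcribed from its printed results tables.  An enantiomer reported below
the method quantification limit is stored with an empty concentration and
a censoring flag (metoprolol's second-eluting enantiomer), so the table
exercises both the plain and the censored enantiomeric-fraction paths.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["influent_enantiomer_means", "worked_example_efs"]


def influent_enantiomer_means() -> pd.DataFrame:
    """Mean E1/E2 concentrations (ng/L) in influent wastewater."""
    path = resources.files("chiralquant.data") / "influent_enantiomer_means.csv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p)
    for col in ("e1_censored", "e2_censored"):
        frame[col] = frame[col].astype(bool)
    return frame


def worked_example_efs() -> pd.DataFrame:
    """Enantiomeric fractions for the bundled influent dataset.

    Censored enantiomers contribute zero, so metoprolol (E2 below the
    quantification limit) reports EF = 1.0 with its censoring flag set.
    """
    from .chiral import ef_from_concentrations

    frame = influent_enantiomer_means().copy()
    frame["ef"] = [
        ef_from_concentrations(
            0.0 if row.e1_censored else float(row.e1_mean_ng_l),
            0.0 if row.e2_censored else float(row.e2_mean_ng_l),
            censored_e1=bool(row.e1_censored),
            censored_e2=bool(row.e2_censored))
        for row in frame.itertuples()
    ]
    frame["ef_censored"] = frame["e1_censored"] | frame["e2_censored"]
    return frame[["analyte", "ef", "ef_censored"]]
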