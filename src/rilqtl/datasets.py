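"""Small built-in reference tables.

Published trait means for the F271 and Cm484 maize parental inbred lines and
for their RIL progeny, under irrigated (I) and non-irrigated (NI) field
scenarios, for agronomic and cell-wall traits.  Used for the percent-response
worked examples; values are scenario-level means in the units given.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["parental_trait_means", "ril_trait_means"]

_PARENTAL = [
    # trait, unit, F271_I, F271_NI, Cm484_I, Cm484_NI
    ("plant_height", "cm", 172.08, 143.52, 134.06, 122.91),
    ("yield", "t/ha", 3.83, 2.43, 2.48, 2.09),
    ("NDF", "%DM", 52.82, 54.58, 47.83, 52.45),
    ("IVDMD", "%DM", 46.78, 50.95, 55.68, 56.28),
    ("IVCWRD", "%CWR", 30.11, 38.16, 36.49, 43.19),
    ("KL.CWR", "%CWR", 16.41, 14.67, 14.61, 13.30),
    ("ADL.NDF", "%NDF", 5.74, 4.66, 4.75, 3.85),
    ("PCAest", "mg/g CWR", 14.04, 10.94, 11.43, 8.68),
]

_RIL = [
    # trait, unit, mean_I, mean_NI
    ("plant_height", "cm", 149.18, 127.07),
    ("yield", "t/ha", 3.01, 2.18),
]


def parental_trait_means() -> pd.DataFrame:
    """Scenario means of the two parental lines for selected traits."""
    return pd.DataFrame(
        _PARENTAL,
        columns=["trait", "unit", "F271_I", "F271_NI", "Cm484_I", "Cm484_NI"],
    ).set_index("trait")


def ril_trait_means() -> pd.DataFrame:
    """Scenario means over the RIL progeny for the agronomic traits."""
    return pd.DataFrame(
        _RIL, columns=["trait", "unit", "mean_I", "mean_NI"]).set_index("trait")
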