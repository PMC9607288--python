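"""Bundled example dataset: moxifloxacin/eugenol uptake by B. subtilis.

Published time-resolved distribution of moxifloxacin (MF, μM) and the
adjuvant eugenol (EG, mM) between solution, the cell-wall surface and
the cell interior of *B. subtilis* suspensions carrying a mannosylated
PEI carrier, with and without EG.  Central values of the reported
mean ± SD table; doses 47 μM MF and 6 mM EG.
"""

from __future__ import annotations

import pandas as pd

from .uptake import UptakeTable

__all__ = ["moxifloxacin_uptake_control", "moxifloxacin_uptake_with_eugenol"]

_TIMES = [0.0, 15.0, 45.0, 120.0, 840.0]  # min

MF_DOSE_UM = 47.0
EG_DOSE_MM = 6.0


def moxifloxacin_uptake_control() -> UptakeTable:
    """MF distribution without the adjuvant (carrier + MF only)."""
    frame = pd.DataFrame(
        {
            "time_min": _TIMES,
            "analyte": "MF",
            "c_solution": [47.0, 29.0, 15.0, 10.0, 12.0],
            "c_adsorbed": [0.0, 15.0, 30.0, 35.0, 33.0],
            "c_absorbed": [0.0, 2.8, 1.6, 1.2, 1.7],
        }
    )
    return UptakeTable(data=frame, dose={"MF": MF_DOSE_UM})


def moxifloxacin_uptake_with_eugenol() -> UptakeTable:
    """MF and EG distribution with 6 mM eugenol in the medium."""
    mf = pd.DataFrame(
        {
            "time_min": _TIMES,
            "analyte": "MF",
            "c_solution": [47.0, 15.0, 10.0, 12.0, 6.0],
            "c_adsorbed": [0.0, 27.0, 34.0, 32.0, 40.0],
            "c_absorbed": [0.0, 4.4, 3.3, 3.1, 0.5],
        }
    )
    eg = pd.DataFrame(
        {
            "time_min": _TIMES,
            "analyte": "EG",
            "c_solution": [6.0, 0.20, 0.10, 0.10, 0.010],
            "c_adsorbed": [0.0, 5.8, 5.9, 5.9, 6.0],
            "c_absorbed": [0.0, 0.030, 0.029, 0.026, 0.0010],
        }
    )
    return UptakeTable(
        data=pd.concat([mf, eg], ignore_index=True),
        dose={"MF": MF_DOSE_UM, "EG": EG_DOSE_MM},
    )
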