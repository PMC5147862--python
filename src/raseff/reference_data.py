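"""Reference constants: benchmark affinities, assay design, region annotations.

``REFERENCE_KD_UM`` is the 5×5 grid of dissociation constants (μM) measured
by fluorescence polarization for five RAS isoforms against five effector
domains under one common condition set. The grid serves two roles here: as
ground truth for the synthetic titration benchmarks (each entry seeds a
simulated curve that the fitter must recover) and as the row/column ordering
of the fitted-affinity output table.

``REFERENCE_REGIONS`` annotates the literature spans of the five interface
regions R1–R5 on the interaction-matrix frame (HRAS rows × CRAF columns).
They are used only to label and compare detected regions, never as input to
the detection algorithm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: assay design: labeled receptor concentration (μM) ...
RECEPTOR_TOTAL_UM = 1.0
#: ... effector titration span (μM) ...
CONC_RANGE_UM = (0.05, 100.0)
#: ... and number of log-spaced titration points
N_POINTS = 24

RAS_PROTEINS = ("HRAS", "KRAS", "NRAS", "RRAS1", "RRAS2")
EFFECTOR_DOMAINS = ("CRAF-RB", "RASSF5-RA", "RALGDS-RA", "PLCε-RA2", "PI3Kα-RB")

#: dissociation constants in μM; rows = effector domains, columns = RAS proteins
REFERENCE_KD_UM = pd.DataFrame(
    np.array(
        [
            [0.094, 0.142, 0.048, 2.29, 4.09],
            [0.238, 0.421, 0.442, 11.5, 10.00],
            [2.50, 1.39, 2.84, 9.71, 5.78],
            [3.70, 8.90, 5.36, 114.4, 145.4],
            [84.3, 204.7, 145.0, 11.00, 18.10],
        ]
    ),
    index=list(EFFECTOR_DOMAINS),
    columns=list(RAS_PROTEINS),
)

#: interface regions on the (HRAS row, CRAF column) frame; comparison only
REFERENCE_REGIONS = {
    "R1": {"rows": (37, 39), "cols": (66, 69)},
    "R2": {"rows": (21, 34), "cols": (83, 90)},
    "R3": {"rows": (36, 64), "cols": (57, 71)},
}


def titration_design(
    n_points: int = N_POINTS,
    conc_range: tuple[float, float] = CONC_RANGE_UM,
) -> np.ndarray:
    """Log-spaced effector concentrations (μM) spanning the assay range."""
    lo, hi = conc_range
    if not (0 < lo < hi):
        raise ValueError("conc_range must be positive and increasing")
    return np.geomspace(lo, hi, n_points)
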