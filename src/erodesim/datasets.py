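"""Built-in experimental data from the filament degradation study.

Mass loss and tensile elastic modulus of 1.9 mm diameter, ~50 mm long
extruded filaments of pure polycaprolactone (PCL) and of a PCL:MCC 98:2
composite (2 % wt:wt microcrystalline cellulose), degraded in a 7 mg/mL
lipase (Pseudomonas cepacia) suspension in PBS for 4, 24 and 48 h.  Values
are group means with standard deviations over 4 replicas.

Note the pure-PCL 48 h mass loss (5.88 %) sits *below* the 24 h value
(6.16 %): enzymatic saturation stopped the erosion, so that entry is not a
valid erosion reference and the PCL simulation schedule ends at 24 h.
"""

from __future__ import annotations

import pandas as pd

from .erosion import ReferenceSchedule

__all__ = [
    "degradation_table",
    "pcl_schedule",
    "composite_schedule",
    "FILAMENT_DIAMETER_MM",
    "FILAMENT_LENGTH_MM",
]

#: geometry of the experimental filaments (mm)
FILAMENT_DIAMETER_MM = 1.9
FILAMENT_LENGTH_MM = 50.3

_ROWS = [
    # material, time_h, mass_loss_pct, mass_loss_sd, modulus_MPa, modulus_sd, pH
    ("PCL", 0, None, None, 306.0, 46.0, 7.59),
    ("PCL", 4, 0.84, 0.11, 304.0, 29.0, 7.00),
    ("PCL", 24, 6.16, 0.28, 265.0, 37.0, 6.28),
    ("PCL", 48, 5.88, 0.28, 270.0, 25.0, 5.59),
    ("PCL:MCC 98:2", 0, None, None, 295.0, 17.0, 7.59),
    ("PCL:MCC 98:2", 4, 1.12, 0.15, 288.0, 36.0, 6.74),
    ("PCL:MCC 98:2", 24, 13.68, 1.31, 239.0, 16.0, 4.70),
    ("PCL:MCC 98:2", 48, 16.15, 5.28, 216.0, 23.0, 4.35),
]


def degradation_table() -> pd.DataFrame:
    """Mass-loss / elastic-modulus evolution of both materials.

    Columns: material, time_h, mass_loss_pct, mass_loss_sd, modulus_MPa,
    modulus_sd, pH.  Mass loss is NaN at t=0 (undegraded reference).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "material",
            "time_h",
            "mass_loss_pct",
            "mass_loss_sd",
            "modulus_MPa",
            "modulus_sd",
            "pH",
        ],
    ).astype({"time_h": float, "mass_loss_pct": float, "mass_loss_sd": float})


def pcl_schedule() -> ReferenceSchedule:
    """Erosion references for pure PCL: 0.84 % @ 4 h, 6.16 % @ 24 h.

    The saturated 48 h measurement (5.88 %, below the 24 h value) is
    excluded — a pure surface-erosion run cannot regain mass.
    """
    return ReferenceSchedule.from_pairs([(4.0, 0.84), (24.0, 6.16)])


def composite_schedule() -> ReferenceSchedule:
    """Erosion references for PCL:MCC 98:2: 1.12 / 13.68 / 16.15 % at
    4 / 24 / 48 h."""
    return ReferenceSchedule.from_pairs([(4.0, 1.12), (24.0, 13.68), (48.0, 16.15)])
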