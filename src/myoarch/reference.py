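"""Published in vivo soleus compartment reference values.

Compartment-mean architecture of the four human soleus compartments at a short
and a long muscle length (cohort means over six subjects, as printed in the
source study's summary table). These are *inputs* to the report-table
arithmetic: the whole-muscle rows, change rows and derived percentages are
recomputed from them by this package, not copied.
"""

from __future__ import annotations

import pandas as pd

from .arch_stats import METRICS, compartment_table, round_half_up

__all__ = ["COMPARTMENTS", "TABLE_CELLS", "reference_records", "reference_summary"]

COMPARTMENTS = ["MA", "LA", "MP", "LP"]

# (compartment, condition) -> metric means; units cm^3, cm^2, mm, deg, 1/m
TABLE_CELLS = {
    ("MA", "short"): dict(volume_cm3=33.5, pcsa_cm2=9.3, fascicle_length_mm=37.7,
                          pennation_deg=22.0, curvature_per_m=15.3),
    ("MA", "long"): dict(volume_cm3=33.5, pcsa_cm2=6.7, fascicle_length_mm=51.9,
                         pennation_deg=17.3, curvature_per_m=7.9),
    ("LA", "short"): dict(volume_cm3=40.4, pcsa_cm2=10.9, fascicle_length_mm=37.7,
                          pennation_deg=27.1, curvature_per_m=16.1),
    ("LA", "long"): dict(volume_cm3=37.0, pcsa_cm2=8.0, fascicle_length_mm=45.9,
                         pennation_deg=18.6, curvature_per_m=7.7),
    ("MP", "short"): dict(volume_cm3=146.6, pcsa_cm2=41.5, fascicle_length_mm=36.0,
                          pennation_deg=38.3, curvature_per_m=19.7),
    ("MP", "long"): dict(volume_cm3=139.4, pcsa_cm2=30.7, fascicle_length_mm=45.9,
                         pennation_deg=24.5, curvature_per_m=11.4),
    ("LP", "short"): dict(volume_cm3=141.7, pcsa_cm2=40.1, fascicle_length_mm=35.7,
                          pennation_deg=34.9, curvature_per_m=18.6),
    ("LP", "long"): dict(volume_cm3=139.2, pcsa_cm2=29.9, fascicle_length_mm=46.2,
                         pennation_deg=24.2, curvature_per_m=10.8),
}


# printed whole-muscle rows (computed in the source study from unrounded
# per-subject data; they can differ from sums/means of the rounded compartment
# cells above by one unit in the last printed digit)
TABLE_WHOLE_CELLS = {
    "short": dict(volume_cm3=362.2, pcsa_cm2=101.8, fascicle_length_mm=36.8,
                  pennation_deg=30.6, curvature_per_m=17.4),
    "long": dict(volume_cm3=349.1, pcsa_cm2=75.2, fascicle_length_mm=47.5,
                 pennation_deg=21.1, curvature_per_m=9.4),
}


def reference_records() -> pd.DataFrame:
    """The reference cells as one pseudo-subject's records (the cohort mean)."""
    rows = [
        {"subject_id": "cohort-mean", "compartment": comp, "condition": cond, **cells}
        for (comp, cond), cells in TABLE_CELLS.items()
    ]
    return pd.DataFrame(rows)


def reference_summary(decimals: int = 1) -> pd.DataFrame:
    """Whole-muscle and change rows recomputed from the reference compartment
    cells (sums for volume/PCSA, unweighted means otherwise, long - short for
    change), rounded half-up to report precision."""
    table = compartment_table(reference_records())
    means = table[[f"{m}_mean" for m in METRICS]].copy()
    means.columns = METRICS
    return means.map(lambda v: round_half_up(v, decimals))
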