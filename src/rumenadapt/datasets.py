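"""Small bundled reference tables.

``load_reference_daily_scores`` returns the published worked example
this package's scoring step is checked against: the per-step daily
indices (display scale, i.e. x1e7) of eight rumen-cannulated dairy
goats across a standard-to-high-concentrate diet challenge, together
with the reported global index of each animal.  The daily indices are
inputs here — feeding them to :func:`rumenadapt.scoring.global_index`
must reproduce the reported Index column (the step between the two
pre-change baseline days is excluded from the sum).

Two caveats travel with the table: the reported index of goat 4 is not
consistent with the sum of its own daily indices (an apparent
typesetting slip in the source table), and goat 5's row typesetting is
ambiguous; both are therefore excluded from arithmetic checks by
default (``consistent_only=True``).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_daily_scores", "STEP_COLUMNS"]

#: Step columns in trajectory order (d1->d2 first, d8->d9 last).
STEP_COLUMNS = [
    "d1_2", "d2_3", "d3_4", "d4_5", "d5_6", "d6_7", "d7_8", "d8_9",
]

_ROWS = [
    # goat, d1->2, d2->3, d3->4, d4->5, d5->6, d6->7, d7->8, d8->9, index
    (1, 0.89, -5.64, -17.74, -2.22, -0.64, 1.10, 2.90, -4.19, -26.42),
    (2, -1.09, -2.14, -6.36, -1.34, 6.20, -1.15, 0.82, -2.69, -6.66),
    (3, -0.80, -1.24, -13.91, 13.12, -4.39, 1.41, -2.38, 0.88, -6.51),
    (4, -0.72, -9.50, -1.31, 0.84, 4.06, -3.87, -1.53, -2.71, -4.01),
    (5, -0.27, -2.38, -6.83, 5.64, -3.77, 2.98, -1.53, 1.19, -4.70),
    (6, -1.25, 5.99, -5.78, 0.60, -3.97, 1.54, -0.99, -1.70, -4.31),
    (7, 3.08, 7.80, -1.11, -16.19, -14.88, 4.89, -0.96, -4.08, -24.53),
    (8, 0.70, -4.60, 2.57, -3.76, 5.77, -0.54, 0.46, -3.67, -3.76),
]

#: Goats whose reported index matches the sum of their own daily indices.
CONSISTENT_GOATS = (1, 2, 3, 6, 7, 8)


def load_reference_daily_scores(consistent_only: bool = False) -> pd.DataFrame:
    """Reference daily indices (x1e7) and reported global index per goat.

    Parameters
    ----------
    consistent_only
        When True, drop the two rows whose reported index cannot be
        checked against their own daily indices (goats 4 and 5).
    """
    df = pd.DataFrame(
        _ROWS, columns=["goat", *STEP_COLUMNS, "reported_index"]
    )
    if consistent_only:
        df = df[df["goat"].isin(CONSISTENT_GOATS)].reset_index(drop=True)
    return df
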