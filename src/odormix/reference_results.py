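"""Published reference concentration-estimation results.

The original methanol/ethanol/acetone measurement campaign on a Cyranose 320
electronic nose reports, for every test mixture, the real concentrations,
the concentrations estimated by weighted constrained least squares, and the
resulting RMSE (all in ppm, rounded to 2 decimals).  These rows are bundled
here so the package's RMSE metric can be validated against independently
published numbers: recomputing RMSE from the real/estimated columns must
reproduce the printed RMSE column.

Rows are grouped by component set: seven three-component mixtures, eighteen
two-component mixtures, and fifteen pure samples.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "THREE_COMPONENT_ROWS",
    "TWO_COMPONENT_ROWS",
    "PURE_ROWS",
    "reference_frame",
]

# (row_id, real_M, real_E, real_A, est_M, est_E, est_A, reported_rmse) — ppm
THREE_COMPONENT_ROWS = [
    ("MEA-1", 34, 34, 34, 33.32, 30.12, 38.61, 3.50),
    ("MEA-2", 34, 34, 51, 37.29, 33.34, 49.54, 2.11),
    ("MEA-3", 34, 34, 68, 34.69, 31.50, 68.82, 1.57),
    ("MEA-4", 34, 51, 34, 38.85, 49.33, 29.74, 3.85),
    ("MEA-5", 34, 68, 34, 35.82, 64.28, 38.30, 3.45),
    ("MEA-6", 51, 34, 34, 56.11, 36.80, 26.81, 5.34),
    ("MEA-7", 68, 34, 34, 66.88, 29.93, 38.24, 3.45),
]

TWO_COMPONENT_ROWS = [
    ("ME-1", 34, 34, 0, 31.70, 31.19, 0.46, 2.11),
    ("ME-2", 34, 51, 0, 37.79, 45.23, 2.84, 4.31),
    ("ME-3", 34, 68, 0, 39.66, 64.52, 2.67, 4.13),
    ("ME-4", 51, 34, 0, 47.44, 32.20, 0.00, 2.30),
    ("ME-5", 51, 51, 0, 52.46, 47.45, 0.00, 2.22),
    ("ME-6", 68, 34, 0, 64.05, 31.94, 0.00, 2.57),
    ("EA-1", 0, 34, 34, 0.48, 32.50, 28.64, 3.23),
    ("EA-2", 0, 34, 51, 2.82, 28.63, 49.35, 3.63),
    ("EA-3", 0, 34, 68, 2.93, 24.32, 68.49, 5.85),
    ("EA-4", 0, 51, 34, 5.77, 39.01, 38.21, 8.06),
    ("EA-5", 0, 51, 51, 5.39, 37.60, 54.68, 8.61),
    ("EA-6", 0, 68, 34, 9.61, 48.33, 40.86, 13.25),
    ("AM-1", 34, 0, 34, 19.27, 13.62, 24.29, 12.87),
    ("AM-2", 34, 0, 51, 20.29, 7.45, 46.22, 9.42),
    ("AM-3", 34, 0, 68, 20.92, 2.77, 65.17, 7.89),
    ("AM-4", 51, 0, 34, 33.37, 7.59, 32.14, 11.13),
    ("AM-5", 51, 0, 51, 36.08, 3.06, 51.03, 8.79),
    ("AM-6", 68, 0, 34, 51.07, 1.96, 47.15, 12.43),
]

PURE_ROWS = [
    ("M-1", 28, 0, 0, 7.55, 16.20, 0.00, 15.06),
    ("M-2", 45, 0, 0, 28.94, 11.38, 0.00, 11.36),
    ("M-3", 57, 0, 0, 40.94, 9.07, 0.00, 10.65),
    ("M-4", 68, 0, 0, 53.96, 6.57, 0.00, 8.95),
    ("M-5", 85, 0, 0, 73.01, 3.92, 0.00, 7.28),
    ("E-1", 0, 28, 0, 0.02, 29.57, 0.00, 0.91),
    ("E-2", 0, 45, 0, 1.32, 41.71, 0.00, 2.05),
    ("E-3", 0, 56, 0, 6.52, 48.33, 2.49, 5.99),
    ("E-4", 0, 68, 0, 8.00, 54.99, 4.30, 9.16),
    ("E-5", 0, 85, 0, 6.12, 68.56, 15.00, 13.33),
    ("A-1", 0, 0, 28, 0.00, 20.17, 0.00, 19.92),
    ("A-2", 0, 0, 45, 0.00, 15.19, 18.17, 17.80),
    ("A-3", 0, 0, 56, 0.00, 11.64, 32.61, 15.08),
    ("A-4", 0, 0, 68, 0.00, 7.54, 47.22, 12.76),
    ("A-5", 0, 0, 85, 0.00, 0.97, 71.11, 8.04),
]


def reference_frame() -> pd.DataFrame:
    """All reference rows as one DataFrame, in published order."""
    cols = ["row_id", "real_M", "real_E", "real_A",
            "est_M", "est_E", "est_A", "reported_rmse"]
    return pd.DataFrame(
        THREE_COMPONENT_ROWS + TWO_COMPONENT_ROWS + PURE_ROWS, columns=cols
    )
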