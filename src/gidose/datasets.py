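"""Bundled clinical summary data.

The motivating clinical dataset: per-patient reference-plan D_0.5cc values
(Gy) of a published 12-patient pancreatic SBRT cohort (40 Gy in five
fractions), reported for each GI organ and for its planning-at-risk volume
(organ + 5 mm).  The underlying CT and dose grids are not public; these
printed per-patient values are the inputs to the cohort-level rankings the
package reproduces (highest-dose organ counts, dose floors).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_d05cc", "reference_d05cc_prv"]

# patient, tumor location, then (organ itself, PRV) D_0.5cc in Gy for
# gastroduodenum, small intestine, large intestine
_D05CC_ROWS = [
    (1, "body", 27.8, 37.4, 17.4, 19.4, 16.2, 18.5),
    (2, "body", 25.7, 33.8, 22.4, 33.0, 20.6, 30.3),
    (3, "body", 26.4, 32.4, 15.2, 18.3, 15.7, 16.0),
    (4, "body", 24.2, 31.8, 15.7, 29.2, 11.8, 12.2),
    (5, "body", 27.4, 32.2, 27.6, 32.6, 25.9, 29.5),
    (6, "head", 25.8, 30.8, 26.8, 32.0, 22.8, 30.0),
    (7, "head", 30.8, 33.0, 14.3, 23.0, 23.7, 28.2),
    (8, "head", 26.8, 31.8, 11.3, 19.2, 16.3, 19.7),
    (9, "body", 30.5, 32.4, 21.1, 28.2, 15.9, 18.8),
    (10, "head", 31.3, 32.9, 9.9, 11.6, 26.1, 30.6),
    (11, "head", 31.6, 32.7, 25.5, 32.1, 18.1, 25.3),
    (12, "head", 30.8, 34.9, 9.7, 13.3, 19.0, 29.6),
]

_ORGANS = ("gastroduodenum", "small_intestine", "large_intestine")


def load_reference_d05cc() -> pd.DataFrame:
    """Tidy long table of the clinical reference-plan D_0.5cc values.

    Columns: patient, tumor_location, organ, region ("organ" or "prv"),
    d05cc_gy.  72 rows (12 patients x 3 organs x 2 regions).
    """
    rows = []
    for patient, loc, *vals in _D05CC_ROWS:
        for k, organ in enumerate(_ORGANS):
            rows.append((patient, loc, organ, "organ", vals[2 * k]))
            rows.append((patient, loc, organ, "prv", vals[2 * k + 1]))
    return pd.DataFrame(
        rows, columns=["patient", "tumor_location", "organ", "region", "d05cc_gy"]
    )


def reference_d05cc_prv() -> pd.DataFrame:
    """PRV D_0.5cc values as a patients x organs table (Gy)."""
    long = load_reference_d05cc()
    prv = long[long["region"] == "prv"]
    return prv.pivot(index="patient", columns="organ", values="d05cc_gy")[list(_ORGANS)]
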