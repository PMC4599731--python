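"""Printed release-group summary used as generator input and worked-example data.

One row per release group (year x population): fork-length moments, number
released, number detected at the upstream (NSOG) and downstream (QCS)
curtains, and the printed route tallies.  Chilko sockeye carried the small
V7 tag; every other group carried V9.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "release_year",
    "species",
    "population",
    "origin",
    "fl_mean_mm",
    "fl_sd_mm",
    "n_released",
    "n_detected_nsog",
    "n_detected_qcs",
    "n_linear",
    "n_counterclockwise",
    "n_clockwise",
]

_ROWS = [
    (2004, "sockeye", "Cultus", "H", 178, 13, 100, 34, 13, 13, 1, 0),
    (2004, "sockeye", "Sakinaw", "H", 193, 15, 97, 38, 16, 16, 4, 1),
    (2005, "sockeye", "Cultus", "H", 177, 14, 378, 44, 22, 17, 8, 4),
    (2005, "sockeye", "Sakinaw", "W", 191, 12, 47, 13, 3, 2, 3, 3),
    (2006, "sockeye", "Cultus", "H", 178, 9, 200, 54, 30, 26, 6, 3),
    (2006, "sockeye", "Sakinaw", "H/W", 206, 14, 136, 40, 15, 12, 7, 6),
    (2007, "sockeye", "Cultus", "H", 182, 11, 319, 107, 64, 58, 12, 4),
    (2010, "sockeye", "Chilko", "W", 130, 4, 199, 25, 4, 3, 4, 1),
    (2011, "sockeye", "Chilko", "W", 133, 7, 443, 54, 24, 23, 2, 0),
    (2012, "sockeye", "Chilko", "W", 123, 4, 386, 60, 18, 19, 7, 3),
    (2013, "sockeye", "Chilko", "W", 123, 2, 432, 184, 48, 42, 32, 13),
    (2004, "steelhead", "Cheakamus", "W", 184, 17, 51, 26, 10, 7, 7, 2),
    (2004, "steelhead", "Englishman", "W", 174, 17, 67, 41, 10, 8, 9, 3),
    (2005, "steelhead", "Cheakamus", "W", 178, 14, 49, 26, 13, 10, 5, 1),
    (2005, "steelhead", "Englishman", "W", 159, 15, 43, 20, 5, 4, 2, 2),
    (2006, "steelhead", "Englishman", "W", 169, 12, 50, 34, 12, 9, 10, 2),
    (2006, "steelhead", "Seymour", "H", 207, 16, 50, 5, 1, 0, 3, 0),
    (2007, "steelhead", "Cheakamus", "H", 183, 11, 100, 12, 3, 3, 1, 0),
    (2007, "steelhead", "Seymour", "H", 186, 13, 60, 6, 1, 1, 1, 0),
    (2008, "steelhead", "Cheakamus", "H/W", 180, 12, 198, 55, 20, 17, 14, 1),
    (2008, "steelhead", "Seymour", "H", 184, 14, 60, 9, 4, 4, 2, 0),
]


def study_groups() -> pd.DataFrame:
    """The printed per-release-group summary as a DataFrame."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df["tag_model"] = [
        "V7" if (sp == "sockeye" and pop == "Chilko") else "V9"
        for sp, pop in zip(df["species"], df["population"])
    ]
    return df
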