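"""Published reference values for the four UCI heart-disease cohorts.

The study that evaluated the CS indicators on the UCI heart-disease
repository reported, for each subset (Cleveland, Hungarian, Long Beach,
Switzerland) and each indicator, the per-group mean, median and sample
SD (group 0 = non-cardiac, group 1 = cardiac), the two-sided
Wilcoxon-Mann-Whitney p-value, and the resulting consistency measure
``d = |mu0 - mu1| / sqrt(s0^2 + s1^2)``.  Those printed values are kept
here so the consistency ranking can be recomputed and cross-checked
without access to the underlying clinical records.

Columns of each stats frame: ``mu0, mu1, m0, m1, s0, s1, p`` indexed by
indicator in the conventional order.
"""

from __future__ import annotations

import pandas as pd

from .indicators import INDICATOR_ORDER

_COLS = ["mu0", "mu1", "m0", "m1", "s0", "s1", "p"]


def _frame(rows: dict[str, tuple]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_COLS)
    return df.reindex(list(INDICATOR_ORDER))


#: Per-group descriptive statistics of the indicators, by cohort.
PUBLISHED_GROUP_STATS: dict[str, pd.DataFrame] = {
    "cleveland": _frame({
        "ALPHA":  (0.0038, 0.0040, 0.0029, 0.0033, 0.0029, 0.0033, 0.4837),
        "ALPHA2": (5.8280, 5.7834, 5.8284, 5.7121, 0.7035, 0.7473, 0.4837),
        "HM":     (88.2808, 79.0296, 51.6722, 42.4812, 118.2997, 94.5672, 0.3004),
        "MAP":    (105.1306, 108.0998, 105.9115, 107.8869, 11.6754, 11.6864, 0.0793),
        "PBPI":   (0.5439, 0.5692, 0.5294, 0.5556, 0.1824, 0.1760, 0.2434),
        "PBPIRC": (19.3680, 19.8608, 15.7457, 17.3187, 12.5346, 11.7759, 0.5273),
        "RC":     (0.0339, 0.0340, 0.0329, 0.0325, 0.0115, 0.0113, 0.9683),
    }),
    "hungarian": _frame({
        "ALPHA":  (0.0048, 0.0047, 0.0039, 0.0038, 0.0043, 0.0035, 0.7747),
        "ALPHA2": (5.5739, 5.5588, 5.5552, 5.5628, 0.6453, 0.6335, 0.7747),
        "HM":     (53.8264, 55.4877, 38.9873, 37.2640, 51.6480, 77.3438, 0.2751),
        "MAP":    (105.4446, 108.6070, 102.9850, 108.0512, 11.4091, 12.3450, 0.0262),
        "PBPI":   (0.5639, 0.5971, 0.5500, 0.5556, 0.1502, 0.2195, 0.1196),
        "PBPIRC": (21.7992, 22.9755, 18.6552, 19.2456, 13.1868, 18.9023, 0.6145),
        "RC":     (0.0295, 0.0300, 0.0280, 0.0291, 0.0081, 0.0080, 0.5268),
    }),
    "longbeach": _frame({
        "ALPHA":  (0.0038, 0.0044, 0.0029, 0.0039, 0.0030, 0.0028, 0.1033),
        "ALPHA2": (5.8083, 5.8785, 5.8440, 5.5574, 0.6754, 3.0681, 0.1033),
        "HM":     (67.7813, 47.4181, 44.0492, 34.3783, 69.1907, 49.5149, 0.0886),
        "MAP":    (102.7137, 106.1425, 99.0182, 104.4601, 13.1111, 11.7342, 0.1067),
        "PBPI":   (0.6404, 0.6842, 0.6085, 0.6500, 0.2085, 0.2005, 0.2863),
        "PBPIRC": (23.5717, 25.9667, 20.7905, 21.8479, 15.9530, 13.7833, 0.2079),
        "RC":     (0.0327, 0.0299, 0.0307, 0.0288, 0.0106, 0.0083, 0.1720),
    }),
    "switzerland": _frame({
        "ALPHA":  (0.0039, 0.0038, 0.0042, 0.0026, 0.0031, 0.0036, 0.9293),
        "ALPHA2": (5.9888, 5.9288, 5.4949, 5.9362, 1.1305, 0.8388, 0.9293),
        "HM":     (197.6817, 112.8445, 33.3719, 56.5868, 285.4129, 166.4005, 0.9293),
        "MAP":    (98.9302, 104.4039, 102.2406, 102.0779, 16.6840, 14.5477, 0.5347),
        "PBPI":   (0.5972, 0.5976, 0.6587, 0.5714, 0.2409, 0.2411, 0.7942),
        "PBPIRC": (22.1667, 21.8520, 26.9187, 15.5101, 13.9135, 19.4161, 0.6276),
        "RC":     (0.0355, 0.0358, 0.0247, 0.0341, 0.0161, 0.0134, 0.5839),
    }),
}

#: Published consistency measures d per cohort and indicator.
PUBLISHED_CONSISTENCY: pd.DataFrame = pd.DataFrame(
    {
        "ALPHA":  [0.0648, 0.0091, 0.1522, 0.0204],
        "ALPHA2": [0.0435, 0.0167, 0.0223, 0.0426],
        "HM":     [0.0611, 0.0179, 0.2393, 0.2568],
        "MAP":    [0.1797, 0.1881, 0.1949, 0.2473],
        "PBPI":   [0.0996, 0.1249, 0.1514, 0.0011],
        "PBPIRC": [0.0286, 0.0510, 0.1136, 0.0132],
        "RC":     [0.0083, 0.0473, 0.2037, 0.0163],
    },
    index=["cleveland", "hungarian", "longbeach", "switzerland"],
)

#: Cohort sizes and class counts (n, n_class0, n_class1).
COHORT_SIZES: dict[str, tuple[int, int, int]] = {
    "cleveland": (282, 157, 125),
    "hungarian": (294, 188, 106),
    "longbeach": (200, 51, 149),
    "switzerland": (123, 8, 115),
}
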