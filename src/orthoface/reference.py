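"""Reference summary statistics from the 20-subject clinical validation.

A clinical cohort of 20 adults (10 men, 10 women, 5 with dentofacial
deformities) was measured with digital calipers (CM, the conventional
reference) and by two trained versions of the automated program (AM1:
200 training epochs; AM2: 1000 epochs).  These published per-measurement
summary statistics — group mean +/- SD per method, and mean +/- SD of the
paired differences — are the inputs for re-deriving the agreement tables,
and the CM column doubles as the population model for the synthetic-face
generator.

All values in millimetres; n = 20 throughout.
"""

from __future__ import annotations

N_SUBJECTS = 20

#: Group mean +/- SD per method: {measurement: {method: (mean, sd)}}.
GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "M1": {"CM": (62.47, 5.05), "AM1": (56.33, 2.50), "AM2": (56.09, 3.06)},
    "M2": {"CM": (67.42, 6.22), "AM1": (63.95, 3.94), "AM2": (65.84, 3.62)},
    "M3": {"CM": (32.02, 2.41), "AM1": (32.01, 2.30), "AM2": (32.83, 2.40)},
    "M4": {"CM": (33.36, 3.54), "AM1": (35.08, 2.59), "AM2": (34.35, 3.60)},
    "M5": {"CM": (20.55, 3.08), "AM1": (19.23, 1.30), "AM2": (19.54, 1.33)},
    "M6": {"CM": (9.27, 1.35), "AM1": (8.94, 1.01), "AM2": (8.12, 1.51)},
    "M7": {"CM": (45.21, 4.79), "AM1": (42.39, 3.35), "AM2": (43.55, 2.93)},
    "M8": {"CM": (11.96, 1.88), "AM1": (9.51, 1.01), "AM2": (10.22, 1.60)},
    "M9": {"CM": (2.20, 0.93), "AM1": (2.34, 0.59), "AM2": (2.81, 0.98)},
}

#: Paired differences CM - AM, mean +/- SD: {measurement: {version: (mean, sd)}}.
DIFF_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "M1": {"AM1": (6.14, 5.32), "AM2": (6.38, 6.08)},
    "M2": {"AM1": (3.47, 6.55), "AM2": (1.58, 7.07)},
    "M3": {"AM1": (0.01, 2.90), "AM2": (-0.81, 3.01)},
    "M4": {"AM1": (-1.71, 3.41), "AM2": (-0.99, 4.18)},
    "M5": {"AM1": (1.32, 3.18), "AM2": (1.01, 3.51)},
    "M6": {"AM1": (0.33, 1.61), "AM2": (1.15, 2.04)},
    "M7": {"AM1": (2.82, 5.56), "AM2": (1.66, 4.98)},
    "M8": {"AM1": (2.44, 1.68), "AM2": (1.74, 1.62)},
    "M9": {"AM1": (-0.13, 1.15), "AM2": (-0.61, 1.43)},
}

#: Exact published p-values for the paired CM-vs-AM comparisons (entries
#: printed only as "< 0.001" are given as None).
PUBLISHED_P: dict[str, dict[str, float | None]] = {
    "M1": {"AM1": None, "AM2": None},
    "M2": {"AM1": 0.029, "AM2": 0.330},
    "M3": {"AM1": 0.983, "AM2": 0.244},
    "M4": {"AM1": 0.037, "AM2": 0.304},
    "M5": {"AM1": 0.079, "AM2": 0.216},
    "M6": {"AM1": 0.366, "AM2": 0.021},
    "M7": {"AM1": 0.035, "AM2": 0.152},
    "M8": {"AM1": None, "AM2": None},
    "M9": {"AM1": 0.610, "AM2": 0.072},
}
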