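"""Centralised unit conversions.

Canonical internal units: activity in nCi, mass in g, counts in cpm,
time in minutes (chip) or seconds (in-vivo transfer constants).
Keeping every conversion here prevents unit drift across modules.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ComputationError

#: disintegrations per minute in one nanocurie
DPM_PER_NCI = 2220.0

#: physical half-life of iodine-125, days
I125_HALF_LIFE_DAYS = 59.4


def cpm_to_nci(counts, counter_efficiency: float):
    """Convert measured counts per minute to activity in nCi.

    ``counter_efficiency`` is in cpm per nCi (detector counts registered per
    nCi of activity in the well), so it already folds in DPM_PER_NCI.
    """
    if counter_efficiency <= 0:
        raise ComputationError("counter_efficiency must be > 0")
    return np.asarray(counts, dtype=float) / counter_efficiency


def nci_to_cpm(activity_nci, counter_efficiency: float):
    if counter_efficiency <= 0:
        raise ComputationError("counter_efficiency must be > 0")
    return np.asarray(activity_nci, dtype=float) * counter_efficiency


def mg_to_g(weight_mg):
    return np.asarray(weight_mg, dtype=float) / 1000.0


def g_to_mg(weight_g):
    return np.asarray(weight_g, dtype=float) * 1000.0


def decay_correct_i125(activity_nci, elapsed_days: float):
    """Correct a measured I-125 activity back to the reference time.

    Returns the activity that was present ``elapsed_days`` before the
    measurement, using the 59.4-day physical half-life.
    """
    if elapsed_days < 0:
        raise ComputationError("elapsed_days must be >= 0")
    factor = 2.0 ** (elapsed_days / I125_HALF_LIFE_DAYS)
    return np.asarray(activity_nci, dtype=float) * factor
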