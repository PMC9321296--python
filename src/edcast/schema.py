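"""Canonical categorical vocabularies shared by the generator and the feature builder.

User-supplied visit streams may carry other categories; the feature builder
folds unknown categories into counts but one-hot encodes only these, so the
feature matrix has a stable schema between training and live prediction.
"""

from __future__ import annotations

AGE_BANDS = ("18-44", "45-64", "65+")
ARRIVAL_METHODS = ("walk-in", "ambulance")
LOCATIONS = ("waiting", "triage", "majors", "resus", "utc", "cdu", "mhs")
OBS_TYPES = ("triage_score", "news", "heart_rate", "resp_rate", "pressure_check")
# observation types whose latest value is a meaningful number (pressure_check is a flag)
NUMERIC_OBS = ("triage_score", "news", "heart_rate", "resp_rate")
CONSULT_SPECIALTIES = ("medicine", "surgery", "ortho")
BATTERIES = ("fbc", "u_e", "crp", "bone_profile")
BATTERY_TESTS = {
    "fbc": ("wcc",),
    "u_e": ("sodium", "creatinine"),
    "crp": ("crp",),
    "bone_profile": ("calcium",),
}
TESTS = ("wcc", "sodium", "creatinine", "crp", "calcium")
TEST_RANGES = {
    "wcc": (4.0, 11.0),
    "sodium": (135.0, 145.0),
    "creatinine": (60.0, 110.0),
    "crp": (0.0, 5.0),
    "calcium": (2.2, 2.6),
}

# arrival-time-of-day bands aligned with the four daily report times
HOUR_BANDS = ("22-06", "06-12", "12-16", "16-22")


def hour_band(hour: int) -> str:
    """Band a clock hour into the four report-time intervals."""
    if 6 <= hour < 12:
        return "06-12"
    if 12 <= hour < 16:
        return "12-16"
    if 16 <= hour < 22:
        return "16-22"
    return "22-06"
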