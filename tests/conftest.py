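import pytest

from gctherm.sequences import PRIMER_PROFILES


@pytest.fixture(scope="session")
def primer_pair():
    return PRIMER_PROFILES["arch_109aF_915aR"]


# Printed per-OTU growth-temperature table rows, keyed by P_G+C percent:
# (tmin, tmin_hw, topt, topt_hw, tmax, tmax_hw), all degC at 1 decimal.
TABLE_PER_OTU = {
    56.1: (18.3, 14.1, 35.4, 14.8, 44.8, 13.8),
    60.2: (34.3, 14.6, 52.7, 15.3, 62.4, 14.3),
    54.7: (12.8, 13.9, 29.4, 14.6, 38.8, 13.7),
    57.9: (25.3, 14.3, 43.0, 15.0, 52.5, 14.1),
    56.5: (19.8, 14.1, 37.1, 14.8, 46.5, 13.9),
    61.2: (38.2, 14.7, 57.0, 15.4, 66.6, 14.5),
    60.6: (35.8, 14.6, 54.4, 15.3, 64.1, 14.4),
    59.9: (33.1, 14.5, 51.5, 15.3, 61.1, 14.3),
    59.2: (30.4, 14.4, 48.5, 15.2, 58.1, 14.2),
    58.1: (26.1, 14.3, 43.8, 15.0, 53.4, 14.1),
}

# Printed community summary rows per sampling date:
# weighted P_G+C, then (tmin, tmin_hw, topt, topt_hw, tmax, tmax_hw).
TABLE_COMMUNITY = {
    "0 months": (57.0, (21.6, 14.2, 39.0, 14.9, 48.5, 13.9)),
    "7 months": (57.7, (24.4, 14.3, 42.0, 15.0, 51.5, 14.0)),
    "13 months": (58.6, (28.2, 14.4, 46.2, 15.1, 55.7, 14.1)),
    "19 months": (59.0, (29.7, 14.4, 47.8, 15.1, 57.4, 14.2)),
    "26 months": (59.0, (29.7, 14.4, 47.8, 15.1, 57.4, 14.2)),
}
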