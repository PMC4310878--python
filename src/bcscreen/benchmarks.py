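"""Published national benchmark outcome tables.

These are the officially reported strategy-evaluation rows for the Japanese
and US screening programmes (100% participation, delta' = 1.5 delta, 60-year
follow-up from age 40): total screenings and breast-cancer deaths per
strategy, the no-screening baselines, and the whole-cohort life expectancies
with and without breast-cancer death.  They serve two purposes:

1. validation of the reporting formulas — every derived column (deaths
   averted, death reduction %, maintained fraction, extension days, NNS) can
   be recomputed from these primitives and checked against the published
   derived columns;
2. magnitude context for simulations on the synthetic fixture curves.

They are *inputs*, never outputs, of this package.
"""

from __future__ import annotations

__all__ = [
    "TABLE_STRATEGIES",
    "BASELINE_DEATHS",
    "LIFE_EXPECTANCY",
    "FALSE_POSITIVES",
    "NNS_COLUMNS",
]

# (country, interval) -> {(scmin, scmax): (screenings, bc_deaths)}
TABLE_STRATEGIES: dict[tuple[str, int], dict[tuple[int, int], tuple[int, int]]] = {
    ("japan", 2): {
        (40, 69): (1_443_763, 1821),
        (50, 69): (947_159, 1952),
        (40, 74): (1_704_723, 1695),
        (50, 74): (1_208_118, 1825),
        (40, 79): (1_867_271, 1636),
        (50, 79): (1_370_666, 1764),
    },
    ("japan", 1): {
        (40, 69): (2_877_439, 1612),
        (50, 69): (1_885_811, 1787),
        (40, 74): (3_311_710, 1491),
        (50, 74): (2_320_081, 1665),
        (40, 79): (3_717_061, 1406),
        (50, 79): (2_725_432, 1582),
    },
    ("us", 2): {
        (40, 69): (1_401_446, 6926),
        (50, 69): (906_670, 7202),
        (40, 74): (1_627_584, 6260),
        (50, 74): (1_132_808, 6536),
        (40, 79): (1_757_771, 5902),
        (50, 79): (1_262_995, 6180),
    },
    ("us", 1): {
        (40, 69): (2_784_694, 6098),
        (50, 69): (1_797_511, 6496),
        (40, 74): (3_159_597, 5403),
        (50, 74): (2_172_414, 5801),
        (40, 79): (3_482_743, 4856),
        (50, 79): (2_495_560, 5253),
    },
}

# no-screening breast-cancer deaths over the 60-year follow-up from age 40
BASELINE_DEATHS: dict[str, int] = {"japan": 2657, "us": 9238}

# whole-cohort average life expectancy at age 40 (expected age at death, years)
LIFE_EXPECTANCY: dict[str, dict[str, float]] = {
    "japan": {"no_screening": 87.72, "no_bc_death": 88.15},
    "us": {"no_screening": 81.91, "no_bc_death": 83.03},
}

# false-positive totals for the biennial 40-74 and 50-74 strategies
FALSE_POSITIVES: dict[str, dict[tuple[int, int], int]] = {
    "japan": {(40, 74): 120_820, (50, 74): 73_127},
    "us": {(40, 74): 139_521, (50, 74): 91_025},
}

# published NNS columns for spot-checking: (country, interval, scmin, scmax)
# -> (nns_detect, nns_avert)
NNS_COLUMNS: dict[tuple[str, int, int, int], tuple[int, int]] = {
    ("japan", 2, 40, 69): (218, 793),
    ("japan", 2, 40, 74): (239, 1006),
    ("japan", 2, 50, 74): (176, 662),
    ("japan", 1, 40, 69): (407, 1785),
    ("us", 2, 40, 69): (119, 202),
    ("us", 2, 40, 74): (118, 260),
    ("us", 2, 50, 74): (85, 173),
    ("us", 1, 40, 69): (210, 457),
}
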