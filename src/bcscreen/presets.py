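"""Country parameter presets and synthetic registry-like rate curves.

The scalar natural-history parameters (progression h2-h4, clinical
presentation f2-f5, stage mortality delta, the delta' multiplier and the
screening test characteristics) are published point values and are shipped
here as the "japan" and "us" presets.

The age-specific curves — incidence h1 and other-cause mortality mu — are
only published as ranges, so this module synthesizes deterministic
*fixture* curves consistent with those ranges and with the qualitative
shapes of the two countries' registry data: Japanese incidence peaks near
age 47 (maximum 146 per 100 000) and declines gently afterwards, US
incidence rises continuously to a plateau around ages 75-79 (maximum 421
per 100 000); other-cause mortality follows a Gompertz curve from 1e-4 at
age 0 to the published age-100 values.  These fixtures stand in for
user-supplied registry tables; analyses of real populations should load
actual schedules with ``rates.read_rate_table``.
"""

from __future__ import annotations

import numpy as np

from .estimation import StageDistribution
from .natural_history import NaturalHistoryParams
from .rates import AGE_MAX, AGE_MIN, AgeRateSchedule, CurveProfile, synth_schedule
from .screening import ScreeningPerformance

__all__ = [
    "PRESETS",
    "incidence_fixture",
    "other_mortality_fixture",
    "specificity_schedule",
    "participation_fixture",
    "natural_history_preset",
    "performance_preset",
    "stage_distribution_preset",
]

# published point parameters per country
PRESETS: dict[str, dict] = {
    "japan": {
        "h2": 0.22, "h3": 0.06, "h4": 0.01,
        "f2": 0.07, "f3": 0.12, "f4": 0.11, "f5": 0.40,
        "delta1": 0.008, "delta2": 0.021, "delta3": 0.062, "delta4": 0.230,
        "m": 1.5,
        "se": 0.815,
        "sp_min": 0.904, "sp_max": 0.947,
        "sd": 0.0032,
        "incidence_peak_age": 47, "incidence_peak": 0.00146,
        "mu_anchors": ((0, 1e-4), (40, 6e-4), (70, 0.009), (100, 0.3136)),
        "observed_participation": 0.30,
        "stage_outpatient_pct": (41.8, 46.3, 9.2, 2.7),
        "stage_screening_pct": (69.9, 27.3, 2.3, 0.6),
    },
    "us": {
        "h2": 0.43, "h3": 0.12, "h4": 0.05,
        "f2": 0.04, "f3": 0.05, "f4": 0.09, "f5": 0.16,
        "delta1": 0.012, "delta2": 0.043, "delta3": 0.107, "delta4": 0.273,
        "m": 1.5,
        "se": 0.835,
        "sp_min": 0.902, "sp_max": 0.931,
        "sd": 0.0047,
        "incidence_peak_age": 77, "incidence_peak": 0.00421,
        "mu_anchors": ((0, 1e-4), (40, 1.4e-3), (70, 0.015), (100, 0.2948)),
        "observed_participation": 0.50,
        "stage_outpatient_pct": (26.3, 38.8, 23.0, 11.9),
        "stage_screening_pct": (63.8, 29.8, 5.1, 1.3),
    },
}


def _preset(country: str) -> dict:
    try:
        return PRESETS[country]
    except KeyError:
        raise KeyError(f"unknown country preset {country!r}; "
                       f"available: {sorted(PRESETS)}") from None


def incidence_fixture(country: str) -> AgeRateSchedule:
    """Synthetic age-specific breast-cancer incidence curve (annual probability)."""
    p = _preset(country)
    peak = p["incidence_peak"]
    if country == "japan":
        # early peak in the late 40s, gentle decline into old age
        anchors = [
            (0, 0.0), (20, 0.0), (25, 2e-5), (30, 2e-4), (35, 6e-4),
            (40, 1.1e-3), (p["incidence_peak_age"], peak),
            (55, 1.25e-3), (65, 1.05e-3), (75, 8.5e-4), (85, 6.5e-4), (100, 5e-4),
        ]
    else:
        # continuous rise to a plateau at ages 75-79, mild decline after
        anchors = [
            (0, 0.0), (20, 0.0), (25, 1e-5), (30, 5e-5), (35, 3e-4),
            (40, 1.2e-3), (50, 2.3e-3), (60, 3.1e-3), (70, 3.8e-3),
            (p["incidence_peak_age"], peak), (85, 4.0e-3), (100, 3.7e-3),
        ]
    return synth_schedule(CurveProfile("peaked", anchors, label=f"{country}-incidence"))


def other_mortality_fixture(country: str) -> AgeRateSchedule:
    """Synthetic all-cause-minus-breast-cancer mortality.

    Piecewise-Gompertz (log-linear between anchors) through life-table-like
    anchor points: 1e-4 at birth, realistic mid-life female rates, and the
    published age-100 endpoint.
    """
    p = _preset(country)
    return synth_schedule(CurveProfile("gompertz", p["mu_anchors"],
                                       label=f"{country}-mu"))


def specificity_schedule(country: str) -> AgeRateSchedule:
    """Specificity linear in age from its minimum at 40 to its maximum at 84.

    Mammography is least specific in the dense-breast 40s; outside the
    screening ages the endpoint values are held constant.
    """
    p = _preset(country)
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    vals = p["sp_min"] + (p["sp_max"] - p["sp_min"]) * np.clip((ages - 40) / (84 - 40), 0, 1)
    return AgeRateSchedule(vals)


def participation_fixture(country: str) -> AgeRateSchedule:
    """Observed-participation fixture: flat at the national rate for ages
    40-65, declining linearly to zero by age 85, zero outside."""
    p = _preset(country)
    e = p["observed_participation"]
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    vals = np.where(
        (ages >= 40) & (ages <= 65), e,
        np.where((ages > 65) & (ages < 85), e * (85 - ages) / 20.0, 0.0),
    )
    return AgeRateSchedule(vals)


def natural_history_preset(country: str, m: float | None = None) -> NaturalHistoryParams:
    """NaturalHistoryParams for a country, on the synthetic fixture curves."""
    p = _preset(country)
    return NaturalHistoryParams(
        h1=incidence_fixture(country),
        mu=other_mortality_fixture(country),
        h2=p["h2"], h3=p["h3"], h4=p["h4"],
        f2=p["f2"], f3=p["f3"], f4=p["f4"], f5=p["f5"],
        delta1=p["delta1"], delta2=p["delta2"], delta3=p["delta3"], delta4=p["delta4"],
        m=p["m"] if m is None else m,
    )


def performance_preset(country: str) -> ScreeningPerformance:
    p = _preset(country)
    return ScreeningPerformance(se=p["se"], sp=specificity_schedule(country),
                                sd_reference=p["sd"])


def params_from_config(path) -> tuple[NaturalHistoryParams, ScreeningPerformance]:
    """Build parameters from a YAML config.

    The file names a base ``preset`` ("japan" or "us") and may override any
    scalar under ``overrides`` (h2-h4, f2-f5, delta1-delta4, m, se) or point
    at rate tables under ``rate_tables`` (h1, mu, sp) to replace the
    synthetic fixture curves.
    """
    import yaml

    from .rates import read_rate_table

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    country = doc.get("preset", "japan")
    base = dict(_preset(country))
    base.update(doc.get("overrides", {}))

    tables = doc.get("rate_tables", {})
    h1 = (read_rate_table(tables["h1"], "h1") if "h1" in tables
          else incidence_fixture(country))
    mu = (read_rate_table(tables["mu"], "mu") if "mu" in tables
          else other_mortality_fixture(country))
    sp = (read_rate_table(tables["sp"], "sp") if "sp" in tables
          else specificity_schedule(country))

    params = NaturalHistoryParams(
        h1=h1, mu=mu,
        h2=base["h2"], h3=base["h3"], h4=base["h4"],
        f2=base["f2"], f3=base["f3"], f4=base["f4"], f5=base["f5"],
        delta1=base["delta1"], delta2=base["delta2"], delta3=base["delta3"],
        delta4=base["delta4"], m=base["m"],
    )
    perf = ScreeningPerformance(se=base["se"], sp=sp, sd_reference=base["sd"])
    return params, perf


def stage_distribution_preset(country: str, mode: str,
                              n_effective: float = 10_000.0) -> StageDistribution:
    """Published stage-at-detection distribution for one detection mode."""
    p = _preset(country)
    key = "stage_outpatient_pct" if mode == "outpatient" else "stage_screening_pct"
    return StageDistribution.from_percent(p[key], mode=mode, n_effective=n_effective)
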