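"""Seeded synthetic input bundles for the SSB portion-size cost-effectiveness model.

The real analysis drew on Australian survey consumption tables, supermarket
sales data and national disease epidemiology.  None of those inputs are
redistributable, so this module generates statistically plausible stand-ins
with the same shape: a single-year-of-age population table (ages 2-100, both
sexes), nine obesity-related disease specifications, a per age-band SSB
consumption profile, and a package-size sales-share table.

When ``calibrate_to_published`` is set, the consumption profile reproduces the
published band-level baseline intakes and the sales-share table reproduces the
published marginals (27% of SSB volume sold as single-serve; 59% of
single-serve volume in packages above 375 mL).  Everything else is synthetic
and seeded: identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")

#: Consumption age bands (inclusive bounds); the upper band is open-ended.
AGE_BANDS: dict[str, tuple[int, int]] = {
    "2-12": (2, 12),
    "13-19": (13, 19),
    "20+": (20, 200),
}

#: Default whole-drink energy density, kJ/mL.  A 600 kJ standard serving of a
#: discretionary beverage corresponds to roughly 375 mL (600 / 375 = 1.6).
DEFAULT_ENERGY_DENSITY = 1.6

#: The nine causally obesity-related diseases modelled.
DISEASE_NAMES = (
    "ischaemic heart disease",
    "hypertensive heart disease",
    "ischemic stroke",
    "diabetes",
    "colorectal cancer",
    "kidney cancer",
    "breast cancer",
    "endometrial cancer",
    "osteoarthritis",
)

# Published band-level baselines (kJ/day/person): total energy intake and SSB
# energy intake, by sex and age band.
_BASELINE_TOTAL_ENERGY = {
    ("male", "2-12"): 8140.3,
    ("female", "2-12"): 7137.4,
    ("male", "13-19"): 10771.7,
    ("female", "13-19"): 8260.6,
    ("male", "20+"): 10308.0,
    ("female", "20+"): 7841.2,
}
_BASELINE_SSB_ENERGY = {
    ("male", "2-12"): 466.6,
    ("female", "2-12"): 426.9,
    ("male", "13-19"): 687.0,
    ("female", "13-19"): 600.8,
    ("male", "20+"): 684.8,
    ("female", "20+"): 557.6,
}

# Calibrated package-size sales shares.  Single-serve volume sums to 0.27 and
# the over-375 mL single-serve portion is 0.59 of that.
_CALIBRATED_SHARES = [
    # (package_size mL, single_serve, volume_share)
    (250, True, 0.27 * 0.41 * 0.40),
    (375, True, 0.27 * 0.41 * 0.60),
    (450, True, 0.27 * 0.59 * 0.38),
    (500, True, 0.27 * 0.59 * 0.31),
    (600, True, 0.27 * 0.59 * 0.31),
    (1250, False, 0.73 * 0.40),
    (2000, False, 0.73 * 0.60),
]

#: Default package-size grid used by the uncalibrated generator.
DEFAULT_PACKAGE_SIZES = (250, 375, 450, 500, 600, 1250, 2000)
SINGLE_SERVE_MAX_SIZE = 600


def age_band(age: int) -> str:
    """Return the consumption age band containing ``age``."""
    for band, (lo, hi) in AGE_BANDS.items():
        if lo <= age <= hi:
            return band
    raise ValueError(f"age {age} outside modelled range")


@dataclass
class DiseaseSpec:
    """One obesity-related disease process.

    ``rates`` is indexed by (sex, age) with columns ``incidence``,
    ``prevalence``, ``case_fatality``, ``remission`` (annual rates /
    proportions) and ``rr_per_bmi_unit`` (relative risk of incidence per
    +1 kg/m^2 of BMI; 1.0 encodes no BMI link).
    """

    name: str
    disability_weight: float
    annual_cost_per_case: float
    rates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"incidence", "prevalence", "case_fatality", "remission",
                    "rr_per_bmi_unit"}
        missing = required - set(self.rates.columns)
        if missing:
            raise ValueError(f"{self.name}: rates table missing {sorted(missing)}")
        if not 0 <= self.disability_weight < 1:
            raise ValueError(f"{self.name}: disability_weight outside [0, 1)")
        if self.annual_cost_per_case < 0:
            raise ValueError(f"{self.name}: negative annual cost")


def generate_population(seed: int, max_age: int = 100) -> pd.DataFrame:
    """Generate the (sex, age) population table.

    Columns: ``sex, age, count, mortality_rate, morbidity_rate, mean_height,
    mean_weight, bmi_mean, bmi_sd``.  Mortality follows a Gompertz-Makeham
    curve (monotone beyond mid-life), background morbidity rises with age, and
    anthropometry follows smooth growth curves.  A per-sex multiplicative
    jitter (seeded) perturbs levels without breaking monotonicity.
    """
    if max_age < 2:
        raise ValueError("max_age must be at least 2")
    rng = np.random.default_rng(seed)
    ages = np.arange(2, max_age + 1)
    rows = []
    for sex in SEXES:
        jitter = rng.uniform(0.93, 1.07, size=4)  # count, mortality, morbidity, bmi
        count = 2.85e5 * np.exp(-np.clip(ages - 55.0, 0.0, None) ** 2 / 450.0)
        count = np.round(count * jitter[0])

        a, b, c = (2.0e-4, 3.2e-5, 0.088) if sex == "male" else (1.5e-4, 1.8e-5, 0.090)
        mortality = np.clip((a + b * np.exp(c * ages)) * jitter[1], 0.0, 0.7)

        morbidity = np.clip((0.04 + 0.12 * (ages / 100.0) ** 1.8) * jitter[2], 0.0, 0.95)

        adult_height = 1.76 if sex == "male" else 1.62
        height = np.interp(ages, [2, 5, 10, 15, 19, 100],
                           [0.87, 1.09, 1.38, 1.67 if sex == "male" else 1.59,
                            adult_height, adult_height])

        bmi_mean = np.interp(ages, [2, 10, 19, 20, 45, 70, 100],
                             [16.5, 17.8, 22.5, 25.0, 27.8, 28.3, 26.8]) * jitter[3]
        bmi_sd = np.interp(ages, [2, 19, 20, 100], [2.0, 3.2, 4.2, 4.5])
        weight = bmi_mean * height**2

        rows.append(pd.DataFrame({
            "sex": sex, "age": ages, "count": count,
            "mortality_rate": mortality, "morbidity_rate": morbidity,
            "mean_height": height, "mean_weight": weight,
            "bmi_mean": bmi_mean, "bmi_sd": bmi_sd,
        }))
    return pd.concat(rows, ignore_index=True)


# Per-disease shape parameters for the synthetic epidemiology:
# (peak incidence /yr, age of half-maximum, logistic slope, peak case-fatality
#  rate /yr, mean prevalent duration yr, RR per BMI unit (male, female),
#  disability weight, annual cost per prevalent case AUD, sexes affected)
_DISEASE_SHAPES = {
    "ischaemic heart disease": (0.025, 70, 9, 0.12, 10, (1.08, 1.08), 0.08, 8000, SEXES),
    "hypertensive heart disease": (0.006, 75, 9, 0.10, 8, (1.10, 1.10), 0.10, 6000, SEXES),
    "ischemic stroke": (0.015, 78, 9, 0.15, 7, (1.06, 1.06), 0.25, 12000, SEXES),
    "diabetes": (0.012, 60, 12, 0.02, 25, (1.18, 1.18), 0.07, 4000, SEXES),
    "colorectal cancer": (0.004, 72, 10, 0.10, 5, (1.03, 1.03), 0.20, 15000, SEXES),
    "kidney cancer": (0.0012, 70, 10, 0.12, 5, (1.06, 1.06), 0.20, 18000, SEXES),
    "breast cancer": (0.0035, 62, 12, 0.05, 8, (1.0, 1.04), 0.15, 14000, ("female",)),
    "endometrial cancer": (0.0012, 65, 10, 0.06, 6, (1.0, 1.10), 0.15, 13000, ("female",)),
    "osteoarthritis": (0.020, 65, 12, 0.0005, 30, (1.05, 1.05), 0.12, 3000, SEXES),
}


def generate_disease_bundle(seed: int, max_age: int = 100) -> list[DiseaseSpec]:
    """Generate the nine-disease epidemiology bundle.

    Incidence and case fatality follow logistic age curves scaled by seeded
    per-disease jitter; prevalence approximates the quasi-steady state
    incidence x duration.  All incidence rates stay below 0.1/yr.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(2, max_age + 1)
    bundle = []
    for name in DISEASE_NAMES:
        imax, a50, slope, cfmax, duration, rrs, dw, cost, sexes = _DISEASE_SHAPES[name]
        jitter = rng.uniform(0.85, 1.15, size=2)
        frames = []
        for sex in SEXES:
            rr = rrs[0] if sex == "male" else rrs[1]
            if sex in sexes:
                logistic = 1.0 / (1.0 + np.exp(-(ages - a50) / slope))
                sex_scale = 1.0 if sex == "male" else 0.85
                if name == "breast cancer":
                    sex_scale = 1.0
                incidence = np.clip(imax * jitter[0] * sex_scale * logistic, 0.0, 0.099)
                case_fatality = cfmax * jitter[1] * (1.0 / (1.0 + np.exp(-(ages - 80) / 8.0)))
                prevalence = np.clip(incidence * duration / (1.0 + incidence * duration), 0.0, 0.6)
            else:
                incidence = np.zeros_like(ages, dtype=float)
                case_fatality = np.zeros_like(ages, dtype=float)
                prevalence = np.zeros_like(ages, dtype=float)
                rr = 1.0
            frames.append(pd.DataFrame({
                "sex": sex, "age": ages,
                "incidence": incidence, "prevalence": prevalence,
                "case_fatality": case_fatality,
                "remission": np.zeros_like(ages, dtype=float),
                "rr_per_bmi_unit": np.full(ages.shape, rr, dtype=float),
            }))
        rates = pd.concat(frames, ignore_index=True).set_index(["sex", "age"]).sort_index()
        bundle.append(DiseaseSpec(name=name, disability_weight=dw,
                                  annual_cost_per_case=cost, rates=rates))
    return bundle


def generate_consumption(
    seed: int,
    calibrate_to_published: bool = True,
    energy_density: float = DEFAULT_ENERGY_DENSITY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the consumption profile and package-size sales-share table.

    Returns ``(profile, shares)``.  ``profile`` has one row per (sex,
    age_band) with columns ``total_energy, ssb_energy, ssb_volume,
    energy_density`` (kJ/day/person and mL/day/person).  ``shares`` has
    columns ``package_size, single_serve, volume_share`` summing to 1.

    With ``calibrate_to_published`` the profile reproduces the published baseline
    intakes and the share table the published single-serve marginals; without
    it both are drawn around those anchors from the seeded generator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            total = _BASELINE_TOTAL_ENERGY[(sex, band)]
            ssb = _BASELINE_SSB_ENERGY[(sex, band)]
            if not calibrate_to_published:
                total *= rng.uniform(0.9, 1.1)
                ssb = min(ssb * rng.uniform(0.8, 1.2), 0.5 * total)
            rows.append({
                "sex": sex, "age_band": band,
                "total_energy": total, "ssb_energy": ssb,
                "ssb_volume": ssb / energy_density,
                "energy_density": energy_density,
            })
    profile = pd.DataFrame(rows)

    if calibrate_to_published:
        shares = pd.DataFrame(_CALIBRATED_SHARES,
                              columns=["package_size", "single_serve", "volume_share"])
    else:
        raw = rng.dirichlet(np.ones(len(DEFAULT_PACKAGE_SIZES)) * 2.0)
        shares = pd.DataFrame({
            "package_size": DEFAULT_PACKAGE_SIZES,
            "single_serve": [s <= SINGLE_SERVE_MAX_SIZE for s in DEFAULT_PACKAGE_SIZES],
            "volume_share": raw / raw.sum(),
        })
    return profile, shares
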