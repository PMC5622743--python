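"""Input-bundle container, CSV round-tripping and validation.

A bundle holds the four input tables (population, diseases, consumption,
package shares) plus a JSON manifest recording how it was produced.  Files
are plain RFC-4180 CSV with a header row, UTF-8 encoded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .synthetic_data import SEXES, AGE_BANDS, DISEASE_NAMES, DiseaseSpec

FILES = ("population.csv", "diseases.csv", "consumption.csv", "package_shares.csv")


@dataclass
class Bundle:
    population: pd.DataFrame
    diseases: list[DiseaseSpec]
    consumption: pd.DataFrame
    shares: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(directory / "population.csv", index=False)
        disease_rows = []
        for d in self.diseases:
            frame = d.rates.reset_index()
            frame.insert(0, "disease", d.name)
            frame["disability_weight"] = d.disability_weight
            frame["annual_cost_per_case"] = d.annual_cost_per_case
            disease_rows.append(frame)
        pd.concat(disease_rows, ignore_index=True).to_csv(
            directory / "diseases.csv", index=False)
        self.consumption.to_csv(directory / "consumption.csv", index=False)
        self.shares.to_csv(directory / "package_shares.csv", index=False)
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "Bundle":
        directory = Path(directory)
        for name in FILES:
            if not (directory / name).exists():
                raise FileNotFoundError(f"bundle file missing: {directory / name}")
        population = pd.read_csv(directory / "population.csv")
        long = pd.read_csv(directory / "diseases.csv")
        diseases = []
        for name, grp in long.groupby("disease", sort=False):
            diseases.append(DiseaseSpec(
                name=name,
                disability_weight=float(grp["disability_weight"].iloc[0]),
                annual_cost_per_case=float(grp["annual_cost_per_case"].iloc[0]),
                rates=grp.set_index(["sex", "age"])[
                    ["incidence", "prevalence", "case_fatality", "remission",
                     "rr_per_bmi_unit"]].sort_index(),
            ))
        consumption = pd.read_csv(directory / "consumption.csv")
        shares = pd.read_csv(directory / "package_shares.csv")
        manifest_path = directory / "manifest.json"
        manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        return cls(population, diseases, consumption, shares, manifest)


def generate_bundle(seed: int, calibrate_to_published: bool = True,
                    max_age: int = 100) -> Bundle:
    """Generate a complete synthetic input bundle from one seed."""
    root = np.random.SeedSequence(seed)
    pop_seed, dis_seed, cons_seed = (int(s.generate_state(1)[0] % 2**31)
                                     for s in root.spawn(3))
    return Bundle(
        population=sd.generate_population(pop_seed, max_age=max_age),
        diseases=sd.generate_disease_bundle(dis_seed, max_age=max_age),
        consumption=sd.generate_consumption(cons_seed, calibrate_to_published)[0],
        shares=sd.generate_consumption(cons_seed, calibrate_to_published)[1],
        manifest={"seed": seed, "calibrate_to_published": calibrate_to_published,
                  "max_age": max_age},
    )


@dataclass(frozen=True)
class Finding:
    table: str
    message: str
    coords: tuple = ()

    def __str__(self) -> str:
        where = f" at {self.coords}" if self.coords else ""
        return f"[{self.table}] {self.message}{where}"


def validate_bundle(bundle: Bundle) -> list[Finding]:
    """Check all type invariants; an empty list means the bundle is valid."""
    findings: list[Finding] = []
    pop = bundle.population

    dup = pop.duplicated(subset=["sex", "age"])
    if dup.any():
        findings.append(Finding("population", "duplicate (sex, age) strata"))
    for sex in SEXES:
        if sex not in set(pop["sex"]):
            findings.append(Finding("population", f"missing sex {sex!r}"))
    for col, lo, hi in (("mortality_rate", 0, 1), ("morbidity_rate", 0, 1)):
        bad = pop[(pop[col] < lo) | (pop[col] > hi)]
        for rec in bad.itertuples(index=False):
            findings.append(Finding("population", f"{col} out of [{lo},{hi}]",
                                    (rec.sex, rec.age)))
    for col in ("count", "mean_height", "mean_weight", "bmi_mean", "bmi_sd"):
        bad = pop[pop[col] < 0] if col == "count" else pop[pop[col] <= 0]
        for rec in bad.itertuples(index=False):
            findings.append(Finding("population", f"non-positive {col}",
                                    (rec.sex, rec.age)))

    names = [d.name for d in bundle.diseases]
    if sorted(names) != sorted(DISEASE_NAMES):
        findings.append(Finding("diseases",
                                f"expected the nine modelled diseases, got {names}"))
    for d in bundle.diseases:
        rates = d.rates
        for col in ("incidence", "case_fatality", "remission"):
            bad = rates[rates[col] < 0]
            for (sex, age) in bad.index:
                findings.append(Finding("diseases", f"negative {col}",
                                        (d.name, sex, age)))
        bad = rates[(rates["prevalence"] < 0) | (rates["prevalence"] >= 1)]
        for (sex, age) in bad.index:
            findings.append(Finding("diseases", "prevalence out of [0,1)",
                                    (d.name, sex, age)))
        bad = rates[rates["rr_per_bmi_unit"] < 1]
        for (sex, age) in bad.index:
            findings.append(Finding("diseases", "relative risk below 1",
                                    (d.name, sex, age)))

    cons = bundle.consumption
    expected = {(s, b) for s in SEXES for b in AGE_BANDS}
    got = set(zip(cons["sex"], cons["age_band"]))
    if got != expected:
        findings.append(Finding("consumption", f"strata mismatch: {got ^ expected}"))
    bad = cons[cons["ssb_energy"] > cons["total_energy"]]
    for rec in bad.itertuples(index=False):
        findings.append(Finding("consumption", "ssb_energy exceeds total_energy",
                                (rec.sex, rec.age_band)))
    mismatch = ~np.isclose(cons["ssb_energy"],
                           cons["ssb_volume"] * cons["energy_density"], rtol=1e-3)
    for rec in cons[mismatch].itertuples(index=False):
        findings.append(Finding("consumption",
                                "ssb_energy != ssb_volume x energy_density",
                                (rec.sex, rec.age_band)))

    total = float(bundle.shares["volume_share"].sum())
    if not np.isclose(total, 1.0, atol=1e-6):
        findings.append(Finding("package_shares",
                                f"volume shares sum to {total:.6f}, not 1"))
    if (bundle.shares["volume_share"] < 0).any():
        findings.append(Finding("package_shares", "negative volume share"))
    if (bundle.shares["package_size"] <= 0).any():
        findings.append(Finding("package_shares", "non-positive package size"))
    return findings
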