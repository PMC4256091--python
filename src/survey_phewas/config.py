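"""Configuration types for the synthetic two-survey population generator.

A :class:`PopulationConfig` fully determines a synthetic dataset: two
surveys, a set of self-reported race-ethnicity strata, SNPs with
stratum-specific coded-allele frequencies (genotypes drawn from
Hardy-Weinberg proportions), phenotypes with survey-specific raw names
grouped into phenotype classes, planted additive genetic effects (possibly
pleiotropic), latent-factor correlation blocks, and MCAR missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

SURVEYS = ("S1", "S2")

PHENOTYPE_TYPES = ("continuous", "binary", "categorical")


class ConfigError(ValueError):
    """Raised when a population configuration violates its invariants."""


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: coded allele and per-stratum coded-allele frequency."""

    snp_id: str
    chrom: str
    position: int
    coded_allele: str
    other_allele: str
    freq: Mapping[str, float]  # stratum label -> coded-allele frequency

    def validate(self, strata: Sequence[str]) -> None:
        for stratum in strata:
            if stratum not in self.freq:
                raise ConfigError(f"{self.snp_id}: no coded-allele frequency for stratum {stratum!r}")
            f = self.freq[stratum]
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{self.snp_id}: frequency {f} for {stratum!r} outside [0, 1]")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype class member with survey-specific raw names.

    ``shared=True`` means the identical measurement exists in both surveys
    (same raw name), so a combined-survey variable can be built; otherwise
    each survey gets a deterministically suffixed raw name and the class can
    only be analyzed per survey.
    """

    name: str  # base name; raw per-survey names derive from it
    class_label: str
    ptype: str = "continuous"
    baseline: float = 50.0
    noise_sd: float = 10.0
    prevalence: float = 0.3  # binary phenotypes only
    categories: tuple[str, ...] = ()  # categorical phenotypes only
    shared: bool = False

    def validate(self) -> None:
        if self.ptype not in PHENOTYPE_TYPES:
            raise ConfigError(f"{self.name}: unknown phenotype type {self.ptype!r}")
        if self.ptype == "binary" and not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"{self.name}: prevalence must be in (0, 1)")
        if self.ptype == "categorical" and len(self.categories) < 2:
            raise ConfigError(f"{self.name}: categorical phenotype needs >=2 categories")
        if self.noise_sd <= 0 and self.ptype == "continuous":
            raise ConfigError(f"{self.name}: noise SD must be positive")

    def raw_name(self, survey: str) -> str:
        return self.name if self.shared else f"{self.name} ({survey})"


@dataclass(frozen=True)
class PlantedEffect:
    """Additive effect of one SNP on every phenotype of one class.

    ``effect`` is the change in the linear predictor per copy of the coded
    allele (phenotype units for continuous phenotypes, log-odds for binary).
    ``strata`` restricts the effect to a subset of strata; empty means all.
    """

    snp_id: str
    class_label: str
    effect: float
    strata: tuple[str, ...] = ()

    def applies_to(self, stratum: str) -> bool:
        return not self.strata or stratum in self.strata


@dataclass(frozen=True)
class CorrelationBlock:
    """Phenotypes sharing one standard-normal latent factor with a loading."""

    phenotypes: tuple[str, ...]
    loading: float = 0.9


@dataclass
class PopulationConfig:
    strata: tuple[str, ...] = ("NHW", "NHB", "MA")
    n_per_stratum: Mapping[str, Mapping[str, int]] = field(default_factory=dict)  # survey -> stratum -> n
    snps: tuple[SnpSpec, ...] = ()
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    missing_rate: float = 0.0
    pct_female: float = 0.52
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate {self.missing_rate} must lie in [0, 1)")
        if not self.strata:
            raise ConfigError("at least one stratum required")
        for survey in SURVEYS:
            counts = self.n_per_stratum.get(survey)
            if not counts:
                raise ConfigError(f"no sample counts for survey {survey}")
            for stratum in self.strata:
                if counts.get(stratum, 0) <= 0:
                    raise ConfigError(f"sample count for {survey}/{stratum} must be positive")
        snp_ids = set()
        for snp in self.snps:
            snp.validate(self.strata)
            if snp.snp_id in snp_ids:
                raise ConfigError(f"duplicate SNP id {snp.snp_id}")
            snp_ids.add(snp.snp_id)
        classes = set()
        names = set()
        for ph in self.phenotypes:
            ph.validate()
            if ph.name in names:
                raise ConfigError(f"duplicate phenotype name {ph.name}")
            names.add(ph.name)
            classes.add(ph.class_label)
        for eff in self.planted_effects:
            if eff.snp_id not in snp_ids:
                raise ConfigError(f"planted effect names unknown SNP {eff.snp_id}")
            if eff.class_label not in classes:
                raise ConfigError(f"planted effect names unknown class {eff.class_label}")
            for stratum in eff.strata:
                if stratum not in self.strata:
                    raise ConfigError(f"planted effect names unknown stratum {stratum}")
        for block in self.correlation_blocks:
            for name in block.phenotypes:
                if name not in names:
                    raise ConfigError(f"correlation block names unknown phenotype {name}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "strata": list(self.strata),
            "n_per_stratum": {s: dict(v) for s, v in self.n_per_stratum.items()},
            "snps": [
                {
                    "snp_id": s.snp_id,
                    "chrom": s.chrom,
                    "position": s.position,
                    "coded_allele": s.coded_allele,
                    "other_allele": s.other_allele,
                    "freq": dict(s.freq),
                }
                for s in self.snps
            ],
            "phenotypes": [
                {
                    "name": p.name,
                    "class_label": p.class_label,
                    "ptype": p.ptype,
                    "baseline": p.baseline,
                    "noise_sd": p.noise_sd,
                    "prevalence": p.prevalence,
                    "categories": list(p.categories),
                    "shared": p.shared,
                }
                for p in self.phenotypes
            ],
            "planted_effects": [
                {
                    "snp_id": e.snp_id,
                    "class_label": e.class_label,
                    "effect": e.effect,
                    "strata": list(e.strata),
                }
                for e in self.planted_effects
            ],
            "correlation_blocks": [
                {"phenotypes": list(b.phenotypes), "loading": b.loading}
                for b in self.correlation_blocks
            ],
            "missing_rate": self.missing_rate,
            "pct_female": self.pct_female,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationConfig":
        cfg = cls(
            strata=tuple(d.get("strata", ("NHW", "NHB", "MA"))),
            n_per_stratum=d.get("n_per_stratum", {}),
            snps=tuple(
                SnpSpec(
                    snp_id=s["snp_id"],
                    chrom=str(s.get("chrom", "1")),
                    position=int(s.get("position", 1)),
                    coded_allele=s.get("coded_allele", "A"),
                    other_allele=s.get("other_allele", "G"),
                    freq=s["freq"],
                )
                for s in d.get("snps", [])
            ),
            phenotypes=tuple(
                PhenotypeSpec(
                    name=p["name"],
                    class_label=p["class_label"],
                    ptype=p.get("ptype", "continuous"),
                    baseline=float(p.get("baseline", 50.0)),
                    noise_sd=float(p.get("noise_sd", 10.0)),
                    prevalence=float(p.get("prevalence", 0.3)),
                    categories=tuple(p.get("categories", ())),
                    shared=bool(p.get("shared", False)),
                )
                for p in d.get("phenotypes", [])
            ),
            planted_effects=tuple(
                PlantedEffect(
                    snp_id=e["snp_id"],
                    class_label=e["class_label"],
                    effect=float(e["effect"]),
                    strata=tuple(e.get("strata", ())),
                )
                for e in d.get("planted_effects", [])
            ),
            correlation_blocks=tuple(
                CorrelationBlock(phenotypes=tuple(b["phenotypes"]), loading=float(b.get("loading", 0.9)))
                for b in d.get("correlation_blocks", [])
            ),
            missing_rate=float(d.get("missing_rate", 0.0)),
            pct_female=float(d.get("pct_female", 0.52)),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(seed: int = 0) -> PopulationConfig:
    """A reduced-scale two-survey population emulating the study structure.

    Three strata, twelve SNPs with stratum-specific allele frequencies,
    ~40 phenotype measurements in 14 classes (a mix of shared/harmonizable
    and survey-specific names, continuous, binary and categorical types,
    one correlated lipid-like block), three planted effect patterns of which
    two are pleiotropic, and 5% MCAR missingness.
    """
    strata = ("NHW", "NHB", "MA")
    freqs = [0.32, 0.18, 0.45, 0.27, 0.38, 0.22, 0.12, 0.41, 0.30, 0.25, 0.35, 0.15]
    snps = tuple(
        SnpSpec(
            snp_id=f"rs{1000 + i}",
            chrom=str(1 + i % 5),
            position=1_000_000 + 150_000 * i,
            coded_allele="A",
            other_allele="G",
            freq={
                "NHW": min(0.95, f + 0.02),
                "NHB": min(0.95, f + 0.08),
                "MA": f,
            },
        )
        for i, f in enumerate(freqs)
    )
    phenotypes = (
        PhenotypeSpec("Total cholesterol", "Cholesterol", baseline=200.0, noise_sd=35.0, shared=True),
        PhenotypeSpec("Serum cholesterol", "Cholesterol", baseline=5.2, noise_sd=0.9),
        PhenotypeSpec("HDL cholesterol", "HDL Cholesterol", baseline=52.0, noise_sd=14.0, shared=True),
        PhenotypeSpec("Triglycerides", "Triglycerides", baseline=130.0, noise_sd=60.0, shared=True),
        PhenotypeSpec("LDL cholesterol", "LDL Cholesterol", baseline=120.0, noise_sd=30.0),
        PhenotypeSpec("Serum uric acid", "Kidney (Uric Acid)", baseline=5.4, noise_sd=1.3, shared=True),
        PhenotypeSpec("Protoporphyrin", "Protoporphyrin", baseline=45.0, noise_sd=16.0),
        PhenotypeSpec("Serum ferritin", "Ferritin", baseline=110.0, noise_sd=70.0),
        PhenotypeSpec("RBC folate", "Folate", baseline=260.0, noise_sd=95.0),
        PhenotypeSpec("Serum vitamin E", "Vitamin E", baseline=1050.0, noise_sd=320.0),
        PhenotypeSpec("Diastolic blood pressure", "Blood Pressure (Diastolic)", baseline=72.0, noise_sd=11.0, shared=True),
        PhenotypeSpec("White blood cell count", "White Blood Cell", baseline=7.1, noise_sd=2.1, shared=True),
        PhenotypeSpec("Arm circumference", "Body Measurements (Arm)", baseline=31.0, noise_sd=4.5),
        PhenotypeSpec("Thigh circumference", "Body Measurements (Leg)", baseline=51.0, noise_sd=6.0),
        PhenotypeSpec("Diabetes diagnosis", "Diabetes", ptype="binary", prevalence=0.09, shared=True),
        PhenotypeSpec("High blood pressure diagnosis", "High blood pressure", ptype="binary", prevalence=0.25),
        PhenotypeSpec(
            "Smoking status",
            "Smoking",
            ptype="categorical",
            categories=("never", "former", "current"),
            shared=True,
        ),
    )
    planted = (
        # pleiotropic lipid SNP: cholesterol + triglycerides in NHW and MA
        PlantedEffect("rs1000", "Cholesterol", effect=0.35, strata=("NHW", "MA")),
        PlantedEffect("rs1000", "Triglycerides", effect=0.30, strata=("NHW", "MA")),
        # pleiotropic urate SNP: uric acid (all strata) + protoporphyrin (NHW)
        PlantedEffect("rs1002", "Kidney (Uric Acid)", effect=-0.30),
        PlantedEffect("rs1002", "Protoporphyrin", effect=-0.30, strata=("NHW",)),
        # single-class SNP
        PlantedEffect("rs1004", "HDL Cholesterol", effect=0.25, strata=("NHW",)),
        # binary effect (log-odds per allele)
        PlantedEffect("rs1005", "Diabetes", effect=0.35),
    )
    blocks = (
        # unit noise variance: pairwise r = loading^2/(loading^2+1), so 1.4
        # puts the cholesterol measures above the 0.6 reporting screen
        CorrelationBlock(("Total cholesterol", "LDL cholesterol", "Serum cholesterol"), loading=1.4),
        CorrelationBlock(("Serum ferritin", "Protoporphyrin"), loading=0.4),
    )
    n = {"S1": {"NHW": 1200, "NHB": 1200, "MA": 1200}, "S2": {"NHW": 1200, "NHB": 1200, "MA": 1200}}
    cfg = PopulationConfig(
        strata=strata,
        n_per_stratum=n,
        snps=snps,
        phenotypes=phenotypes,
        planted_effects=planted,
        correlation_blocks=blocks,
        missing_rate=0.05,
        seed=seed,
    )
    cfg.validate()
    return cfg
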