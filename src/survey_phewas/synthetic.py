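"""Synthetic two-survey genotype/phenotype generator with planted effects.

Genotypes are drawn per stratum from Hardy-Weinberg proportions at the
stratum's coded-allele frequency.  Continuous phenotypes follow an additive
mean model

    y = baseline + noise_sd * (sum_k effect_k * g_k + loading * F + eps),

with ``F`` a standard-normal latent factor shared within a correlation
block and ``eps`` standard normal, so a planted ``effect`` is the shift per
coded-allele copy in units of the phenotype's noise SD.  Binary phenotypes
use a logistic link on the same standardized linear predictor with the
intercept set to hit the configured prevalence.  Missingness is applied
completely at random, independently per cell.  A single global seed is
expanded into independent per-component streams (genotypes, phenotype
noise, missingness, demographics) so each component is reproducible on its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SURVEYS, ConfigError, PopulationConfig

_STREAMS = ("genotypes", "phenotypes", "missingness", "demographics")


def _rngs(config: PopulationConfig) -> dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(seq) for name, seq in zip(_STREAMS, seqs)}


@dataclass
class SyntheticDataset:
    """Everything one synthetic run produces.

    ``genotypes``/``phenotypes`` map survey id to a wide DataFrame indexed by
    sample id with a ``stratum`` (and for phenotypes a ``sex``) column ahead
    of the data columns.  ``truth`` is the planted-effect ground truth,
    ``class_map`` the survey/raw-name/class-label table, and ``pheno_meta``
    per-survey measurement metadata (raw name, class, type).
    """

    config: PopulationConfig
    genotypes: dict[str, pd.DataFrame]
    phenotypes: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    class_map: pd.DataFrame = field(default_factory=pd.DataFrame)
    pheno_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for survey in SURVEYS:
            self.genotypes[survey].to_csv(outdir / f"genotypes_{survey}.tsv", sep="\t")
            self.phenotypes[survey].to_csv(outdir / f"phenotypes_{survey}.tsv", sep="\t")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.class_map.to_csv(outdir / "class_map.tsv", sep="\t", index=False)
        self.pheno_meta.to_csv(outdir / "pheno_meta.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def generate_genotypes(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Sample genotype tables (one per survey) under Hardy-Weinberg equilibrium.

    Each table is indexed by sample id with a ``stratum`` column followed by
    one float column per SNP holding coded-allele dosages in {0, 1, 2} (NaN
    once missingness is applied downstream).
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)["genotypes"]
    tables = {}
    for survey in SURVEYS:
        frames = []
        for stratum in config.strata:
            n = config.n_per_stratum[survey][stratum]
            ids = [f"{survey}_{stratum}_{i:06d}" for i in range(n)]
            data = {"stratum": [stratum] * n}
            for snp in config.snps:
                f = snp.freq[stratum]
                # HWE: genotype = sum of two independent allele draws
                data[snp.snp_id] = rng.binomial(1, f, size=n) + rng.binomial(1, f, size=n)
            frames.append(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))
        table = pd.concat(frames)
        snp_cols = [s.snp_id for s in config.snps]
        table[snp_cols] = table[snp_cols].astype(float)
        tables[survey] = table
    return tables


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_phenotypes(
    config: PopulationConfig,
    genotypes: Mapping[str, pd.DataFrame],
    rngs: Mapping[str, np.random.Generator] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate phenotype tables per survey plus the planted-effect truth table.

    Returns ``(phenotypes, truth)``; ``truth`` has one row per planted effect
    per applicable stratum: (snp, class_label, stratum, effect, sign).
    """
    config.validate()
    if rngs is None:
        r = _rngs(config)
        rngs = {"phenotypes": r["phenotypes"], "missingness": r["missingness"], "demographics": r["demographics"]}
    noise_rng = rngs["phenotypes"]
    miss_rng = rngs["missingness"]
    demo_rng = rngs["demographics"]

    effects_by_class: dict[str, list] = {}
    for eff in config.planted_effects:
        effects_by_class.setdefault(eff.class_label, []).append(eff)

    # latent-factor loading per phenotype name
    loading: dict[str, float] = {}
    block_of: dict[str, int] = {}
    for b_idx, block in enumerate(config.correlation_blocks):
        for name in block.phenotypes:
            loading[name] = block.loading
            block_of[name] = b_idx

    tables: dict[str, pd.DataFrame] = {}
    for survey in SURVEYS:
        geno = genotypes[survey]
        cols: dict[str, np.ndarray | pd.Series] = {"stratum": geno["stratum"].to_numpy()}
        n_total = len(geno)
        sex = np.where(demo_rng.random(n_total) < config.pct_female, "F", "M")
        cols["sex"] = sex

        # one latent factor draw per (block, sample)
        factors = noise_rng.standard_normal((len(config.correlation_blocks), n_total))

        stratum_arr = geno["stratum"].to_numpy()
        for ph in config.phenotypes:
            # standardized genetic predictor: sum of effect * dosage, stratum-gated
            predictor = np.zeros(n_total)
            for eff in effects_by_class.get(ph.class_label, []):
                g = geno[eff.snp_id].to_numpy(dtype=float)
                g = np.nan_to_num(g)  # genotypes have no missingness at this point
                mask = np.isin(stratum_arr, eff.strata) if eff.strata else np.ones(n_total, bool)
                predictor += np.where(mask, eff.effect * g, 0.0)
            lam = loading.get(ph.name, 0.0)
            if lam:
                predictor = predictor + lam * factors[block_of[ph.name]]

            raw = ph.raw_name(survey)
            if ph.ptype == "continuous":
                z = predictor + noise_rng.standard_normal(n_total)
                # assay floor: biomarker measurements cannot go negative
                cols[raw] = np.clip(ph.baseline + ph.noise_sd * z, 0.0, None)
            elif ph.ptype == "binary":
                alpha = np.log(ph.prevalence / (1.0 - ph.prevalence))
                # center the predictor so the configured prevalence is hit on average
                centered = predictor - predictor.mean()
                cols[raw] = (noise_rng.random(n_total) < _sigmoid(alpha + centered)).astype(float)
            elif ph.ptype == "categorical":
                k = len(ph.categories)
                cols[raw] = np.asarray(ph.categories, dtype=object)[demo_rng.integers(0, k, size=n_total)]
            else:  # pragma: no cover - guarded by validate()
                raise ConfigError(f"unknown phenotype type {ph.ptype!r}")
        table = pd.DataFrame(cols, index=geno.index.copy())

        # MCAR missingness, independent per cell, phenotype data columns only
        if config.missing_rate > 0:
            data_cols = [c for c in table.columns if c not in ("stratum", "sex")]
            mask = miss_rng.random((n_total, len(data_cols))) < config.missing_rate
            for j, c in enumerate(data_cols):
                col = table[c]
                if col.dtype == object:
                    col = col.where(~mask[:, j], other=None)
                else:
                    col = col.mask(mask[:, j])
                table[c] = col
        tables[survey] = table

    truth_rows = []
    for eff in config.planted_effects:
        strata = eff.strata or config.strata
        for stratum in strata:
            truth_rows.append(
                {
                    "snp": eff.snp_id,
                    "class_label": eff.class_label,
                    "stratum": stratum,
                    "effect": eff.effect,
                    "sign": "+" if eff.effect > 0 else ("-" if eff.effect < 0 else "0"),
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["snp", "class_label", "stratum", "effect", "sign"])
    return tables, truth


def build_class_map(config: PopulationConfig) -> pd.DataFrame:
    """Survey / raw phenotype name / class label table for harmonization."""
    rows = [
        {"survey": survey, "phenotype": ph.raw_name(survey), "class_label": ph.class_label}
        for survey in SURVEYS
        for ph in config.phenotypes
    ]
    return pd.DataFrame(rows, columns=["survey", "phenotype", "class_label"])


def build_pheno_meta(config: PopulationConfig) -> pd.DataFrame:
    rows = [
        {
            "survey": survey,
            "phenotype": ph.raw_name(survey),
            "class_label": ph.class_label,
            "ptype": ph.ptype,
            "shared": ph.shared,
        }
        for survey in SURVEYS
        for ph in config.phenotypes
    ]
    return pd.DataFrame(rows, columns=["survey", "phenotype", "class_label", "ptype", "shared"])


def generate_dataset(config: PopulationConfig) -> SyntheticDataset:
    """Run the full generator under the config's seed."""
    config.validate()
    rngs = _rngs(config)
    genotypes = generate_genotypes(config, rngs["genotypes"])
    # apply genotype missingness after phenotype generation uses clean dosages;
    # planted effects act on the true genotype, missingness only hides it
    phenotypes, truth = generate_phenotypes(config, genotypes, rngs)
    if config.missing_rate > 0:
        miss_rng = rngs["missingness"]
        for survey in SURVEYS:
            geno = genotypes[survey]
            snp_cols = [s.snp_id for s in config.snps]
            mask = miss_rng.random((len(geno), len(snp_cols))) < config.missing_rate
            block = geno[snp_cols].to_numpy(dtype=float)
            block[mask] = np.nan
            geno[snp_cols] = block
    return SyntheticDataset(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        truth=truth,
        class_map=build_class_map(config),
        pheno_meta=build_pheno_meta(config),
    )


def write_minimal_vcf(dataset: SyntheticDataset, survey: str, path: str | Path) -> None:
    """Write one survey's genotypes as a minimal uncompressed VCF (GT only)."""
    config = dataset.config
    geno = dataset.genotypes[survey]
    samples = list(geno.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for snp in sorted(config.snps, key=lambda s: (s.chrom, s.position)):
        dosages = geno[snp.snp_id].to_numpy(dtype=float)
        gts = ["./." if np.isnan(d) else gt_code[d] for d in dosages]
        # ALT is the coded allele so dosage counts ALT copies
        lines.append(
            f"{snp.chrom}\t{snp.position}\t{snp.snp_id}\t{snp.other_allele}\t{snp.coded_allele}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def null_scan_tables(
    n_snps: int,
    n_measurements: int,
    n_per_stratum: int,
    strata: tuple[str, ...] = ("A", "B"),
    freq: float = 0.3,
    seed: int = 0,
):
    """Two-survey null inputs at scan scale: HWE genotypes, pure-noise phenotypes.

    One continuous measurement per phenotype class, no planted effects and no
    missingness — the calibration bed for scan p-value uniformity and the
    replication filter's null pass rate.  Returns ``(genotypes, measurements)``
    keyed by survey, ready for :func:`survey_phewas.scan.run_scan`.
    """
    from .harmonize import MeasurementSet  # local import avoids a cycle at module load

    rng = np.random.default_rng(seed)
    snp_cols = [f"rs{j}" for j in range(n_snps)]
    meas_cols = [f"ph{j}" for j in range(n_measurements)]
    genotypes: dict[str, pd.DataFrame] = {}
    measurements: dict[str, MeasurementSet] = {}
    for survey in SURVEYS:
        geno_frames, pheno_frames = [], []
        for stratum in strata:
            ids = [f"{survey}_{stratum}_{i:06d}" for i in range(n_per_stratum)]
            geno = pd.DataFrame(
                rng.binomial(2, freq, size=(n_per_stratum, n_snps)).astype(float),
                index=pd.Index(ids, name="sample_id"),
                columns=snp_cols,
            )
            geno.insert(0, "stratum", stratum)
            pheno = pd.DataFrame(
                rng.standard_normal((n_per_stratum, n_measurements)),
                index=geno.index,
                columns=meas_cols,
            )
            pheno.insert(0, "stratum", stratum)
            geno_frames.append(geno)
            pheno_frames.append(pheno)
        geno = pd.concat(geno_frames)
        pheno = pd.concat(pheno_frames)
        meta = pd.DataFrame(
            {
                "measurement": meas_cols,
                "phenotype": meas_cols,
                "transform": "none",
                "class_label": meas_cols,
                "ptype": "continuous",
            }
        )
        genotypes[survey] = geno
        measurements[survey] = MeasurementSet(
            survey=survey,
            values=pheno[meas_cols],
            meta=meta,
            strata=pheno["stratum"],
        )
    return genotypes, measurements


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp": str, "class_label": str, "stratum": str, "sign": str})
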