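"""Synthetic case-control cohorts with the structure the pipeline assumes.

No individual-level data accompany the study design this package implements,
so every downstream stage is exercised on simulated cohorts that reproduce
its statistical structure:

* carrier status per gene drawn under a dominant single-carrier model with
  control frequency ``f`` (of order 0.05-0.5%, the range seen for candidate
  cancer-susceptibility genes) and case frequency ``f*OR / (1 + f*(OR-1))``;
* country-like strata that may differ in baseline frequency and in
  case:control ratio, which induces confounding of the crude odds ratio;
* read evidence (depth, alternate allele fraction, amplicon count, chip
  flag) around the genotype-acceptance thresholds, with overdispersed
  negative-binomial depth and beta-binomial allele counts;
* annotation fields (consequence, ClinVar class, splice scores, SIFT /
  PolyPhen-2 / PROVEAN) that exercise every classification rule, plus rare
  missense variants for the admixture-likelihood test.

One RNG is seeded per bundle; per-gene sub-streams are derived from the seed
and a stable hash of the gene name so edits to the gene list do not perturb
other genes' draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

_DELETERIOUS_TEMPLATES = (
    # (consequence, clinvar, mes_ref, mes_alt, distance, side) cycling per gene
    ("nonsense", "absent", None, None, None, None),
    ("frameshift_indel", "absent", None, None, None, None),
    ("canonical_splice_site", "absent", None, None, None, None),
    ("missense", "pathogenic", None, None, None, None),
    ("missense", "absent", 8.0, 3.0, 2.0, "donor"),  # splice-disrupting exonic SNV
    ("start_loss", "absent", None, None, None, None),
)


@dataclass
class GeneSpec:
    """One simulated gene: control carrier frequency and true odds ratio."""

    name: str
    control_freq: float
    odds_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_freq <= 0.5):
            raise ConfigError(
                f"gene {self.name}: control_freq must be in [0, 0.5], got {self.control_freq}"
            )
        if self.odds_ratio <= 0:
            raise ConfigError(
                f"gene {self.name}: odds_ratio must be positive, got {self.odds_ratio}"
            )


@dataclass
class StratumSpec:
    """One country-like stratum: its sample sizes and baseline-frequency multiplier."""

    label: str
    n_cases: int
    n_controls: int
    freq_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError(f"stratum {self.label}: counts must be >= 0")
        if self.freq_multiplier < 0:
            raise ConfigError(f"stratum {self.label}: freq_multiplier must be >= 0")


@dataclass
class ReadModel:
    """Generative model for per-call read evidence.

    Depth is negative binomial with the given mean and size (dispersion)
    parameter; the heterozygote alt fraction is beta-binomial with
    concentration ``het_alt_concentration`` centred at 0.5.  ``chip_rate`` is
    the probability a call also has an orthogonal chip genotype and
    ``extra_amplicon_rate`` the probability it appears on >1 amplicon.
    Defaults reflect a deep targeted amplicon panel (mean depth ~200).
    """

    mean_depth: float = 200.0
    depth_dispersion: float = 50.0
    het_alt_concentration: float = 50.0
    chip_rate: float = 0.0
    extra_amplicon_rate: float = 0.10
    error_rate: float = 0.005  # alt-read rate at non-carrier sites

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("read model: depth parameters must be positive")
        if not (0 <= self.chip_rate <= 1) or not (0 <= self.extra_amplicon_rate <= 1):
            raise ConfigError("read model: rates must be probabilities")


@dataclass
class SimConfig:
    """Full simulation design: strata, genes, read model, missense layer."""

    strata: list[StratumSpec]
    genes: list[GeneSpec]
    read_model: ReadModel = field(default_factory=ReadModel)
    platform: str = "TS"
    n_missense_per_gene: int = 0
    missense_damaging_fraction: float = 0.5
    missense_maf_range: tuple[float, float] = (0.0005, 0.005)
    missense_or: float = 1.0
    missense_assoc_fraction: float = 0.0
    hgsoc_fraction: float = 0.932
    coverage_beta: tuple[float, float] = (60.0, 3.0)  # frac_target_at_15x ~ Beta
    seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in ("TS", "ES", "CHIP"):
            raise ConfigError(f"platform must be TS|ES|CHIP, got {self.platform!r}")
        if self.n_missense_per_gene < 0:
            raise ConfigError("n_missense_per_gene must be >= 0")
        if not (0 <= self.missense_damaging_fraction <= 1):
            raise ConfigError("missense_damaging_fraction must be in [0, 1]")
        if not (0 <= self.missense_assoc_fraction <= 1):
            raise ConfigError("missense_assoc_fraction must be in [0, 1]")
        if self.missense_or <= 0:
            raise ConfigError("missense_or must be positive")
        for g in self.genes:
            for s in self.strata:
                if g.control_freq * s.freq_multiplier > 0.5:
                    raise ConfigError(
                        f"gene {g.name} x stratum {s.label}: scaled frequency exceeds 0.5"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        kwargs["strata"] = [StratumSpec(**s) for s in raw["strata"]]
        kwargs["genes"] = [GeneSpec(**g) for g in raw.get("genes", [])]
        if "read_model" in raw:
            kwargs["read_model"] = ReadModel(**raw["read_model"])
        for key in ("missense_maf_range", "coverage_beta"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, mutually consistent."""

    manifest: pd.DataFrame  # sample_id, status, histotype, stratum, platform, frac_target_at_15x
    variants: pd.DataFrame  # VariantAnnotation columns
    genotypes: pd.DataFrame  # long: sample_id, variant_id, gt (non-reference rows only)
    evidence: pd.DataFrame  # sample_id, variant_id, depth, alt_reads, n_amplicons, chip_genotype_available
    truth: dict  # per-gene true OR and control frequency

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        self.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        self.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, indir: str | Path) -> "CohortBundle":
        indir = Path(indir)
        return cls(
            manifest=pd.read_csv(indir / "manifest.csv"),
            variants=pd.read_csv(indir / "variants.tsv", sep="\t"),
            genotypes=pd.read_csv(indir / "genotypes.tsv", sep="\t"),
            evidence=pd.read_csv(indir / "evidence.tsv", sep="\t"),
            truth=json.loads((indir / "truth.json").read_text()),
        )


def case_freq(f: float, or_: float) -> float:
    """Carrier frequency among cases implied by control frequency and OR."""
    return f * or_ / (1.0 + f * (or_ - 1.0))


def _gene_rng(seed: int, gene: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(gene.encode()), salt])


def _deleterious_variants_for_gene(gene: str, n: int = 6) -> pd.DataFrame:
    rows = []
    for i in range(n):
        cons, clin, mes_r, mes_a, dist, side = _DELETERIOUS_TEMPLATES[
            i % len(_DELETERIOUS_TEMPLATES)
        ]
        rows.append(
            {
                "variant_id": f"{gene}_del{i}",
                "gene": gene,
                "chrom": "1",
                "pos": 1000 + i,
                "ref": "A" if cons != "frameshift_indel" else "AT",
                "alt": "T" if cons != "frameshift_indel" else "A",
                "consequence": cons,
                "clinvar_class": clin,
                "mes_ref": mes_r,
                "mes_alt": mes_a,
                "distance_to_boundary": dist,
                "boundary_side": side,
                "maf": 0.001,
                "sift": None,
                "polyphen": None,
                "provean": None,
                "call_rate": 1.0,
            }
        )
    return pd.DataFrame(rows)


def _missense_variants_for_gene(
    gene: str, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_missense_per_gene
    lo, hi = config.missense_maf_range
    mafs = rng.uniform(lo, hi, size=n)
    damaging = rng.random(n) < config.missense_damaging_fraction
    associated = rng.random(n) < config.missense_assoc_fraction
    rows = []
    for i in range(n):
        if damaging[i]:
            sift, pph, prov = rng.uniform(0.0, 0.04), "probably_damaging", rng.uniform(-6, -2.6)
        else:
            sift, pph, prov = rng.uniform(0.1, 0.9), "benign", rng.uniform(-2.0, 1.0)
        rows.append(
            {
                "variant_id": f"{gene}_mis{i}",
                "gene": gene,
                "chrom": "1",
                "pos": 2000 + i,
                "ref": "G",
                "alt": "C",
                "consequence": "missense",
                "clinvar_class": "absent",
                "mes_ref": None,
                "mes_alt": None,
                "distance_to_boundary": None,
                "boundary_side": None,
                "maf": float(mafs[i]),
                "sift": float(sift),
                "polyphen": pph,
                "provean": float(prov),
                "call_rate": 1.0,
                "_associated": bool(associated[i]),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Draw one cohort bundle under the configured design.

    Carrier status is drawn per gene per sample; a carrier is assigned one of
    the gene's deleterious variants uniformly (genotype 1, the dominant
    single-carrier model).  Rare missense genotypes are drawn per variant at
    Hardy-Weinberg given the allele frequency, with allele-frequency
    enrichment in cases for the configured associated fraction.
    """
    rng = np.random.default_rng(config.seed)

    # -- manifest ----------------------------------------------------------
    rows = []
    for s in config.strata:
        for i in range(s.n_cases):
            rows.append((f"{s.label}_case{i}", "case", s.label))
        for i in range(s.n_controls):
            rows.append((f"{s.label}_ctrl{i}", "control", s.label))
    manifest = pd.DataFrame(rows, columns=["sample_id", "status", "stratum"])
    manifest["platform"] = config.platform
    is_case = (manifest["status"] == "case").to_numpy()
    histo = np.where(
        is_case,
        np.where(rng.random(len(manifest)) < config.hgsoc_fraction, "HGSOC", "other-EOC"),
        "NA",
    )
    manifest["histotype"] = histo
    a0, b0 = config.coverage_beta
    manifest["frac_target_at_15x"] = np.round(rng.beta(a0, b0, size=len(manifest)), 6)

    # -- variants ----------------------------------------------------------
    var_frames, truth_genes = [], {}
    for g in config.genes:
        var_frames.append(_deleterious_variants_for_gene(g.name))
        if config.n_missense_per_gene:
            var_frames.append(
                _missense_variants_for_gene(g.name, config, _gene_rng(config.seed, g.name, 1))
            )
        truth_genes[g.name] = {"control_freq": g.control_freq, "odds_ratio": g.odds_ratio}
    columns = [
        "variant_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
        "clinvar_class", "mes_ref", "mes_alt", "distance_to_boundary",
        "boundary_side", "maf", "sift", "polyphen", "provean", "call_rate",
        "_associated",
    ]
    if var_frames:
        records = [rec for frame in var_frames for rec in frame.to_dict("records")]
        variants = pd.DataFrame.from_records(records, columns=columns)
        if variants["_associated"].isna().all():
            variants = variants.drop(columns=["_associated"])
        else:
            variants["_associated"] = [
                bool(v) if v is not None and v == v else False
                for v in variants["_associated"]
            ]
    else:
        variants = pd.DataFrame(columns=columns[:-1])

    # -- genotypes ---------------------------------------------------------
    strat_arr = manifest["stratum"].to_numpy()
    gt_rows: list[tuple[str, str, int]] = []
    sample_ids = manifest["sample_id"].to_numpy()
    for g in config.genes:
        grng = _gene_rng(config.seed, g.name)
        p = np.empty(len(manifest))
        for s in config.strata:
            f_s = min(g.control_freq * s.freq_multiplier, 0.5)
            in_s = strat_arr == s.label
            p[in_s & ~is_case] = f_s
            p[in_s & is_case] = case_freq(f_s, g.odds_ratio)
        carrier = grng.random(len(manifest)) < p
        del_ids = [v for v in variants.loc[variants["gene"] == g.name, "variant_id"]
                   if "_del" in v]
        which = grng.integers(0, len(del_ids), size=int(carrier.sum()))
        for sid, w in zip(sample_ids[carrier], which):
            gt_rows.append((sid, del_ids[w], 1))

        if config.n_missense_per_gene:
            mrng = _gene_rng(config.seed, g.name, 2)
            mis = variants[(variants["gene"] == g.name) & (variants["consequence"] == "missense")]
            for _, mv in mis.iterrows():
                q0 = mv["maf"]
                q1 = (
                    q0 * config.missense_or / (1 + q0 * (config.missense_or - 1))
                    if mv.get("_associated", False)
                    else q0
                )
                q = np.where(is_case, q1, q0)
                gts = mrng.binomial(2, q)
                for sid, gt in zip(sample_ids[gts > 0], gts[gts > 0]):
                    gt_rows.append((sid, mv["variant_id"], int(gt)))

    genotypes = pd.DataFrame(gt_rows, columns=["sample_id", "variant_id", "gt"])
    if "_associated" in variants.columns:
        truth_missense = {
            r["variant_id"]: bool(r["_associated"])
            for _, r in variants.iterrows()
            if r["consequence"] == "missense"
        }
        variants = variants.drop(columns=["_associated"])
    else:
        truth_missense = {}

    evidence = simulate_read_evidence(
        genotypes, config.read_model, seed=int(np.random.default_rng(config.seed).integers(2**31))
    )

    truth = {
        "genes": truth_genes,
        "missense_associated": truth_missense,
        "missense_or": config.missense_or,
        "seed": config.seed,
    }
    return CohortBundle(manifest, variants, genotypes, evidence, truth)


def simulate_read_evidence(
    genotypes: pd.DataFrame, read_model: ReadModel, seed: int = 0
) -> pd.DataFrame:
    """Read evidence for every genotype row under the stated generative model.

    Depth ~ NegativeBinomial(mean, size); heterozygote alt fraction ~
    Beta(kappa/2, kappa/2) compounded with the depth (beta-binomial);
    homozygote-alt sites centre near 1 and reference sites (gt=0, if any are
    present in the table) near the sequencing error rate.
    """
    rng = np.random.default_rng(seed)
    rm = read_model
    n = len(genotypes)
    size = rm.depth_dispersion
    depth = rng.negative_binomial(size, size / (size + rm.mean_depth), size=n)
    gt = genotypes["gt"].to_numpy() if n else np.array([], dtype=int)
    kappa = rm.het_alt_concentration
    p_alt = np.empty(n)
    het = gt == 1
    hom = gt >= 2
    ref = gt == 0
    p_alt[het] = rng.beta(kappa / 2, kappa / 2, size=int(het.sum()))
    p_alt[hom] = rng.beta(0.98 * kappa, 0.02 * kappa, size=int(hom.sum()))
    p_alt[ref] = rm.error_rate
    alt_reads = rng.binomial(depth, p_alt) if n else np.array([], dtype=int)
    evidence = pd.DataFrame(
        {
            "sample_id": genotypes["sample_id"].to_numpy() if n else [],
            "variant_id": genotypes["variant_id"].to_numpy() if n else [],
            "depth": depth,
            "alt_reads": alt_reads,
            "n_amplicons": 1 + rng.binomial(1, rm.extra_amplicon_rate, size=n),
            "chip_genotype_available": rng.random(n) < rm.chip_rate,
        }
    )
    return evidence
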