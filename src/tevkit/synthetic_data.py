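"""Seeded synthetic cohorts, TEV catalogs, annotations and RNA-seq call tables.

The generator emulates the structure of the real inputs the pipeline was
designed for: a cohort of 445 individuals from 5 populations with sex and
population covariates, a TEV catalog dominated by Alu elements with a rare
tail below 5% MAF and a fraction of deletion-coded records, RPKM-scale
expression with additive per-allele cis effects planted at known (variant,
gene) pairs, and jittered RNA-seq insertion calls with configurable true-
and false-positive behaviour.  Everything is deterministic given the seed
and is written in exactly the formats :mod:`tevkit.io_catalog` reads, so the
whole pipeline is testable without any download.

Ground truth (planted effects, transcribed variants, call labels) is
returned alongside the data and stored in the fixture bundle as JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_catalog import (
    CytoBand, ExpressionMatrix, GeneModel, SampleInfo, TevVariant,
    write_bed, write_cytobands, write_expression, write_gene_annotation,
    write_sample_info, write_tev_vcf,
)


class ConfigError(ValueError):
    """A simulation configuration violates its own constraints."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the design
    of the cohort the pipeline targets (445 LCL donors, 5 populations,
    Alu-dominated catalog extending below 5% MAF down to a 3-carrier floor).

    Variant counts default to a 1:15 scale-down of the real catalog's class
    composition so the default bundle stays fast to generate and scan.
    """

    n_samples: int = 445
    populations: tuple[str, ...] = ("CEU", "FIN", "GBR", "TSI", "YRI")
    population_proportions: tuple[float, ...] = (0.2, 0.21, 0.2, 0.2, 0.19)
    # per-class variant counts (Alu, L1, SVA); real ratio ~ 9605:1430:544
    n_alu: int = 640
    n_l1: int = 95
    n_sva: int = 36
    # MAF spectrum: mixture of a rare tail and a common component
    rare_fraction: float = 0.45          # fraction of variants below maf_common_min
    maf_floor: Optional[float] = None    # default: the 3-carrier floor, 1.5/n
    maf_common_min: float = 0.05
    maf_common_max: float = 0.5
    deletion_fraction: float = 0.15      # ~1291 of 8551 records are *_DEL
    missing_rate: float = 0.0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {
        "chr1": 60_000_000, "chr2": 45_000_000, "chr3": 30_000_000})
    n_genes: int = 300
    n_bands_per_chrom: int = 8
    regulatory_coverage: float = 0.08
    # planted cis effects
    n_planted: int = 20
    effect_size: float = 1.5             # expression units per presence allele
    planted_min_maf: float = 0.05        # plant only on common variants
    # covariates and noise
    sex_effect_sd: float = 0.5
    population_effect_sd: float = 0.5
    noise_sd: float = 1.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 0.7
    log2_expression: bool = False        # simulate/fit on log2(x+1) scale
    # RNA-seq insertion calls
    n_transcribed: int = 25
    rna_tp_rate: float = 0.9
    rna_jitter_bp: int = 25              # strict bound; must stay < 50
    n_false_calls: int = 25
    seed: int = 2019

    def __post_init__(self) -> None:
        if len(self.populations) != len(self.population_proportions):
            raise ConfigError("population labels and proportions differ in length")
        if abs(sum(self.population_proportions) - 1.0) > 1e-9:
            raise ConfigError("population proportions must sum to 1")
        if min(self.n_alu, self.n_l1, self.n_sva, self.n_genes, self.n_samples) < 0:
            raise ConfigError("counts must be non-negative")
        if not 0.0 <= self.rna_tp_rate <= 1.0:
            raise ConfigError("rna_tp_rate outside [0, 1]")
        if self.maf_floor is None:
            self.maf_floor = 1.5 / max(self.n_samples, 1)
        if self.maf_floor < 1.0 / (2 * self.n_samples):
            raise ConfigError("maf_floor below 1/(2n): rarest variant unobservable")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> list[SampleInfo]:
    """Draw sex and population labels for ``n_samples`` individuals."""
    if len(config.populations) < 2 and config.population_effect_sd > 0:
        raise ConfigError("population covariates need at least 2 populations")
    rng = config.stage_rng("cohort")
    pops = rng.choice(config.populations, size=config.n_samples,
                      p=config.population_proportions)
    sexes = rng.choice(["male", "female"], size=config.n_samples)
    return [SampleInfo(f"S{i:04d}", sexes[i], str(pops[i]))
            for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# TEV catalog
# ---------------------------------------------------------------------------

_CLASS_LENGTH_RANGE = {"Alu": (250, 350), "L1": (400, 6000), "SVA": (700, 3000)}


def _draw_mafs(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    rare = rng.random(n) < config.rare_fraction
    mafs = np.empty(n)
    mafs[rare] = rng.uniform(config.maf_floor, config.maf_common_min, rare.sum())
    # log-uniform over the common range, matching the decay of real site
    # frequency spectra better than a flat draw
    lo, hi = np.log(config.maf_common_min), np.log(config.maf_common_max)
    mafs[~rare] = np.exp(rng.uniform(lo, hi, (~rare).sum()))
    return mafs


def simulate_tevs(config: SimulationConfig,
                  cohort: Sequence[SampleInfo]) -> list[TevVariant]:
    """Simulate the TEV catalog: positions uniform per chromosome
    (chromosome chosen proportional to length), Hardy-Weinberg genotypes at
    each variant's MAF, equal-probability strands, and a configured fraction
    of deletion-coded records."""
    if min(config.chrom_sizes.values()) <= 0:
        raise ConfigError("chromosome sizes must be positive")
    rng = config.stage_rng("tevs")
    n_samples = len(cohort)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    counts = {"Alu": config.n_alu, "L1": config.n_l1, "SVA": config.n_sva}

    variants: list[TevVariant] = []
    idx = 0
    for te_class, n in counts.items():
        mafs = _draw_mafs(rng, n, config)
        chrom_idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
        lo, hi = _CLASS_LENGTH_RANGE[te_class]
        for k in range(n):
            chrom = chroms[chrom_idx[k]]
            length = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(1, config.chrom_sizes[chrom] - length))
            # HWE: dosage = sum of two Bernoulli(maf) alleles
            dosages = rng.binomial(2, mafs[k], size=n_samples).astype(float)
            if config.missing_rate > 0:
                dosages[rng.random(n_samples) < config.missing_rate] = np.nan
            variants.append(TevVariant(
                variant_id=f"tev{idx:05d}", chrom=chrom, pos=pos,
                te_class=te_class,
                strand="+" if rng.random() < 0.5 else "-",
                deletion_coded=bool(rng.random() < config.deletion_fraction),
                length=length, dosages=dosages))
            idx += 1
    variants.sort(key=lambda v: (v.chrom, v.pos, v.variant_id))
    return variants


# ---------------------------------------------------------------------------
# Gene models, bands, regulatory features
# ---------------------------------------------------------------------------

_BIOTYPES = ("protein_coding", "pseudogene", "lincRNA", "antisense", "other")
_BIOTYPE_P = (0.70, 0.10, 0.10, 0.05, 0.05)


def _build_substructure(rng: np.random.Generator, start: int, end: int
                        ) -> list[tuple[str, int, int]]:
    """5'UTR - alternating exon/intron - 3'UTR blocks partitioning [start, end)."""
    span = end - start
    n_exons = int(rng.integers(2, 7))
    utr5 = int(rng.integers(100, 300))
    utr3 = int(rng.integers(200, 800))
    inner = span - utr5 - utr3
    weights = rng.random(2 * n_exons - 1) + 0.1
    lengths = np.maximum(1, (inner * weights / weights.sum()).astype(int))
    lengths[-1] = inner - lengths[:-1].sum()
    blocks = [("five_prime_utr", start, start + utr5)]
    cursor = start + utr5
    for i, ln in enumerate(lengths):
        feat = "exon" if i % 2 == 0 else "intron"
        blocks.append((feat, cursor, cursor + int(ln)))
        cursor += int(ln)
    blocks.append(("three_prime_utr", cursor, end))
    return blocks


def simulate_genes(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping gene models with UTR/exon/intron substructure."""
    rng = config.stage_rng("genes")
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, (config.n_genes * sizes / sizes.sum()).astype(int))
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        slot = config.chrom_sizes[chrom] // n
        for k in range(n):
            span = int(rng.integers(5_000, min(100_000, max(6_000, slot - 2_000))))
            offset = int(rng.integers(0, max(1, slot - span - 1)))
            start = k * slot + offset
            end = start + span
            genes.append(GeneModel(
                gene_id=f"GENE{gid:05d}", chrom=chrom, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                biotype=str(rng.choice(_BIOTYPES, p=_BIOTYPE_P)),
                substructure=_build_substructure(rng, start, end)))
            gid += 1
    return genes


def simulate_cytobands(config: SimulationConfig) -> list[CytoBand]:
    """Partition each chromosome into p- and q-arm bands of jittered size."""
    rng = config.stage_rng("bands")
    bands: list[CytoBand] = []
    for chrom, size in config.chrom_sizes.items():
        n = config.n_bands_per_chrom
        cuts = np.sort(rng.choice(np.arange(1, size // 1000), size=n - 1,
                                  replace=False)) * 1000
        edges = np.concatenate([[0], cuts, [size]])
        half = n // 2
        for i in range(n):
            if i < half:
                name = f"p{half - i}"          # p arm counts down toward centromere
            else:
                name = f"q{i - half + 1}"
            bands.append(CytoBand(chrom, int(edges[i]), int(edges[i + 1]),
                                  chrom.removeprefix("chr") + name,
                                  "gneg" if i % 2 == 0 else "gpos50"))
    return bands


def simulate_regulatory(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """Random regulatory intervals targeting ``regulatory_coverage`` of the
    genome, emulating an Ensembl regulatory build at small scale."""
    rng = config.stage_rng("regulatory")
    out: list[tuple[str, int, int]] = []
    for chrom, size in config.chrom_sizes.items():
        covered = 0
        target = config.regulatory_coverage * size
        while covered < target:
            length = int(rng.integers(200, 2_001))
            start = int(rng.integers(0, size - length))
            out.append((chrom, start, start + length))
            covered += length
    return sorted(out)


# ---------------------------------------------------------------------------
# Expression with planted effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """Ground truth for one planted cis association."""
    variant_id: str
    gene_id: str
    beta: float       # expression units per presence allele
    distance: int     # bp between variant locus and gene interval


def _cis_distance(variant: TevVariant, gene: GeneModel) -> Optional[int]:
    if variant.chrom != gene.chrom:
        return None
    vs, ve = variant.interval
    if ve <= gene.start:
        return gene.start - ve
    if gene.end <= vs:
        return vs - gene.end
    return 0


def simulate_expression(config: SimulationConfig, cohort: Sequence[SampleInfo],
                        tevs: Sequence[TevVariant], genes: Sequence[GeneModel],
                        cis_window: int = 1_000_000,
                        ) -> tuple[ExpressionMatrix, list[PlantedEffect]]:
    """Simulate RPKM-scale expression with additive planted cis effects.

    y[g, s] = mu_g + a_g * 1{male} + b_g(pop) + sum(beta * dosage) + noise,
    clipped at 0.  Planted (variant, gene) pairs are drawn only among cis
    pairs (distance < ``cis_window``) whose variant is common enough
    (expected MAF >= ``planted_min_maf``, proxied by the realized allele
    frequency) to make the effect detectable at the configured cohort size.
    """
    rng = config.stage_rng("expression")
    n_samples = len(cohort)
    male = np.array([s.sex == "male" for s in cohort], dtype=float)
    pop_labels = sorted({s.population for s in cohort})
    pop_idx = np.array([pop_labels.index(s.population) for s in cohort])

    mu = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                           len(genes)))
    sex_eff = rng.normal(0.0, config.sex_effect_sd, len(genes))
    pop_eff = rng.normal(0.0, config.population_effect_sd,
                         (len(genes), len(pop_labels)))

    values = (mu[:, None]
              + sex_eff[:, None] * male[None, :]
              + pop_eff[:, pop_idx])

    # choose planted pairs among eligible cis pairs
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    eligible: list[tuple[str, str, int]] = []
    for v in tevs:
        af = np.nanmean(v.dosages) / 2.0
        if af < config.planted_min_maf:
            continue
        for g in genes:
            d = _cis_distance(v, g)
            if d is not None and d < cis_window:
                eligible.append((v.variant_id, g.gene_id, d))
    if config.n_planted > len(eligible):
        raise ConfigError(
            f"cannot plant {config.n_planted} effects: only {len(eligible)} "
            f"eligible cis pairs")
    chosen = rng.choice(len(eligible), size=config.n_planted, replace=False)
    planted = [PlantedEffect(*eligible[int(i)][:2], beta=config.effect_size,
                             distance=eligible[int(i)][2])
               for i in sorted(chosen)]
    tev_by_id = {v.variant_id: v for v in tevs}
    for eff in planted:
        dos = np.nan_to_num(tev_by_id[eff.variant_id].dosages)
        values[gene_index[eff.gene_id]] += eff.beta * dos

    values = values + rng.normal(0.0, config.noise_sd, values.shape)
    values = np.clip(values, 0.0, None)
    if config.log2_expression:
        values = np.log2(values + 1.0)
    matrix = ExpressionMatrix([g.gene_id for g in genes],
                              [s.sample_id for s in cohort], values)
    return matrix, planted


def check_planted_cis(planted: Sequence[PlantedEffect],
                      cis_window: int = 1_000_000) -> None:
    for eff in planted:
        if eff.distance >= cis_window:
            raise ConfigError(f"planted effect {eff.variant_id}/{eff.gene_id} "
                              f"is not a cis pair")


# ---------------------------------------------------------------------------
# RNA-seq insertion calls
# ---------------------------------------------------------------------------

def simulate_rna_calls(config: SimulationConfig, tevs: Sequence[TevVariant],
                       cohort: Sequence[SampleInfo],
                       genes: Optional[Sequence[GeneModel]] = None,
                       ) -> tuple[pd.DataFrame, list[dict], list[str]]:
    """Emit a MELT-style insertion-call table for a transcribed subset of TEVs.

    Transcribed TEVs are drawn among intra-genic variants (any gene overlap)
    when gene models are supplied, otherwise among all variants.  For each
    (carrier sample, transcribed TEV) pair a true call of the same class is
    emitted with probability ``rna_tp_rate`` at the variant position plus a
    uniform integer jitter strictly inside ``(-rna_jitter_bp, rna_jitter_bp)``;
    ``n_false_calls`` decoys are added at random positions/classes/samples.

    Returns (call table, ground-truth match labels, transcribed variant ids).
    """
    if not 0.0 <= config.rna_tp_rate <= 1.0:
        raise ConfigError("rna_tp_rate outside [0, 1]")
    if config.rna_jitter_bp >= 50:
        raise ConfigError("rna_jitter_bp must stay below the 50 bp match rule")
    rng = config.stage_rng("rna")
    sample_ids = [s.sample_id for s in cohort]

    if genes:
        candidates = [v for v in tevs
                      if any(_cis_distance(v, g) == 0 for g in genes)]
    else:
        candidates = list(tevs)
    candidates = [v for v in candidates if v.carrier_count > 0]
    n_pick = min(config.n_transcribed, len(candidates))
    picked = rng.choice(len(candidates), size=n_pick, replace=False)
    transcribed = [candidates[int(i)] for i in sorted(picked)]

    gene_for: dict[str, str] = {}
    if genes:
        for v in transcribed:
            for g in genes:
                if _cis_distance(v, g) == 0:
                    gene_for[v.variant_id] = g.gene_id
                    break

    rows, truth = [], []
    call_id = 0
    for v in transcribed:
        carriers = [sample_ids[i] for i in np.flatnonzero(
            np.nan_to_num(v.dosages) >= 1)]
        for s in carriers:
            if rng.random() >= config.rna_tp_rate:
                continue
            jitter = int(rng.integers(-config.rna_jitter_bp + 1,
                                      config.rna_jitter_bp)) if config.rna_jitter_bp else 0
            rows.append((f"call{call_id:05d}", s, v.chrom, v.pos + jitter,
                         v.te_class, gene_for.get(v.variant_id, "")))
            truth.append({"call_id": f"call{call_id:05d}",
                          "variant_id": v.variant_id, "sample_id": s})
            call_id += 1
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(config.n_false_calls):
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        rows.append((f"call{call_id:05d}",
                     sample_ids[int(rng.integers(len(sample_ids)))],
                     chrom, int(rng.integers(1, config.chrom_sizes[chrom])),
                     ["Alu", "L1", "SVA"][int(rng.integers(3))], ""))
        call_id += 1
    table = pd.DataFrame(rows, columns=["call_id", "sample_id", "chrom", "pos",
                                        "te_class", "annotated_gene"])
    return table, truth, [v.variant_id for v in transcribed]


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = ("tevs.vcf", "expression.tsv", "samples.tsv", "genes.gtf",
                "regulatory.bed", "cytobands.tsv", "rna_calls.tsv",
                "ground_truth.json")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, outdir: str,
                         overwrite: bool = False) -> dict:
    """Generate a full synthetic study and write all formats the pipeline
    reads, plus ground truth and a manifest with file hashes and the seed.

    Refuses to write into a non-empty directory unless ``overwrite`` is set.
    Byte-identical across runs with the same config.
    """
    os.makedirs(outdir, exist_ok=True)
    existing = [f for f in os.listdir(outdir) if not f.startswith(".")]
    if existing and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")

    cohort = simulate_cohort(config)
    tevs = simulate_tevs(config, cohort)
    genes = simulate_genes(config)
    expr, planted = simulate_expression(config, cohort, tevs, genes)
    check_planted_cis(planted)
    calls, truth, transcribed = simulate_rna_calls(config, tevs, cohort, genes)
    bands = simulate_cytobands(config)
    regulatory = simulate_regulatory(config)

    sample_ids = [s.sample_id for s in cohort]
    p = lambda name: os.path.join(outdir, name)
    write_tev_vcf(p("tevs.vcf"), tevs, sample_ids, config.chrom_sizes)
    write_expression(p("expression.tsv"), expr)
    write_sample_info(p("samples.tsv"), cohort)
    write_gene_annotation(p("genes.gtf"), genes)
    write_bed(p("regulatory.bed"), regulatory)
    write_cytobands(p("cytobands.tsv"), bands)
    calls.to_csv(p("rna_calls.tsv"), sep="\t", index=False)
    with open(p("ground_truth.json"), "w") as fh:
        json.dump({"seed": config.seed,
                   "planted_effects": [asdict(e) for e in planted],
                   "transcribed_tevs": transcribed,
                   "true_calls": truth}, fh, indent=1, sort_keys=True)

    manifest = {"seed": config.seed,
                "config": {k: (v if not isinstance(v, dict) else dict(v))
                           for k, v in asdict(config).items()},
                "files": {name: _sha256(p(name)) for name in BUNDLE_FILES}}
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Compact scan-scale datasets (clustered layout, used for calibration work)
# ---------------------------------------------------------------------------

def make_scan_dataset(n_samples: int = 200, n_genes: int = 40,
                      variants_per_gene: int = 50, n_planted: int = 0,
                      beta: float = 1.5, noise_sd: float = 1.0,
                      seed: int = 0) -> tuple[SimulationConfig, list[SampleInfo],
                                              list[TevVariant], list[GeneModel],
                                              ExpressionMatrix, list[PlantedEffect]]:
    """A clustered in-memory study: each gene sits in its own 3 Mbp slot with
    its variants within 0.5 Mbp, so the cis-pair set is exactly
    ``n_genes * variants_per_gene`` and scan-level calibration runs fast.

    Planted variants are drawn from the common part of the MAF spectrum (one
    random cis variant per distinct gene, up to ``n_planted`` genes).
    """
    slot = 3_000_000
    config = SimulationConfig(
        n_samples=n_samples, chrom_sizes={"chr1": n_genes * slot},
        n_alu=0, n_l1=0, n_sva=0, n_genes=0, n_planted=0,
        effect_size=beta, noise_sd=noise_sd, seed=seed)
    rng = config.stage_rng("scan-dataset")
    cohort = simulate_cohort(config)

    genes, variants = [], []
    for gi in range(n_genes):
        g_start = gi * slot + slot // 2
        genes.append(GeneModel(f"GENE{gi:05d}", "chr1", g_start, g_start + 10_000,
                               "+" if rng.random() < 0.5 else "-"))
        mafs = _draw_mafs(rng, variants_per_gene, config)
        for vi in range(variants_per_gene):
            pos = int(g_start - 500_000 + rng.integers(0, 1_000_000))
            dosages = rng.binomial(2, mafs[vi], size=n_samples).astype(float)
            variants.append(TevVariant(
                f"tev{gi:03d}_{vi:03d}", "chr1", max(1, pos),
                ["Alu", "L1", "SVA"][int(rng.integers(3))],
                "+" if rng.random() < 0.5 else "-",
                bool(rng.random() < config.deletion_fraction),
                300, dosages))

    planted: list[PlantedEffect] = []
    if n_planted:
        for gi in rng.choice(n_genes, size=n_planted, replace=False):
            block = variants[gi * variants_per_gene:(gi + 1) * variants_per_gene]
            common = [v for v in block
                      if np.nanmean(v.dosages) / 2.0 >= 0.05]
            v = common[int(rng.integers(len(common)))] if common else block[0]
            planted.append(PlantedEffect(v.variant_id, genes[gi].gene_id,
                                         beta, 0))
    effect_cfg = SimulationConfig(
        n_samples=n_samples, chrom_sizes={"chr1": n_genes * slot},
        n_alu=0, n_l1=0, n_sva=0, n_genes=0, n_planted=0,
        effect_size=beta, noise_sd=noise_sd, seed=seed)
    expr, _ = _expression_for(effect_cfg, cohort, variants, genes, planted)
    return config, cohort, variants, genes, expr, planted


def _expression_for(config: SimulationConfig, cohort: Sequence[SampleInfo],
                    tevs: Sequence[TevVariant], genes: Sequence[GeneModel],
                    planted: Sequence[PlantedEffect],
                    ) -> tuple[ExpressionMatrix, list[PlantedEffect]]:
    """Expression under the additive generative model for a fixed planted set."""
    rng = config.stage_rng("expression")
    male = np.array([s.sex == "male" for s in cohort], dtype=float)
    pop_labels = sorted({s.population for s in cohort})
    pop_idx = np.array([pop_labels.index(s.population) for s in cohort])
    mu = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                           len(genes)))
    sex_eff = rng.normal(0.0, config.sex_effect_sd, len(genes))
    pop_eff = rng.normal(0.0, config.population_effect_sd,
                         (len(genes), len(pop_labels)))
    values = (mu[:, None] + sex_eff[:, None] * male[None, :]
              + pop_eff[:, pop_idx])
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    tev_by_id = {v.variant_id: v for v in tevs}
    for eff in planted:
        values[gene_index[eff.gene_id]] += eff.beta * np.nan_to_num(
            tev_by_id[eff.variant_id].dosages)
    values = np.clip(values + rng.normal(0.0, config.noise_sd, values.shape),
                     0.0, None)
    matrix = ExpressionMatrix([g.gene_id for g in genes],
                              [s.sample_id for s in cohort], values)
    return matrix, list(planted)
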