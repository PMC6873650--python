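"""End-to-end orchestration: synthetic bundle (or real-format inputs) ->
catalog filter -> cis-eQTL scan (+ optional genotype randomization) ->
window and regulatory enrichment -> orientation/context -> RNA-TEV analyses,
with a run manifest and a consolidated text report.

One global seed fans out to per-stage child seeds (derived by hashing the
stage name) so any stage can be re-run in isolation and two runs with the
same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict
from typing import Optional

import pandas as pd

from . import __version__
from .io_catalog import (
    filter_by_carriers, align_samples, min_carrier_frequency,
    read_cytobands, read_expression, read_gene_annotation, read_regulatory,
    read_sample_info, read_tev_vcf,
)
from .synthetic_data import SimulationConfig, write_fixture_bundle
from .eqtl_engine import (
    build_cis_pairs, permutation_validation, run_scan,
)
from .window_enrichment import (
    band_density, variant_features, window_enrichment_scan,
)
from .annotation_context import (
    ContextIndex, classify_contexts, class_contribution_test,
    context_comparison, enrichment_to_frame, orientation_concordance,
    regulatory_enrichment,
)
from .rna_tev import (
    calls_from_frame, class_ratio_log2, match_rna_calls, overlap_with_eqtls,
    presence_matrix, rna_tev_table,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed, kept below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class PipelineSettings:
    """Analysis thresholds; defaults are the study's canonical values."""
    min_carriers: int = 3
    cis_window: int = 1_000_000
    fdr_threshold: float = 0.05
    z_threshold: float = 3.0
    randomizations: int = 100
    match_distance: int = 50
    window_width: int = 10_000_000
    window_step: int = 5_000_000
    permute: bool = False      # run the genotype-randomization validation


OUTPUT_FILES = {
    "class_summary": "class_summary.tsv",
    "eqtl": "eqtl_results.tsv",
    "permutation": "permutation.json",
    "window_tevs": "window_enrichment_tevs.tsv",
    "window_eqtls": "window_enrichment_eqtls.tsv",
    "regulatory": "regulatory_enrichment.tsv",
    "orientation": "orientation.tsv",
    "context": "context_comparison.tsv",
    "bands": "band_density.tsv",
    "rna": "rna_tevs.tsv",
    "class_ratio": "rna_class_ratio.tsv",
    "presence": "rna_presence_matrix.tsv",
    "manifest": "manifest.json",
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: SimulationConfig, outdir: str,
                 settings: Optional[PipelineSettings] = None,
                 input_dir: Optional[str] = None) -> dict:
    """Run every stage and write all result tables plus the manifest.

    With ``input_dir`` unset, a synthetic bundle is generated under
    ``outdir/inputs`` from ``config`` and then consumed through the same
    file readers a real-data run would use; pointing ``input_dir`` at a
    directory holding the expected file names (tevs.vcf, expression.tsv,
    samples.tsv, genes.gtf, regulatory.bed, cytobands.tsv, rna_calls.tsv)
    runs the identical analysis on external data.
    """
    settings = settings or PipelineSettings()
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "settings": asdict(settings), "counts": {},
                      "stage_seeds": {}, "inputs": {}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:   # noqa: BLE001 - stage name must surface
                _dump_manifest(manifest, outdir)
                raise StageError(name, exc) from exc
        return wrap

    # --- inputs -----------------------------------------------------------
    if input_dir is None:
        input_dir = os.path.join(outdir, "inputs")
        stage("simulate")(write_fixture_bundle, config, input_dir, overwrite=True)
    p = lambda name: os.path.join(input_dir, name)
    for name in ("tevs.vcf", "expression.tsv", "samples.tsv", "genes.gtf",
                 "regulatory.bed", "cytobands.tsv", "rna_calls.tsv"):
        manifest["inputs"][name] = _sha256(p(name))

    cohort = stage("read")(read_sample_info, p("samples.tsv"))
    sample_ids = [s.sample_id for s in cohort]
    variants = stage("read")(read_tev_vcf, p("tevs.vcf"), sample_ids)
    expression = stage("read")(read_expression, p("expression.tsv"))
    genes = stage("read")(read_gene_annotation, p("genes.gtf"))
    regulatory = stage("read")(read_regulatory, p("regulatory.bed"))
    cytobands = stage("read")(read_cytobands, p("cytobands.tsv"))
    calls = calls_from_frame(pd.read_csv(p("rna_calls.tsv"), sep="\t", comment="#"))
    manifest["counts"]["variants_read"] = len(variants)

    # --- catalog filter ---------------------------------------------------
    filtered = stage("filter")(filter_by_carriers, variants, settings.min_carriers)
    manifest["counts"]["variants_filtered"] = len(filtered)
    manifest["counts"]["implied_min_carrier_frequency_pct"] = min_carrier_frequency(
        settings.min_carriers, len(sample_ids))

    expression, filtered, sample_ids, cohort = stage("align")(
        align_samples, expression, filtered, sample_ids, cohort)

    # --- cis-eQTL scan ----------------------------------------------------
    pairs = stage("scan")(build_cis_pairs, filtered, genes, settings.cis_window)
    scan = stage("scan")(run_scan, pairs, expression, filtered, cohort,
                         settings.fdr_threshold)
    manifest["counts"]["pairs_built"] = len(pairs)
    manifest["counts"]["pairs_tested"] = len(scan.results)
    manifest["counts"]["pairs_skipped"] = dict(scan.skipped)
    manifest["counts"]["significant_associations"] = scan.n_significant
    _write_tsv(scan.to_frame(), os.path.join(outdir, OUTPUT_FILES["eqtl"]))

    if settings.permute:
        seed = derive_seed(config.seed, "permutation")
        manifest["stage_seeds"]["permutation"] = seed
        summary = stage("permute")(permutation_validation, pairs, expression,
                                   filtered, cohort, settings.randomizations,
                                   seed, settings.fdr_threshold)
        with open(os.path.join(outdir, OUTPUT_FILES["permutation"]), "w") as fh:
            json.dump({"observed_significant": summary.observed_significant,
                       "replicate_counts": summary.replicate_counts,
                       "mean": summary.mean, "sd": summary.sd,
                       "z": summary.z, "empirical_p": summary.empirical_p,
                       "degenerate_sd": summary.degenerate_sd}, fh, indent=1)

    # --- per-class summary (total / filtered / significant) ---------------
    sig_by_class = {}
    class_of = {v.variant_id: v.te_class for v in filtered}
    for r in scan.results:
        if r.significant:
            c = class_of[r.variant_id]
            sig_by_class[c] = sig_by_class.get(c, 0) + 1
    summary_rows = []
    for c in ("Alu", "L1", "SVA"):
        total = sum(1 for v in variants if v.te_class == c)
        filt = sum(1 for v in filtered if v.te_class == c)
        summary_rows.append((c, total, filt, sig_by_class.get(c, 0)))
    summary_rows.append(("Total", len(variants), len(filtered),
                         sum(sig_by_class.values())))
    class_summary = pd.DataFrame(summary_rows, columns=[
        "te_class", "total", "extended_set", "cis_eqtl_associations"])
    _write_tsv(class_summary, os.path.join(outdir, OUTPUT_FILES["class_summary"]))

    # --- window enrichment: all TEVs, then significant eQTL variants ------
    by_class = {c: [v for v in filtered if v.te_class == c]
                for c in ("Alu", "L1", "SVA")}
    features_by_class = {c: variant_features(vs) for c, vs in by_class.items()}
    seed_w = derive_seed(config.seed, "windows")
    manifest["stage_seeds"]["windows"] = seed_w
    win_tevs = stage("windows")(
        window_enrichment_scan, features_by_class, config.chrom_sizes,
        settings.randomizations, seed_w, settings.window_width,
        settings.window_step, settings.z_threshold)
    _write_tsv(win_tevs, os.path.join(outdir, OUTPUT_FILES["window_tevs"]))

    sig_ids = {r.variant_id for r in scan.results if r.significant}
    sig_variants = [v for v in filtered if v.variant_id in sig_ids]
    eqtl_features = {c: variant_features([v for v in sig_variants
                                          if v.te_class == c])
                     for c in ("Alu", "L1", "SVA")}
    seed_we = derive_seed(config.seed, "windows-eqtl")
    manifest["stage_seeds"]["windows_eqtl"] = seed_we
    win_eqtls = stage("windows")(
        window_enrichment_scan,
        {c: f for c, f in eqtl_features.items() if f},
        config.chrom_sizes, settings.randomizations, seed_we,
        settings.window_width, settings.window_step, settings.z_threshold)
    _write_tsv(win_eqtls, os.path.join(outdir, OUTPUT_FILES["window_eqtls"]))

    # --- regulatory / orientation / context -------------------------------
    seed_r = derive_seed(config.seed, "regulatory")
    manifest["stage_seeds"]["regulatory"] = seed_r
    reg = stage("regulatory")(regulatory_enrichment, by_class, regulatory,
                              config.chrom_sizes, settings.randomizations,
                              seed_r, settings.z_threshold)
    _write_tsv(enrichment_to_frame(reg), os.path.join(outdir, OUTPUT_FILES["regulatory"]))

    orient = stage("orientation")(orientation_concordance, filtered, genes)
    odf = orient.to_frame()
    pw = pd.DataFrame([(a, b, p_) for (a, b), p_ in orient.pairwise_p.items()],
                      columns=["class_a", "class_b", "fisher_p"])
    _write_tsv(odf, os.path.join(outdir, OUTPUT_FILES["orientation"]))
    _write_tsv(pw, os.path.join(outdir, "orientation_pairwise.tsv"))

    totals = {c: len(vs) for c, vs in by_class.items()}
    sig_counts = {c: len({r.variant_id for r in scan.results
                          if r.significant and class_of[r.variant_id] == c})
                  for c in totals}
    contribution = class_contribution_test(totals, sig_counts)
    _write_tsv(pd.DataFrame([(a, b, p_) for (a, b), p_ in contribution.items()],
                            columns=["class_a", "class_b", "fisher_p"]),
               os.path.join(outdir, "class_contribution.tsv"))

    # --- RNA-TEV analyses -------------------------------------------------
    rna = stage("rna")(match_rna_calls, filtered, calls, sample_ids,
                       settings.match_distance)
    rna, n_in_eqtl = overlap_with_eqtls(rna, scan.results)
    manifest["counts"]["rna_tevs"] = len(rna)
    manifest["counts"]["rna_tevs_in_eqtl_set"] = n_in_eqtl
    _write_tsv(rna_tev_table(rna), os.path.join(outdir, OUTPUT_FILES["rna"]))
    _write_tsv(class_ratio_log2(rna, filtered),
               os.path.join(outdir, OUTPUT_FILES["class_ratio"]))
    pres = presence_matrix(rna, cohort)
    pres.to_csv(os.path.join(outdir, OUTPUT_FILES["presence"]), sep="\t")

    index = ContextIndex(genes)
    all_labels = classify_contexts(filtered, index)
    rna_set = {r.variant_id for r in rna}
    rna_labels = [lab for v, lab in zip(filtered, all_labels)
                  if v.variant_id in rna_set]
    ctx = stage("context")(context_comparison, rna_labels, all_labels)
    _write_tsv(ctx, os.path.join(outdir, OUTPUT_FILES["context"]))

    # --- band density of significant eQTL variants ------------------------
    bands = stage("bands")(band_density,
                           variant_features(sig_variants) or [], cytobands)
    _write_tsv(bands, os.path.join(outdir, OUTPUT_FILES["bands"]))

    _check_manifest(manifest)
    _dump_manifest(manifest, outdir)
    return manifest


def _check_manifest(manifest: dict) -> None:
    c = manifest["counts"]
    assert c["variants_filtered"] <= c["variants_read"]
    assert c["significant_associations"] <= c["pairs_tested"]
    skipped = sum(c["pairs_skipped"].values())
    assert c["pairs_tested"] + skipped == c["pairs_built"]


def _dump_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, OUTPUT_FILES["manifest"]), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_SECTIONS = (
    ("Per-class catalog summary", OUTPUT_FILES["class_summary"]),
    ("Top enriched windows (TEVs)", OUTPUT_FILES["window_tevs"]),
    ("Regulatory-region enrichment", OUTPUT_FILES["regulatory"]),
    ("Intra-genic orientation", OUTPUT_FILES["orientation"]),
    ("Karyotype-band eQTL density", OUTPUT_FILES["bands"]),
    ("RNA-TEV summary", OUTPUT_FILES["rna"]),
)


def report(outdir: str) -> str:
    """Human-readable summary assembled from the saved stage tables.

    Regenerating the report from the same directory is idempotent; sections
    whose table is missing are marked 'not run'.
    """
    lines = [f"tevkit report (v{__version__})", "=" * 32]
    for title, fname in _SECTIONS:
        lines.append("")
        lines.append(f"## {title}")
        path = os.path.join(outdir, fname)
        if not os.path.exists(path):
            lines.append("[not run]")
            continue
        df = pd.read_csv(path, sep="\t")
        if fname == OUTPUT_FILES["window_tevs"]:
            df = df.sort_values("z", ascending=False).head(10)
        if fname == OUTPUT_FILES["bands"]:
            df = df.groupby("group", group_keys=False).head(5)
        if fname == OUTPUT_FILES["rna"]:
            lines.append(f"{len(df)} RNA-TEVs "
                         f"({int(df['in_eqtl_set'].sum())} in the significant eQTL set)")
            df = df.head(10)
        lines.append(df.to_string(index=False, max_rows=20))
    return "\n".join(lines) + "\n"
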