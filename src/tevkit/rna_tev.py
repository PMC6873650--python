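"""Matching RNA-seq-derived insertion calls to DNA-genotyped TEVs.

A TEV counts as transcribed (an "RNA-TEV") when an insertion call of the
same TE class, from a sample that carries the variant at DNA level (dosage
>= 1), lies strictly within 50 bp of the variant position.  Each call is
assigned to at most one TEV: the nearest eligible one, ties broken toward
the lower variant coordinate.  Downstream summaries mirror the standard
descriptive views: class composition of RNA-TEVs against the full catalog,
a carrier presence matrix with samples grouped by population, and the
overlap with the significant cis-eQTL set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eqtl_engine import EqtlResult
from .io_catalog import SampleInfo, TevVariant, ValidationError


@dataclass(frozen=True)
class InsertionCall:
    """One MELT-style non-reference insertion call from RNA-seq."""
    call_id: str
    sample_id: str
    chrom: str
    pos: int                 # 1-based
    te_class: str
    annotated_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.call_id}: pos < 1")
        if self.te_class not in ("Alu", "L1", "SVA"):
            raise ValidationError(f"{self.call_id}: unknown class {self.te_class}")


@dataclass
class RnaTev:
    """A DNA TEV supported by at least one matching RNA-seq call."""
    variant_id: str
    chrom: str
    pos: int
    te_class: str
    supporting_calls: list[InsertionCall] = field(default_factory=list)
    carrier_samples: set[str] = field(default_factory=set)
    associated_gene: Optional[str] = None
    in_eqtl_set: bool = False


def calls_from_frame(df: pd.DataFrame) -> list[InsertionCall]:
    """Build calls from a MELT-style table with columns call_id, sample_id,
    chrom, pos, te_class and optional annotated_gene."""
    out = []
    for r in df.itertuples(index=False):
        gene = getattr(r, "annotated_gene", None)
        if gene is not None and (pd.isna(gene) or gene == ""):
            gene = None
        out.append(InsertionCall(str(r.call_id), str(r.sample_id), str(r.chrom),
                                 int(r.pos), str(r.te_class), gene))
    return out


def match_rna_calls(tevs: Sequence[TevVariant], calls: Sequence[InsertionCall],
                    genotype_samples: Sequence[str], max_distance: int = 50,
                    ) -> list[RnaTev]:
    """Assign calls to TEVs and return the supported TEVs as RnaTevs.

    A call supports a TEV iff same chromosome, same class, |pos difference|
    strictly below ``max_distance``, and the call's sample has DNA dosage
    >= 1 for that TEV.  Each call goes to at most one TEV (nearest;
    ties to the lower coordinate).  Output order follows genomic position.
    """
    sample_idx = {s: i for i, s in enumerate(genotype_samples)}
    by_key: dict[tuple[str, str], list[TevVariant]] = {}
    for v in tevs:
        by_key.setdefault((v.chrom, v.te_class), []).append(v)
    for lst in by_key.values():
        lst.sort(key=lambda v: (v.pos, v.variant_id))

    matched: dict[str, RnaTev] = {}
    for call in sorted(calls, key=lambda c: c.call_id):
        i = sample_idx.get(call.sample_id)
        if i is None:
            continue
        best: Optional[TevVariant] = None
        best_d = max_distance
        for v in by_key.get((call.chrom, call.te_class), ()):
            d = abs(call.pos - v.pos)
            if d >= max_distance:
                continue
            dosage = v.dosages[i]
            if np.isnan(dosage) or dosage < 1:
                continue
            if d < best_d or (d == best_d and (best is None or v.pos < best.pos)):
                best, best_d = v, d
        if best is None:
            continue
        rt = matched.get(best.variant_id)
        if rt is None:
            carriers = {genotype_samples[k] for k in
                        np.flatnonzero(np.nan_to_num(best.dosages) >= 1)}
            rt = RnaTev(best.variant_id, best.chrom, best.pos, best.te_class,
                        carrier_samples=carriers,
                        associated_gene=call.annotated_gene)
            matched[best.variant_id] = rt
        rt.supporting_calls.append(call)
        if rt.associated_gene is None and call.annotated_gene:
            rt.associated_gene = call.annotated_gene
    return sorted(matched.values(), key=lambda r: (r.chrom, r.pos, r.variant_id))


def class_ratio_log2(rna_tevs: Sequence[RnaTev],
                     all_tevs: Sequence[TevVariant]) -> pd.DataFrame:
    """log2 of (percent of RNA-TEVs in class) / (percent of all TEVs in
    class); classes absent from the RNA set are -inf and flagged."""
    classes = ("Alu", "L1", "SVA")
    n_rna, n_all = len(rna_tevs), len(all_tevs)
    rows = []
    for c in classes:
        r = sum(1 for v in rna_tevs if v.te_class == c)
        a = sum(1 for v in all_tevs if v.te_class == c)
        pct_r = 100.0 * r / n_rna if n_rna else np.nan
        pct_a = 100.0 * a / n_all if n_all else np.nan
        if not n_rna or np.isnan(pct_r) or not pct_a:
            ratio, flagged = np.nan, True
        elif pct_r == 0.0:
            ratio, flagged = -np.inf, True
        else:
            ratio, flagged = float(np.log2(pct_r / pct_a)), False
        rows.append((c, r, a, pct_r, pct_a, ratio, flagged))
    return pd.DataFrame(rows, columns=["te_class", "n_rna", "n_all", "pct_rna",
                                       "pct_all", "log2_ratio", "flagged"])


def presence_matrix(rna_tevs: Sequence[RnaTev],
                    cohort: Sequence[SampleInfo]) -> pd.DataFrame:
    """Binary RNA-TEV x sample matrix; 1 where the sample carries the variant
    at DNA level.  Columns are grouped by population (then sample id), rows
    ordered by genomic coordinate."""
    ordered = sorted(cohort, key=lambda s: (s.population, s.sample_id))
    cols = [s.sample_id for s in ordered]
    rows = sorted(rna_tevs, key=lambda r: (r.chrom, r.pos, r.variant_id))
    data = np.zeros((len(rows), len(cols)), dtype=int)
    col_idx = {s: j for j, s in enumerate(cols)}
    for i, rt in enumerate(rows):
        for s in rt.carrier_samples:
            if s in col_idx:
                data[i, col_idx[s]] = 1
    df = pd.DataFrame(data, index=[r.variant_id for r in rows], columns=cols)
    df.columns = pd.MultiIndex.from_tuples(
        [(s.population, s.sample_id) for s in ordered],
        names=["population", "sample_id"])
    return df


def overlap_with_eqtls(rna_tevs: Sequence[RnaTev],
                       eqtl_results: Sequence[EqtlResult]) -> tuple[list[RnaTev], int]:
    """Flag RNA-TEVs whose variant has at least one significant association;
    returns the annotated list and the flagged count."""
    significant = {r.variant_id for r in eqtl_results if r.significant}
    count = 0
    for rt in rna_tevs:
        rt.in_eqtl_set = rt.variant_id in significant
        count += rt.in_eqtl_set
    return list(rna_tevs), count


def rna_tev_table(rna_tevs: Sequence[RnaTev]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variant_id, r.chrom, r.pos, r.te_class, len(r.supporting_calls),
          len(r.carrier_samples), r.associated_gene or "", r.in_eqtl_set)
         for r in rna_tevs],
        columns=["variant_id", "chrom", "pos", "te_class", "n_supporting_calls",
                 "n_carriers", "associated_gene", "in_eqtl_set"])
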