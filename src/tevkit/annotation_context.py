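"""Regulatory-region enrichment, intra-genic orientation concordance, class
contribution tests, and genomic-context classification.

All categorical comparisons use the two-sided Fisher exact test (the sum of
hypergeometric probabilities no larger than that of the observed table).
Regulatory enrichment compares the percentage of each TE class overlapping
any regulatory interval with R uniform randomizations of the class's
coordinates; |Z| > 3 calls enrichment (Z > 3) or depletion (Z < -3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_catalog import GeneModel, TevVariant
from .window_enrichment import EnrichmentStat, Feature, randomize_coordinates

CONTEXT_LABELS = ("three_prime_utr", "five_prime_utr", "exon", "intron",
                  "intergenic")
#: lookup precedence when a locus overlaps several annotated features
_CONTEXT_PRECEDENCE = {"three_prime_utr": 0, "five_prime_utr": 1, "exon": 2,
                       "intron": 3}


def _interval_forest(intervals: Sequence[Feature]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        forest.setdefault(chrom, IntervalTree()).addi(start, end)
    return forest


def fisher_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts."""
    arr = np.asarray(table, dtype=int)
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Regulatory enrichment
# ---------------------------------------------------------------------------

def regulatory_enrichment(variants_by_class: dict[str, Sequence[TevVariant]],
                          regulatory: Sequence[Feature],
                          chrom_sizes: dict[str, int], R: int = 100,
                          seed: int = 0, z_threshold: float = 3.0,
                          ) -> list[EnrichmentStat]:
    """Percentage of each class overlapping regulatory sequence versus
    randomized placements; one cell per class x {regulatory, non_regulatory}.

    The non-regulatory cell is the complementary percentage, so its Z is the
    negative of the regulatory one; both are reported the way the paired
    barplots are read.  Empty classes yield 'not_applicable' cells.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    forest = _interval_forest(regulatory)
    rng = np.random.default_rng(seed)
    out: list[EnrichmentStat] = []

    def pct_overlap(feats: Sequence[Feature]) -> float:
        hits = sum(1 for c, s, e in feats
                   if c in forest and forest[c].overlaps(s, e))
        return 100.0 * hits / len(feats)

    for te_class in sorted(variants_by_class):
        variants = list(variants_by_class[te_class])
        if not variants:
            for cell in ("regulatory", "non_regulatory"):
                out.append(EnrichmentStat(f"{te_class}:{cell}", np.nan, np.nan,
                                          np.nan, np.nan, np.nan, False,
                                          direction="not_applicable"))
            continue
        feats = [(v.chrom,) + v.interval for v in variants]
        observed = pct_overlap(feats)
        rand = np.array([pct_overlap(randomize_coordinates(feats, chrom_sizes, rng))
                         for _ in range(R)])
        for cell, obs, rnd in (("regulatory", observed, rand),
                               ("non_regulatory", 100.0 - observed, 100.0 - rand)):
            mean, sd = float(rnd.mean()), float(rnd.std(ddof=1))
            degenerate = sd == 0.0
            if degenerate:
                z = np.inf if obs > mean else (0.0 if obs == mean else -np.inf)
            else:
                z = (obs - mean) / sd
            emp_p = (1 + int((rnd >= obs).sum())) / (1 + R)
            direction = ("enriched" if z > z_threshold
                         else "depleted" if z < -z_threshold else "neutral")
            out.append(EnrichmentStat(f"{te_class}:{cell}", obs, mean, sd,
                                      float(z), emp_p,
                                      significant=abs(z) > z_threshold,
                                      direction=direction,
                                      degenerate_sd=degenerate))
    return out


def enrichment_to_frame(stats_list: Sequence[EnrichmentStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.unit, s.observed, s.rand_mean, s.rand_sd, s.z, s.empirical_p,
          s.significant, s.direction, s.degenerate_sd) for s in stats_list],
        columns=["unit", "observed", "rand_mean", "rand_sd", "z",
                 "empirical_p", "significant", "direction", "degenerate_sd"])


# ---------------------------------------------------------------------------
# Orientation concordance
# ---------------------------------------------------------------------------

@dataclass
class OrientationTable:
    """Concordant/discordant counts of intra-genic variants per TE class.

    A variant is concordant when it shares the strand of at least one gene
    it overlaps (the deterministic rule for loci overlapping genes on both
    strands); strand-unknown variants land in ``unoriented``.
    ``pairwise_p`` holds two-sided Fisher p-values on (concordant,
    discordant) counts for each class pair.
    """
    concordant: dict[str, int] = field(default_factory=dict)
    discordant: dict[str, int] = field(default_factory=dict)
    unoriented: dict[str, int] = field(default_factory=dict)
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def percent_concordant(self, te_class: str) -> float:
        total = self.concordant.get(te_class, 0) + self.discordant.get(te_class, 0)
        return 100.0 * self.concordant.get(te_class, 0) / total if total else np.nan

    def to_frame(self) -> pd.DataFrame:
        classes = sorted(set(self.concordant) | set(self.discordant)
                         | set(self.unoriented))
        return pd.DataFrame(
            [(c, self.concordant.get(c, 0), self.discordant.get(c, 0),
              self.unoriented.get(c, 0), self.percent_concordant(c))
             for c in classes],
            columns=["te_class", "concordant", "discordant", "unoriented",
                     "percent_concordant"])


def orientation_concordance(variants: Sequence[TevVariant],
                            genes: Sequence[GeneModel]) -> OrientationTable:
    """Classify intra-genic variants as strand-concordant or -discordant with
    their host gene, per TE class, with pairwise Fisher comparisons."""
    forest: dict[str, IntervalTree] = {}
    for g in genes:
        forest.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.strand)
    table = OrientationTable()
    for v in variants:
        s, e = v.interval
        hits = forest.get(v.chrom, IntervalTree()).overlap(s, e)
        if not hits:
            continue
        if v.strand is None:
            table.unoriented[v.te_class] = table.unoriented.get(v.te_class, 0) + 1
            continue
        strands = {h.data for h in hits}
        bucket = table.concordant if v.strand in strands else table.discordant
        bucket[v.te_class] = bucket.get(v.te_class, 0) + 1
    classes = sorted(set(table.concordant) | set(table.discordant))
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            table.pairwise_p[(c1, c2)] = fisher_two_sided(
                [[table.concordant.get(c1, 0), table.discordant.get(c1, 0)],
                 [table.concordant.get(c2, 0), table.discordant.get(c2, 0)]])
    return table


# ---------------------------------------------------------------------------
# Class contribution
# ---------------------------------------------------------------------------

def class_contribution_test(total_by_class: dict[str, int],
                            significant_by_class: dict[str, int],
                            ) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Fisher tests for over/under-representation of each
    class among significant associations: rows are (significant,
    not-significant), columns the two classes."""
    for c, sig in significant_by_class.items():
        if sig < 0 or total_by_class.get(c, 0) < sig:
            raise ValueError(f"{c}: significant exceeds total or is negative")
    classes = sorted(total_by_class)
    out = {}
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            s1 = significant_by_class.get(c1, 0)
            s2 = significant_by_class.get(c2, 0)
            out[(c1, c2)] = fisher_two_sided(
                [[s1, total_by_class[c1] - s1],
                 [s2, total_by_class[c2] - s2]])
    return out


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

class ContextIndex:
    """Interval lookup of gene substructure for batch context classification."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._features: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for g in genes:
            self._spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
            for feat, s, e in g.substructure:
                self._features.setdefault(g.chrom, IntervalTree()).addi(s, e, feat)

    def classify(self, chrom: str, start: int, end: int) -> str:
        hits = self._features.get(chrom, IntervalTree()).overlap(start, end)
        feats = {h.data for h in hits}
        for label in sorted(_CONTEXT_PRECEDENCE, key=_CONTEXT_PRECEDENCE.get):
            if label in feats:
                return label
        # inside a gene span with no annotated block: treat as intronic
        if self._spans.get(chrom, IntervalTree()).overlaps(start, end):
            return "intron"
        return "intergenic"


def classify_context(variant: TevVariant, genes: Sequence[GeneModel] | ContextIndex) -> str:
    """Context label for one variant locus, by precedence
    3'UTR > 5'UTR > exon > intron, else intergenic."""
    index = genes if isinstance(genes, ContextIndex) else ContextIndex(genes)
    return index.classify(variant.chrom, *variant.interval)


def classify_contexts(variants: Sequence[TevVariant],
                      genes: Sequence[GeneModel] | ContextIndex) -> list[str]:
    index = genes if isinstance(genes, ContextIndex) else ContextIndex(genes)
    return [index.classify(v.chrom, *v.interval) for v in variants]


def context_comparison(labels_subset: Sequence[str],
                       labels_background: Sequence[str]) -> pd.DataFrame:
    """Per-context enrichment of one variant set against another: percentage
    in each set, log2 percentage ratio, and a two-sided Fisher p on
    (in-context, out-of-context) counts."""
    n_a, n_b = len(labels_subset), len(labels_background)
    rows = []
    for label in CONTEXT_LABELS:
        a = sum(1 for x in labels_subset if x == label)
        b = sum(1 for x in labels_background if x == label)
        pct_a = 100.0 * a / n_a if n_a else np.nan
        pct_b = 100.0 * b / n_b if n_b else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float(np.log2(pct_a / pct_b)) if n_a and n_b and pct_b else np.nan
        p = fisher_two_sided([[a, n_a - a], [b, n_b - b]]) if n_a and n_b else np.nan
        rows.append((label, a, b, pct_a, pct_b, ratio, p))
    return pd.DataFrame(rows, columns=["context", "count_subset",
                                       "count_background", "pct_subset",
                                       "pct_background", "log2_ratio", "fisher_p"])
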