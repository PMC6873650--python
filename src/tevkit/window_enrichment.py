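"""Sliding-window enrichment against randomized coordinates, and karyotype-
band density ranking.

The genome is tiled into overlapping windows (10 Mbp wide, 5 Mbp step by
default), feature counts per window are compared with R randomizations in
which the same number of features with the same length multiset is placed
uniformly on the genome, and windows with Z > 3 are called enriched.  The
same machinery serves both the full TEV catalog and the positions of
significant cis-eQTL variants.  Band density ranks karyotype bands by
feature count normalized to band length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eqtl_engine import bh_adjust
from .io_catalog import CytoBand, ValidationError

#: a feature: (chrom, start, end), 0-based half-open
Feature = tuple[str, int, int]


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    index: int        # ordinal within its chromosome


@dataclass
class EnrichmentStat:
    """Observed count (or percentage) against a randomization null."""
    unit: str
    observed: float
    rand_mean: float
    rand_sd: float
    z: float
    empirical_p: float
    significant: bool
    direction: str = ""       # enriched | depleted | neutral (where depletion is called)
    degenerate_sd: bool = False


# ---------------------------------------------------------------------------
# Tiling and counting
# ---------------------------------------------------------------------------

def tile_genome(chrom_sizes: dict[str, int], width: int = 10_000_000,
                step: int = 5_000_000) -> list[GenomicWindow]:
    """Sliding windows starting at 0, step, 2*step, ... while start < length;
    terminal windows are clipped to the chromosome end."""
    if not 0 < step <= width:
        raise ValueError("need 0 < step <= width")
    windows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValidationError(f"non-positive size for {chrom}")
        index = 0
        start = 0
        while start < size:
            windows.append(GenomicWindow(chrom, start, min(start + width, size), index))
            index += 1
            start += step
    return windows


def count_in_windows(windows: Sequence[GenomicWindow],
                     features: Sequence[Feature]) -> np.ndarray:
    """Per-window overlap counts; a feature increments every window it
    overlaps under the half-open test.

    Window starts form a regular grid per chromosome, so the overlapping
    index range is computed arithmetically rather than by scanning.
    """
    counts = np.zeros(len(windows), dtype=int)
    by_chrom: dict[str, list[tuple[int, GenomicWindow]]] = {}
    for j, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((j, w))
    meta = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda t: t[1].index)
        if len(lst) > 1:
            step = lst[1][1].start - lst[0][1].start
        else:
            step = lst[0][1].end - lst[0][1].start or 1
        width = max(w.end - w.start for _, w in lst)
        meta[chrom] = (lst, step, width)
    for chrom, start, end in features:
        if chrom not in meta:
            continue
        lst, step, width = meta[chrom]
        i_min = max(0, (start - width) // step + 1)
        i_max = min(len(lst) - 1, (end - 1) // step)
        for i in range(int(i_min), int(i_max) + 1):
            j, w = lst[i]
            if w.start < end and start < w.end:
                counts[j] += 1
    return counts


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def randomize_coordinates(features: Sequence[Feature],
                          chrom_sizes: dict[str, int],
                          rng: np.random.Generator) -> list[Feature]:
    """Place the same features (length multiset preserved) uniformly on the
    genome: each feature picks a chromosome with probability proportional to
    its placeable length and a uniform start fully inside it."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if not features:
        return []
    lengths = np.array([e - s for _, s, e in features], dtype=np.int64)
    placeable = sizes[None, :] - lengths[:, None]          # features x chroms
    weights = np.maximum(placeable, 0).astype(float)
    totals = weights.sum(axis=1)
    if (totals == 0).any():
        bad = int(lengths[totals == 0][0])
        raise ValueError(f"feature of length {bad} exceeds every chromosome")
    cum = np.cumsum(weights, axis=1)
    u = rng.random(len(lengths)) * totals
    ci = (u[:, None] >= cum).sum(axis=1)
    starts = rng.integers(0, placeable[np.arange(len(lengths)), ci] + 1)
    return [(chroms[int(c)], int(s), int(s + ln))
            for c, s, ln in zip(ci, starts, lengths)]


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def window_enrichment_scan(features_by_class: dict[str, Sequence[Feature]],
                           chrom_sizes: dict[str, int], R: int = 100,
                           seed: int = 0, width: int = 10_000_000,
                           step: int = 5_000_000, z_threshold: float = 3.0,
                           windows: Optional[Sequence[GenomicWindow]] = None,
                           ) -> pd.DataFrame:
    """Per class, compare observed window counts with R uniform
    randomizations of the same feature set.

    Returns one row per (class, window) with observed count, randomization
    mean/sd (sd with ddof=1), Z, empirical p with +1 pseudocount,
    -log10(empirical p), a BH q over windows within the class, and the
    Z > ``z_threshold`` enrichment call.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    if windows is None:
        windows = tile_genome(chrom_sizes, width, step)
    rng = np.random.default_rng(seed)
    rows = []
    for te_class in sorted(features_by_class):
        feats = list(features_by_class[te_class])
        observed = count_in_windows(windows, feats)
        rand_counts = np.empty((R, len(windows)))
        for r in range(R):
            rand = randomize_coordinates(feats, chrom_sizes, rng)
            rand_counts[r] = count_in_windows(windows, rand)
        mean = rand_counts.mean(axis=0)
        sd = rand_counts.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (observed - mean) / sd
        degenerate = sd == 0
        z[degenerate & (observed > mean)] = np.inf
        z[degenerate & (observed == mean)] = 0.0
        z[degenerate & (observed < mean)] = -np.inf
        emp_p = (1 + (rand_counts >= observed[None, :]).sum(axis=0)) / (1 + R)
        q = bh_adjust(emp_p)
        for j, w in enumerate(windows):
            rows.append((te_class, w.chrom, w.start, w.end, w.index,
                         int(observed[j]), mean[j], sd[j], z[j], emp_p[j],
                         -np.log10(emp_p[j]), q[j],
                         bool(z[j] > z_threshold), bool(degenerate[j])))
    return pd.DataFrame(rows, columns=[
        "te_class", "chrom", "start", "end", "window_index", "observed",
        "rand_mean", "rand_sd", "z", "empirical_p", "neg_log10_p", "q",
        "enriched", "degenerate_sd"])


# ---------------------------------------------------------------------------
# Karyotype-band density
# ---------------------------------------------------------------------------

def band_density(features: Sequence[Feature] | dict[str, Sequence[Feature]],
                 cytobands: Sequence[CytoBand]) -> pd.DataFrame:
    """Per-band feature counts normalized to band length, ranked by density.

    Accepts a single feature list or a {group: features} mapping (e.g. one
    eQTL list per tissue); with groups, ranking is within each group.
    """
    groups = features if isinstance(features, dict) else {"all": features}
    for b in cytobands:
        if b.length <= 0:
            raise ValidationError(f"zero-length band {b.band_name}")
    rows = []
    for group in sorted(groups):
        feats = list(groups[group])
        for band in cytobands:
            count = sum(1 for c, s, e in feats
                        if c == band.chrom and s < band.end and band.start < e)
            rows.append((group, band.band_name, band.chrom, band.start,
                         band.end, count, count / band.length))
    df = pd.DataFrame(rows, columns=["group", "band", "chrom", "start", "end",
                                     "count", "density_per_bp"])
    df = df.sort_values(["group", "density_per_bp", "band"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("group").cumcount() + 1
    return df.reset_index(drop=True)


def variant_features(variants, use_interval: bool = True) -> list[Feature]:
    """Project TevVariants to features for window/band counting (the variant
    locus, not the associated gene)."""
    out = []
    for v in variants:
        s, e = v.interval if use_interval else (v.pos - 1, v.pos)
        out.append((v.chrom, s, e))
    return out
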