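"""cis-eQTL scan for TE presence dosages.

The model is the classic additive eQTL regression: for each (variant, gene)
pair within the cis window, expression is regressed by ordinary least
squares on the per-sample presence dosage (0/1/2) with an intercept, a sex
indicator and K-1 population indicators,

    y = b0 + beta * g + a * male + sum_k c_k * pop_k + e,

and the dosage coefficient is tested with the usual t statistic on
``n - p`` residual degrees of freedom.  Benjamini-Hochberg adjustment is
applied jointly over all *tested* pairs and pairs at q <= 0.05 are called
significant.  A genotype-randomization check re-runs the full scan R times
with every variant's dosage vector independently permuted across samples,
summarizing how far the observed significant count sits above the null.

The scan is computed through the Frisch-Waugh-Lovell decomposition: the
covariate design is residualized out of expression and dosages once (via a
QR factorization), after which each pair reduces to a simple regression.
This is algebraically identical to the full OLS fit and is what makes 100
whole-scan randomizations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_catalog import ExpressionMatrix, GeneModel, SampleInfo, TevVariant

#: residual sum of squares below this fraction of total SS counts as exact
_PERFECT_FIT_RTOL = 1e-12
#: residual dosage variation below this (after covariate projection) means
#: the dosage is collinear with the covariates
_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class CisPair:
    """A (variant, gene) pair eligible for the cis scan."""
    variant_id: str
    gene_id: str
    distance: int     # bp between variant locus and gene interval; 0 if inside


@dataclass
class EqtlResult:
    variant_id: str
    gene_id: str
    n_used: int
    beta: float
    se: float
    t: float
    p: float
    q: float = np.nan
    significant: bool = False
    perfect_fit: bool = False


@dataclass
class AdditiveFit:
    """Core fields of a single-pair additive model fit."""
    status: str               # ok | monomorphic | collinear | insufficient_samples
    n_used: int = 0
    beta: float = np.nan
    se: float = np.nan
    t: float = np.nan
    p: float = np.nan
    perfect_fit: bool = False


@dataclass
class ScanResult:
    results: list[EqtlResult]
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.variant_id, r.gene_id, r.n_used, r.beta, r.se, r.t, r.p, r.q,
              r.significant, r.perfect_fit) for r in self.results],
            columns=["variant_id", "gene_id", "n_used", "beta", "se", "t",
                     "p", "q", "significant", "perfect_fit"])


@dataclass
class PermutationSummary:
    observed_significant: int
    replicate_counts: list[int]
    mean: float
    sd: float
    z: float
    empirical_p: float
    degenerate_sd: bool = False   # sd over replicates was 0


# ---------------------------------------------------------------------------
# cis pairing
# ---------------------------------------------------------------------------

def build_cis_pairs(variants: Sequence[TevVariant], genes: Sequence[GeneModel],
                    max_distance: int = 1_000_000,
                    anchor: str = "interval") -> list[CisPair]:
    """Enumerate (variant, gene) pairs with distance strictly below the window.

    Distance is the gap between the variant locus (full span for
    deletion-coded variants, 1 bp otherwise) and the gene interval, 0 when
    they overlap.  ``anchor='tss'`` measures to the transcription start
    site instead of the gene body.
    """
    pairs: list[CisPair] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for v in variants:
        vs, ve = v.interval
        for g in genes_by_chrom.get(v.chrom, ()):
            if anchor == "tss":
                tss = g.start if g.strand == "+" else g.end - 1
                gs, ge = tss, tss + 1
            else:
                gs, ge = g.start, g.end
            if ve <= gs:
                d = gs - ve
            elif ge <= vs:
                d = vs - ge
            else:
                d = 0
            if d < max_distance:
                pairs.append(CisPair(v.variant_id, g.gene_id, d))
    return pairs


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def build_covariate_design(cohort: Sequence[SampleInfo]) -> pd.DataFrame:
    """Sex indicator plus K-1 population indicators (reference level = first
    population in sorted order); no intercept column."""
    df = pd.DataFrame({
        "male": [1.0 if s.sex == "male" else 0.0 for s in cohort]})
    pops = sorted({s.population for s in cohort})
    for pop in pops[1:]:
        df[f"pop_{pop}"] = [1.0 if s.population == pop else 0.0 for s in cohort]
    return df


# ---------------------------------------------------------------------------
# Single-pair fit
# ---------------------------------------------------------------------------

def fit_additive_model(y: np.ndarray, g: np.ndarray,
                       covariates: Optional[pd.DataFrame] = None) -> AdditiveFit:
    """OLS of expression on [intercept, dosage, covariates] for one pair.

    Samples with missing dosage are dropped (not imputed).  Returns the
    dosage coefficient with its textbook standard error and two-sided
    t-test p-value; degenerate designs are reported through ``status``
    rather than raised.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~np.isnan(g)
    y, g = y[keep], g[keep]
    cov = None
    if covariates is not None and covariates.shape[1] > 0:
        cov = np.asarray(covariates, dtype=float)[keep]
    n = len(y)
    if len(np.unique(g)) < 2:
        return AdditiveFit("monomorphic", n_used=n)
    cols = [np.ones(n), g] + ([] if cov is None else [cov])
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p + 1:
        return AdditiveFit("insufficient_samples", n_used=n)
    if np.linalg.matrix_rank(X) < p:
        return AdditiveFit("collinear", n_used=n)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    tss = float((y - y.mean()) @ (y - y.mean()))
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    if ssr <= _PERFECT_FIT_RTOL * max(tss, 1.0):
        return AdditiveFit("ok", n_used=n, beta=float(coef[1]), se=0.0,
                           t=np.inf if coef[1] > 0 else (-np.inf if coef[1] < 0 else 0.0),
                           p=0.0, perfect_fit=True)
    se = float(np.sqrt(ssr / df * xtx_inv[1, 1]))
    t = float(coef[1] / se)
    return AdditiveFit("ok", n_used=n, beta=float(coef[1]), se=se, t=t,
                       p=float(2.0 * stats.t.sf(abs(t), df)))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def _scan_matrices(expression: ExpressionMatrix, variants: Sequence[TevVariant],
                   cohort: Sequence[SampleInfo], pairs: Sequence[CisPair],
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                              np.ndarray, np.ndarray]:
    gene_idx = {gid: i for i, gid in enumerate(expression.gene_ids)}
    var_idx = {v.variant_id: i for i, v in enumerate(variants)}
    pair_v = np.array([var_idx[p.variant_id] for p in pairs], dtype=int)
    pair_g = np.array([gene_idx[p.gene_id] for p in pairs], dtype=int)
    Y = expression.values
    G = np.stack([v.dosages for v in variants]) if variants else np.empty((0, len(cohort)))
    cov = build_covariate_design(cohort)
    C = np.column_stack([np.ones(len(cohort)), cov.to_numpy()])
    return Y, G, C, pair_v, pair_g


def _scan_core(Y: np.ndarray, G: np.ndarray, C: np.ndarray,
               pair_v: np.ndarray, pair_g: np.ndarray, cov: pd.DataFrame,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                          np.ndarray, np.ndarray, np.ndarray]:
    """Fit all pairs; returns per-pair (beta, se, t, p, n_used, perfect, status).

    status codes: 0 ok, 1 monomorphic, 2 collinear, 3 insufficient_samples.
    Pairs whose variant has missing dosages take the per-pair path; all
    others go through the vectorized FWL projection, which is exact OLS.
    """
    n = Y.shape[1]
    p_cols = C.shape[1] + 1
    df = n - p_cols

    Q, _ = np.linalg.qr(C)
    complete = ~np.isnan(G).any(axis=1)
    RY = Y - (Y @ Q) @ Q.T
    RG = np.where(complete[:, None], G, 0.0)
    RG = RG - (RG @ Q) @ Q.T

    m = len(pair_v)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.full(m, n, dtype=int)
    perfect = np.zeros(m, dtype=bool)
    status = np.zeros(m, dtype=int)

    vec = complete[pair_v]
    if vec.any():
        vi, gi = pair_v[vec], pair_g[vec]
        rg, ry = RG[vi], RY[gi]
        rgss = np.einsum("ij,ij->i", rg, rg)
        ryss = np.einsum("ij,ij->i", ry, ry)
        gry = np.einsum("ij,ij->i", rg, ry)

        n_distinct = np.array([len(np.unique(G[i])) for i in np.unique(vi)])
        mono_variant = {int(u): nd < 2 for u, nd in zip(np.unique(vi), n_distinct)}
        mono = np.array([mono_variant[int(i)] for i in vi])
        gss = np.einsum("ij,ij->i", G[vi], G[vi])
        coll = ~mono & (rgss < _COLLINEAR_TOL * np.maximum(gss, 1.0))
        ok = ~mono & ~coll

        b = np.zeros(len(vi))
        b[ok] = gry[ok] / rgss[ok]
        ssr = ryss - b * b * rgss
        pf = ok & (ssr <= _PERFECT_FIT_RTOL * np.maximum(ryss, 1.0))
        s = np.full(len(vi), np.nan)
        reg = ok & ~pf
        s[reg] = np.sqrt(ssr[reg] / df / rgss[reg])
        tv = np.full(len(vi), np.nan)
        tv[reg] = b[reg] / s[reg]
        pv = np.full(len(vi), np.nan)
        pv[reg] = 2.0 * stats.t.sf(np.abs(tv[reg]), df)
        s[pf] = 0.0
        tv[pf] = np.sign(b[pf]) * np.inf
        tv[pf & (b == 0)] = 0.0
        pv[pf] = 0.0

        idx = np.flatnonzero(vec)
        beta[idx[ok]] = b[ok]
        se[idx] = s
        tstat[idx] = tv
        pval[idx] = pv
        perfect[idx[pf]] = True
        status[idx[mono]] = 1
        status[idx[coll]] = 2

    for j in np.flatnonzero(~vec):
        fit = fit_additive_model(Y[pair_g[j]], G[pair_v[j]], cov)
        n_used[j] = fit.n_used
        if fit.status == "ok":
            beta[j], se[j], tstat[j], pval[j] = fit.beta, fit.se, fit.t, fit.p
            perfect[j] = fit.perfect_fit
        else:
            status[j] = {"monomorphic": 1, "collinear": 2,
                         "insufficient_samples": 3}[fit.status]
    return beta, se, tstat, pval, n_used, perfect, status


_STATUS_NAMES = {1: "monomorphic", 2: "collinear", 3: "insufficient_samples"}


def run_scan(pairs: Sequence[CisPair], expression: ExpressionMatrix,
             variants: Sequence[TevVariant], cohort: Sequence[SampleInfo],
             fdr_threshold: float = 0.05) -> ScanResult:
    """Fit every cis pair, BH-adjust jointly over tested pairs, and flag
    significance at ``q <= fdr_threshold``.

    Pairs skipped for degenerate dosage (monomorphic after missing-sample
    removal, collinear with covariates, too few samples) are excluded from
    the BH family and tallied in ``skipped``.
    """
    if not pairs:
        return ScanResult(results=[], skipped={})
    Y, G, C, pair_v, pair_g = _scan_matrices(expression, variants, cohort, pairs)
    cov = build_covariate_design(cohort)
    beta, se, t, p, n_used, perfect, status = _scan_core(Y, G, C, pair_v, pair_g, cov)

    tested = status == 0
    q = np.full(len(pairs), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    results = []
    skipped: dict[str, int] = {}
    for j, pair in enumerate(pairs):
        if not tested[j]:
            name = _STATUS_NAMES[int(status[j])]
            skipped[name] = skipped.get(name, 0) + 1
            continue
        results.append(EqtlResult(
            pair.variant_id, pair.gene_id, int(n_used[j]), float(beta[j]),
            float(se[j]), float(t[j]), float(p[j]), float(q[j]),
            significant=bool(q[j] <= fdr_threshold),
            perfect_fit=bool(perfect[j])))
    return ScanResult(results=results, skipped=skipped)


def _count_significant(p: np.ndarray, tested: np.ndarray,
                       fdr_threshold: float) -> int:
    if not tested.any():
        return 0
    return int((bh_adjust(p[tested]) <= fdr_threshold).sum())


def permutation_validation(pairs: Sequence[CisPair], expression: ExpressionMatrix,
                           variants: Sequence[TevVariant],
                           cohort: Sequence[SampleInfo], R: int = 100,
                           seed: int = 0, fdr_threshold: float = 0.05,
                           ) -> PermutationSummary:
    """Genotype-randomization check of the scan's significant count.

    Each replicate permutes every variant's dosage vector independently
    across samples (expression and covariates untouched), re-runs the full
    scan, and records its significant count; the observed count is compared
    with the replicate distribution through a Z score and an empirical
    p-value with a +1 pseudocount.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    Y, G, C, pair_v, pair_g = _scan_matrices(expression, variants, cohort, pairs)
    cov = build_covariate_design(cohort)
    *_, p_obs, _, _, status = _scan_core(Y, G, C, pair_v, pair_g, cov)
    observed = _count_significant(p_obs, status == 0, fdr_threshold)

    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(R):
        keys = rng.random(G.shape)
        perm = np.argsort(keys, axis=1)
        Gp = np.take_along_axis(G, perm, axis=1)
        *_, p_r, _, _, status_r = _scan_core(Y, Gp, C, pair_v, pair_g, cov)
        counts.append(_count_significant(p_r, status_r == 0, fdr_threshold))

    counts_arr = np.array(counts, dtype=float)
    mean = float(counts_arr.mean())
    sd = float(counts_arr.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        z = np.inf if observed > mean else (0.0 if observed == mean else -np.inf)
    else:
        z = (observed - mean) / sd
    emp_p = (1 + int((counts_arr >= observed).sum())) / (1 + R)
    return PermutationSummary(observed, counts, mean, sd, float(z), emp_p,
                              degenerate_sd=degenerate)
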