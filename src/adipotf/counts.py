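"""Count-based statistics for differential binding and expression.

The differential test models counts as negative binomial with
``variance = mean + dispersion * mean**2``.  Samples are normalized with
median-of-ratios size factors; per-feature dispersions are estimated by
method of moments and shrunk toward a mean-dispersion trend
``alpha(mu) = a1/mu + a0`` fitted across features; p-values come from an
exact-style conditional test that enumerates all allocations of the
pooled per-condition count totals under the null of equal concentration.
Multiple testing is controlled with Benjamini-Hochberg within each
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from adipotf.types import CountMatrix, GeneModel, GenomicInterval, PeakSet

logger = logging.getLogger("adipotf")

#: pseudocount (in normalized counts) used when forming fold-changes
FC_PSEUDOCOUNT = 0.5

#: a feature keeps its own moment dispersion estimate only when it exceeds
#: the fitted mean-dispersion trend by this factor
DISPERSION_OUTLIER_MULT = 10.0


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_tags_in_intervals(tags_by_sample: dict[str, list[tuple[str, int]]],
                            intervals: PeakSet,
                            samples: pd.DataFrame | None = None) -> CountMatrix:
    """Count tags whose position falls inside each interval.

    A tag inside several (overlapping) intervals increments all of them.
    """
    feature_ids = [iv.name or f"region_{i}" for i, iv in enumerate(intervals)]
    counts = pd.DataFrame(
        0, index=feature_ids, columns=list(tags_by_sample), dtype=int
    )
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for sample, tags in tags_by_sample.items():
        col = np.zeros(len(intervals), dtype=int)
        for chrom, pos in tags:
            for (s, e, i) in by_chrom.get(chrom, ()):
                if s <= pos < e:
                    col[i] += 1
        counts[sample] = col
    if samples is None:
        samples = pd.DataFrame(
            {"condition": ["na"] * len(tags_by_sample)}, index=list(tags_by_sample)
        )
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# size factors (median-of-ratios)
# ---------------------------------------------------------------------------

def estimate_size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with all-positive counts the geometric mean across
    samples is the reference; a sample's factor is the median of its
    count/reference ratios.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; cannot form the "
            "geometric-mean reference (consider a pseudo-reference)"
        )
    log_arr = np.log(arr[all_positive])
    log_geomean = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB differential test
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    feature_id: str
    base_mean: float
    fc: float            # condition B vs A, on normalized counts
    log2fc: float
    p: float
    padj: float
    klass: str           # up / down / ns / untested


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Non-negative least squares fit of disp ~ a0 + a1/mean."""
    ok = (means > 0) & (disps > 0)
    if ok.sum() < 2:
        return (float(disps[ok].mean()) if ok.any() else 0.01, 0.0)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = nnls(X, disps[ok])
    return float(coef[0]), float(coef[1])


def _exact_nb_p(k_a: int, k_b: int, mu_a: float, mu_b: float,
                disp_a: float, disp_b: float) -> float:
    """Conditional exact-style NB p-value.

    Conditions on the pooled total k = k_a + k_b, enumerates every
    allocation (a, k-a), and sums the probabilities of allocations no
    more likely than the observed one.
    """
    k = k_a + k_b
    if k == 0:
        return 1.0
    a = np.arange(k + 1)

    def _logpmf(x, mu, disp):
        if disp <= 1e-12:
            return stats.poisson.logpmf(x, mu)
        r = 1.0 / disp
        return stats.nbinom.logpmf(x, r, r / (r + mu))

    logp = _logpmf(a, mu_a, disp_a) + _logpmf(k - a, mu_b, disp_b)
    logp -= logp.max()
    p_all = np.exp(logp)
    p_obs = p_all[k_a]
    total = p_all.sum()
    # small tolerance so ties with the observed probability are included
    tail = p_all[p_all <= p_obs * (1 + 1e-10)].sum()
    return float(min(1.0, tail / total))


def nb_differential_test(matrix: CountMatrix, cond_a: str, cond_b: str,
                         size_factors: pd.Series | None = None
                         ) -> pd.DataFrame:
    """Two-condition negative-binomial differential test.

    Returns a DataFrame indexed by feature with columns base_mean, fc
    (B vs A on normalized counts, with a 0.5 pseudocount), log2fc, p,
    padj (BH) and class ('untested' for all-zero features, else 'ns';
    use :func:`classify_de` / :func:`classify_dynamic_regions` to apply
    thresholds).
    """
    samples_a = matrix.samples_in_condition(cond_a)
    samples_b = matrix.samples_in_condition(cond_b)
    if not samples_a or not samples_b:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} must both have samples")
    if len(samples_a) < 2 and len(samples_b) < 2:
        logger.warning(
            "fewer than 2 replicates in both conditions; dispersion is "
            "estimated from samples pooled across conditions"
        )
    counts = matrix.counts[samples_a + samples_b]
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors[samples_a + samples_b].to_numpy()
    norm = counts.to_numpy(dtype=float) / sf
    n_a, n_b = len(samples_a), len(samples_b)
    norm_a, norm_b = norm[:, :n_a], norm[:, n_a:]

    base_mean = norm.mean(axis=1)
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)

    # --- method-of-moments dispersion, within conditions when possible ---
    if n_a >= 2 or n_b >= 2:
        num = np.zeros(len(counts))
        den = np.zeros(len(counts))
        for grp, mu in ((norm_a, mean_a), (norm_b, mean_b)):
            if grp.shape[1] >= 2:
                v = grp.var(axis=1, ddof=1)
                # subtract the shot-noise (Poisson) component
                num += v - mu * np.mean(1.0 / sf)
                den += np.maximum(mu, 1e-8) ** 2
        raw_disp = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    else:
        v = norm.var(axis=1, ddof=1)
        raw_disp = (v - base_mean * np.mean(1.0 / sf)) / np.maximum(base_mean, 1e-8) ** 2
    raw_disp = np.clip(raw_disp, 0.0, 20.0)

    a0, a1 = _fit_dispersion_trend(base_mean, raw_disp)
    trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    trend = np.clip(trend, 1e-8, 20.0)
    # with few replicates the per-feature moment estimate is mostly noise:
    # use the fitted trend, keeping the raw value only for extreme
    # variance outliers (which then stay conservative)
    disp = np.where(raw_disp > DISPERSION_OUTLIER_MULT * trend, raw_disp, trend)

    s_a = sf[:n_a].sum()
    s_b = sf[n_a:].sum()
    sq_a = (sf[:n_a] ** 2).sum()
    sq_b = (sf[n_a:] ** 2).sum()

    k_a = counts[samples_a].sum(axis=1).to_numpy()
    k_b = counts[samples_b].sum(axis=1).to_numpy()

    p = np.full(len(counts), np.nan)
    tested = (k_a + k_b) > 0
    for i in np.where(tested)[0]:
        q = base_mean[i]
        mu_a = q * s_a
        mu_b = q * s_b
        # dispersion of the pooled sum: var = mu + disp_eff * mu^2
        disp_eff_a = disp[i] * sq_a / s_a**2
        disp_eff_b = disp[i] * sq_b / s_b**2
        p[i] = _exact_nb_p(int(k_a[i]), int(k_b[i]), mu_a, mu_b,
                           disp_eff_a, disp_eff_b)

    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    fc = (mean_b + FC_PSEUDOCOUNT) / (mean_a + FC_PSEUDOCOUNT)
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "padj": padj,
            "class": np.where(tested, "ns", "untested"),
        },
        index=counts.index,
    )
    res.index.name = "feature_id"
    return res


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_de(results: pd.DataFrame, fc: float = 1.5,
                padj: float = 0.01, fc_down: float | None = None) -> pd.Series:
    """Up / down / ns calls with inclusive thresholds.

    up: fc >= ``fc`` and padj <= ``padj``; down: fc <= ``fc_down`` and
    padj <= ``padj``; untested features stay untested.  ``fc_down``
    defaults to the reciprocal of ``fc`` rounded to two decimals
    (0.67 for fc=1.5), matching how such thresholds are conventionally
    quoted.
    """
    if fc_down is None:
        fc_down = round(1.0 / fc, 2)
    out = pd.Series("ns", index=results.index, name="class")
    tested = results["class"] != "untested" if "class" in results else results["p"].notna()
    sig = tested & (results["padj"] <= padj)
    out[sig & (results["fc"] >= fc)] = "up"
    out[sig & (results["fc"] <= fc_down)] = "down"
    out[~tested] = "untested"
    return out


def classify_dynamic_regions(results_early_vs_late: pd.DataFrame,
                             fc: float = 2.0, padj: float = 0.1) -> pd.Series:
    """Early-only / late-only / static classification of bound regions.

    ``results_early_vs_late`` must come from
    ``nb_differential_test(matrix, 'early', 'late')`` so that fc is
    late vs early.  late_only: fc >= ``fc`` and padj <= ``padj``;
    early_only: fc <= 1/``fc`` and padj <= ``padj``; else static.
    """
    out = pd.Series("static", index=results_early_vs_late.index, name="dynamic_class")
    r = results_early_vs_late
    sig = (r["padj"] <= padj) & r["p"].notna()
    out[sig & (r["fc"] >= fc)] = "late_only"
    out[sig & (r["fc"] <= 1.0 / fc)] = "early_only"
    return out


def assign_gene_dynamic_class(genes: list[GeneModel], regions: PeakSet,
                              region_classes: pd.Series,
                              upstream: int = 500) -> pd.Series:
    """Per-gene dynamic-binding class from classified regions.

    The overlap window is the gene body plus ``upstream`` bp upstream of
    the TSS (strand-aware).  A gene with at least one early-only region
    in its window is an ``early_only_gene``; one with at least one
    late-only region and no early-only region is a ``late_only_gene``;
    one overlapping only static regions is a ``static_only_gene``.
    Genes with no region in the window are absent from the result.
    """
    region_list = list(regions)
    classes = region_classes.reindex(
        [iv.name or f"region_{i}" for i, iv in enumerate(region_list)]
    ).to_numpy()
    out = {}
    for g in genes:
        window = g.regulatory_window(upstream)
        hit_classes = {
            classes[i] for i, iv in enumerate(region_list) if iv.overlaps(window)
        }
        if not hit_classes:
            continue
        if "early_only" in hit_classes:
            out[g.gene_id] = "early_only_gene"
        elif "late_only" in hit_classes:
            out[g.gene_id] = "late_only_gene"
        else:
            out[g.gene_id] = "static_only_gene"
    return pd.Series(out, name="gene_dynamic_class", dtype=object)


def expressed_by_polii(tag_count: float, region_len_bp: int,
                       threshold: float = 10.0) -> bool:
    """Call a gene transcribed from POLII occupancy: at least
    ``threshold`` tags per 500 bp of gene body (inclusive)."""
    if region_len_bp <= 0:
        raise ValueError("region length must be > 0")
    return tag_count / (region_len_bp / 500.0) >= threshold


# ---------------------------------------------------------------------------
# categorical enrichment and set comparisons
# ---------------------------------------------------------------------------

def cluster_enrichment(gene_classes: pd.Series, cluster_assignment: pd.Series
                       ) -> pd.DataFrame:
    """Per-cluster, per-direction 2x2 enrichment (chi-square, 1 df,
    continuity-corrected; Fisher's exact when any expected cell < 5).

    ``gene_classes`` holds up/down/ns per gene; ``cluster_assignment``
    maps (a subset of) the same genes to cluster labels.  Returns one row
    per (cluster, direction) with observed, expected, fold, p and the
    test used.
    """
    genes = gene_classes.index.intersection(cluster_assignment.index)
    gc = gene_classes.loc[genes]
    ca = cluster_assignment.loc[genes]
    rows = []
    n_total = len(genes)
    for cluster in sorted(ca.unique()):
        in_cluster = ca == cluster
        for direction in ("up", "down"):
            in_dir = gc == direction
            a = int((in_cluster & in_dir).sum())
            b = int((in_cluster & ~in_dir).sum())
            c = int((~in_cluster & in_dir).sum())
            d = int((~in_cluster & ~in_dir).sum())
            expected = in_cluster.sum() * in_dir.sum() / n_total if n_total else np.nan
            table = np.array([[a, b], [c, d]])
            row_sums = table.sum(axis=1, keepdims=True)
            col_sums = table.sum(axis=0, keepdims=True)
            exp_cells = row_sums * col_sums / max(table.sum(), 1)
            if (exp_cells < 5).any():
                _, p = stats.fisher_exact(table, alternative="two-sided")
                test = "fisher"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
                test = "chi2"
            rows.append(
                {
                    "cluster": cluster,
                    "direction": direction,
                    "observed": a,
                    "expected": expected,
                    "fold": a / expected if expected else np.nan,
                    "p": p,
                    "test": test,
                }
            )
    return pd.DataFrame(rows)


def compare_regulator_sets(fc_by_gene: pd.Series, positive_set: list[str],
                           negative_set: list[str]) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of fold-changes between two
    curated gene sets (e.g. positive vs negative regulators).

    Exact enumeration when both sets have <= 8 measured genes, normal
    approximation with tie correction otherwise.
    """
    x = fc_by_gene.reindex([g for g in positive_set if g in fc_by_gene.index]).dropna()
    y = fc_by_gene.reindex([g for g in negative_set if g in fc_by_gene.index]).dropna()
    if len(x) == 0 or len(y) == 0:
        missing = [g for g in (positive_set if len(x) == 0 else negative_set)
                   if g not in fc_by_gene.index]
        raise ValueError(f"set empty after intersecting with measured genes; "
                         f"missing: {missing}")
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "median_positive": float(np.median(x)),
        "median_negative": float(np.median(y)),
        "n_positive": len(x),
        "n_negative": len(y),
        "method": method,
    }


def rank_correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman or Pearson correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)
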