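"""Interval arithmetic, peak annotation, shifted-peak nulls and enrichment.

The annotation scheme assigns each peak to exactly one category with a
fixed priority: TSS (within +/- ``tss_window`` bp of an annotated TSS),
then exon, then intron, then gene-proximal (within ``proximal_dist`` bp
of a gene), then distal.  "Overlap" always means at least 1 bp of
intersection.

Shifted-peak nulls re-place every peak uniformly at random on its own
chromosome with its length preserved, which keeps the per-chromosome
composition and the length distribution of the observed set.
"""

from __future__ import annotations

import bisect
import math

import numpy as np
from scipy import stats

from adipotf.types import GenomicInterval, GenomeLayout, GeneModel, PeakSet

ANNOTATION_CATEGORIES = ("TSS", "exon", "intron", "proximal", "distal")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_peak_calls(set_a: PeakSet, set_b: PeakSet,
                     layout: GenomeLayout | None = None,
                     name: str = "merged") -> PeakSet:
    """Union of two peak-caller outputs with overlapping or book-ended
    (0-gap) intervals coalesced into single bound regions.

    The merged region inherits the summit of the highest-scoring source
    interval; when no source interval carries a score the merged-region
    midpoint is used.
    """
    if layout is not None:
        layout.validate(set_a)
        layout.validate(set_b)
    pooled = sorted(
        list(set_a) + list(set_b), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[GenomicInterval] = []
    cluster: list[GenomicInterval] = []

    def _flush() -> None:
        if not cluster:
            return
        chrom = cluster[0].chrom
        start = min(iv.start for iv in cluster)
        end = max(iv.end for iv in cluster)
        scored = [iv for iv in cluster if iv.score is not None]
        if scored:
            best = max(scored, key=lambda iv: iv.score)
            summit = best.effective_summit
            score = best.score
        else:
            summit = (start + end) // 2
            score = None
        merged.append(
            GenomicInterval(
                chrom, start, end,
                name=f"{name}_{len(merged) + 1}",
                score=score, summit=summit,
                source=",".join(sorted({iv.source for iv in cluster if iv.source})),
            )
        )

    for iv in pooled:
        if cluster and iv.chrom == cluster[0].chrom and iv.start <= max(
            c.end for c in cluster
        ):
            cluster.append(iv)
        else:
            _flush()
            cluster = [iv]
    _flush()
    return PeakSet(merged, name=name)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_peak(peak: GenomicInterval, genes: list[GeneModel],
                  tss_window: int = 500, proximal_dist: int = 10000) -> str:
    """First matching category in the priority order
    TSS > exon > intron > proximal > distal."""
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if any(peak.overlaps(g.tss_window(tss_window)) for g in same_chrom):
        return "TSS"
    if any(peak.overlaps(ex) for g in same_chrom for ex in g.exons):
        return "exon"
    if any(peak.overlaps(g.body) for g in same_chrom):
        return "intron"
    for g in same_chrom:
        d = peak.distance_to(g.body)
        if d is not None and d <= proximal_dist:
            return "proximal"
    return "distal"


def annotate_peaks(peaks: PeakSet, genes: list[GeneModel],
                   tss_window: int = 500, proximal_dist: int = 10000
                   ) -> dict[str, str]:
    """Category per peak name; categories partition the set."""
    return {
        iv.name or f"peak_{i}": annotate_peak(iv, genes, tss_window, proximal_dist)
        for i, iv in enumerate(peaks)
    }


def assign_peaks_to_genes(peaks: PeakSet, genes: list[GeneModel],
                          max_dist: int = 10000):
    """Map every peak to every gene whose body-or-TSS lies within
    ``max_dist`` bp (distance 0 when overlapping).

    Returns ``(peak_to_genes, gene_to_peaks)`` keyed by peak index and
    gene id respectively.
    """
    peak_to_genes: dict[int, list[str]] = {i: [] for i in range(len(peaks))}
    gene_to_peaks: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    for i, iv in enumerate(peaks):
        for g in genes:
            d = iv.distance_to(g.body)
            if d is not None and d <= max_dist:
                peak_to_genes[i].append(g.gene_id)
                gene_to_peaks[g.gene_id].append(i)
    return peak_to_genes, gene_to_peaks


def closest_gene(peak: GenomicInterval, genes: list[GeneModel]
                 ) -> tuple[str, int]:
    """Gene on the peak's chromosome minimizing |summit - TSS|.

    Ties break to the lexicographically smallest gene_id.  The returned
    distance is signed: negative when the summit lies upstream of the TSS
    on the gene's strand.
    """
    if not genes:
        raise ValueError("no genes supplied")
    candidates = [g for g in genes if g.chrom == peak.chrom]
    if not candidates:
        raise ValueError(f"no genes on chromosome {peak.chrom}")
    summit = peak.effective_summit
    best = min(candidates, key=lambda g: (abs(summit - g.tss), g.gene_id))
    offset = summit - best.tss
    signed = offset if best.strand == "+" else -offset
    return best.gene_id, signed


# ---------------------------------------------------------------------------
# shifted nulls
# ---------------------------------------------------------------------------

def shift_peaks_random(peaks: PeakSet, layout: GenomeLayout,
                       seed: int | np.random.Generator) -> PeakSet:
    """Re-place every interval at a uniform random start on its own
    chromosome, preserving its length (and its summit offset)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout.validate(peaks)
    shifted = []
    for iv in peaks:
        chrom_len = layout[iv.chrom]
        if iv.length > chrom_len:
            raise ValueError(
                f"interval of length {iv.length} longer than {iv.chrom} ({chrom_len})"
            )
        new_start = int(rng.integers(0, chrom_len - iv.length + 1))
        summit = None if iv.summit is None else new_start + (iv.summit - iv.start)
        shifted.append(
            GenomicInterval(
                iv.chrom, new_start, new_start + iv.length,
                name=iv.name, score=iv.score, strand=iv.strand,
                summit=summit, source=iv.source,
            )
        )
    return PeakSet(shifted, name=f"{peaks.name}_shifted")


# ---------------------------------------------------------------------------
# overlap counting and enrichment
# ---------------------------------------------------------------------------

def overlap_peaks(set_a: PeakSet, set_b: PeakSet):
    """Number of A intervals intersecting (>= 1 bp) any B interval, plus
    the list of overlapping (index_a, index_b) pairs."""
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(set_b):
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in b_by_chrom.values():
        lst.sort()
    pairs = []
    n_overlapping = 0
    for i, iv in enumerate(set_a):
        lst = b_by_chrom.get(iv.chrom, [])
        starts = [x[0] for x in lst]
        hi = bisect.bisect_left(starts, iv.end)
        hit = False
        for (bs, be, j) in lst[:hi]:
            if be > iv.start:
                pairs.append((i, j))
                hit = True
        if hit:
            n_overlapping += 1
    return n_overlapping, pairs


def overlap_enrichment(set_a: PeakSet, set_b: PeakSet, layout: GenomeLayout,
                       n_shifts: int = 100,
                       seed: int | np.random.Generator = 0) -> dict:
    """Observed overlap of A with B against a shifted-A null.

    Returns observed and expected overlap counts, the fold enrichment,
    a two-sided Fisher's exact p on the 2x2 table contrasting real and
    (average) shifted peaks, and a permutation p-value
    ``(1 + #{shifts >= observed}) / (n_shifts + 1)``.
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed, _ = overlap_peaks(set_a, set_b)
    null_counts = np.empty(n_shifts, dtype=int)
    for s in range(n_shifts):
        null_counts[s], _ = overlap_peaks(shift_peaks_random(set_a, layout, rng), set_b)
    expected = float(null_counts.mean())
    n_a = len(set_a)
    perm_p = (1 + int((null_counts >= observed).sum())) / (n_shifts + 1)
    if expected == 0:
        fold = math.inf if observed > 0 else math.nan
        fisher_p = math.nan
    else:
        fold = observed / expected
        exp_r = int(round(expected))
        table = [[observed, n_a - observed], [exp_r, n_a - exp_r]]
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "observed": observed,
        "expected": expected,
        "fold": fold,
        "fisher_p": fisher_p,
        "perm_p": perm_p,
        "n_shifts": n_shifts,
    }


def category_enrichment(peaks: PeakSet, feature_sets: dict[str, PeakSet],
                        layout: GenomeLayout, n_shifts: int = 1,
                        seed: int | np.random.Generator = 0) -> dict[str, dict]:
    """Hypergeometric enrichment of peaks in genomic feature classes
    (promoters, CpG-like regions, exons, ...) against shifted-peak
    background.

    The universe is the observed peaks plus ``n_shifts`` shifted copies;
    successes are universe members overlapping the feature; the upper
    hypergeometric tail is reported for the observed success count among
    the real peaks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shifted_sets = [shift_peaks_random(peaks, layout, rng) for _ in range(n_shifts)]
    results: dict[str, dict] = {}
    n_real = len(peaks)
    n_universe = n_real * (1 + n_shifts)
    for fname, features in feature_sets.items():
        if len(features) == 0:
            results[fname] = {"observed": 0, "expected": math.nan,
                              "fold": math.nan, "p": 1.0}
            continue
        obs, _ = overlap_peaks(peaks, features)
        shifted_hits = sum(overlap_peaks(s, features)[0] for s in shifted_sets)
        successes = obs + shifted_hits
        expected = n_real * successes / n_universe
        p = float(stats.hypergeom.sf(obs - 1, n_universe, successes, n_real))
        fold = obs / expected if expected > 0 else math.nan
        results[fname] = {"observed": obs, "expected": expected,
                          "fold": fold, "p": p}
    return results


# ---------------------------------------------------------------------------
# summit-centered signal matrices
# ---------------------------------------------------------------------------

def summit_signal_matrix(tags_by_sample: dict[str, list[tuple[str, int, str]]],
                         summits: PeakSet, layout: GenomeLayout,
                         window: int = 2000, bin_size: int = 5,
                         extend: int = 200,
                         size_factors: dict[str, float] | None = None,
                         reference: str | None = None):
    """Normalized, log2-transformed coverage around peak summits.

    Each tag (chrom, position, strand) is extended ``extend`` bp in its
    strand direction; per-bin coverage inside a ``window`` bp region
    centered on each summit is summed, divided by the sample's size
    factor and log2(x+1)-transformed.  Rows (peaks) are ordered by
    decreasing row mean of the ``reference`` sample (first sample by
    default).

    Returns ``(matrices, order, flagged)`` where ``matrices`` maps sample
    id to a (n_peaks x window/bin) array in row order ``order`` and
    ``flagged`` lists peak indices whose window ran past a chromosome
    edge (those bins are zero).
    """
    if window % bin_size:
        raise ValueError("window must be a multiple of bin_size")
    n_bins = window // bin_size
    half = window // 2
    summit_pos = summits.summits()
    chroms = [iv.chrom for iv in summits]
    flagged = [
        i for i, iv in enumerate(summits)
        if summit_pos[i] - half < 0 or summit_pos[i] + half > layout[iv.chrom]
    ]
    if size_factors is None:
        size_factors = {s: 1.0 for s in tags_by_sample}
    matrices: dict[str, np.ndarray] = {}
    for sample, tags in tags_by_sample.items():
        sf = size_factors[sample]
        if sf <= 0:
            raise ValueError(f"size factor for {sample} must be > 0")
        mat = np.zeros((len(summits), n_bins))
        tags_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, strand in tags:
            frag = (pos, pos + extend) if strand == "+" else (pos - extend + 1, pos + 1)
            tags_by_chrom.setdefault(chrom, []).append(frag)
        for i, (chrom, center) in enumerate(zip(chroms, summit_pos)):
            w_start = center - half
            for fs, fe in tags_by_chrom.get(chrom, ()):  # fragment span
                lo = max(fs, max(w_start, 0))
                hi = min(fe, min(w_start + window, layout[chrom]))
                if lo >= hi:
                    continue
                b0 = (lo - w_start) // bin_size
                b1 = (hi - 1 - w_start) // bin_size
                for b in range(b0, b1 + 1):
                    bin_lo = w_start + b * bin_size
                    cov = min(hi, bin_lo + bin_size) - max(lo, bin_lo)
                    mat[i, b] += cov
        matrices[sample] = np.log2(mat / sf + 1.0)
    ref = reference or next(iter(tags_by_sample))
    order = np.argsort(-matrices[ref].mean(axis=1), kind="stable")
    matrices = {s: m[order] for s, m in matrices.items()}
    return matrices, order, flagged
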