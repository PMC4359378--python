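"""Permutation tests for regulatory-network targeting.

The central question: are more members of a curated network both bound
by the factor and transcriptionally regulated by its knockdown than
expected for a random gene set of the same size?  The null draws gene
sets of the network's size uniformly without replacement from a stated
universe (all expressed genes by default) and recomputes the statistic;
the permutation p-value is ``(1 + #{null >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from adipotf.types import GeneModel, PeakSet

logger = logging.getLogger("adipotf")


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold: float
    perm_p: float
    n_perm: int
    seed: int | None


def load_adipogenic_network() -> list[str]:
    """Curated adipogenic gene-regulatory-network membership shipped with
    the package (see ``data/agrn_members_synthetic.txt``; a synthetic
    reconstruction assembled from regulators named in the adipogenesis
    literature, not the study's original curation)."""
    text = (
        resources.files("adipotf.data")
        .joinpath("agrn_members_synthetic.txt")
        .read_text()
    )
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def _perm_counts(target_pool: set[str], universe: list[str], set_size: int,
                 n_perm: int, rng: np.random.Generator) -> np.ndarray:
    univ = np.asarray(universe, dtype=object)
    is_target = np.isin(univ, list(target_pool))
    counts = np.empty(n_perm, dtype=int)
    n = len(univ)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        counts[i] = int(is_target[idx].sum())
    return counts


def network_targeting_test(network: list[str], bound_genes: set[str],
                           down_genes: set[str], universe: list[str],
                           n_perm: int = 10000, seed: int = 0
                           ) -> EnrichmentResult:
    """Bound-and-regulated network members vs random gene sets.

    statistic = |network ∩ bound ∩ down|; the null redraws gene sets of
    size |network| from the universe.
    """
    universe_set = set(universe)
    kept = [g for g in network if g in universe_set]
    dropped = set(network) - set(kept)
    if dropped:
        logger.warning("dropping %d network genes absent from the universe: %s",
                       len(dropped), sorted(dropped)[:10])
    if len(kept) > len(universe_set):
        raise ValueError("network larger than the universe")
    if not kept:
        raise ValueError("no network gene is in the universe")
    targets = (bound_genes & down_genes) & universe_set
    observed = len(set(kept) & targets)
    rng = np.random.default_rng(seed)
    null = _perm_counts(targets, sorted(universe_set), len(kept), n_perm, rng)
    perm_p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    expected = len(kept) * len(targets) / len(universe_set)
    fold = observed / expected if expected > 0 else math.nan
    return EnrichmentResult(observed, expected, fold, perm_p, n_perm, seed)


def labeled_set_enrichment(candidates: list[str], labels: dict[str, bool],
                           n_perm: int = 10000, seed: int = 0
                           ) -> EnrichmentResult:
    """Enrichment of a binary label among candidate genes vs random draws
    from the labeled universe."""
    universe = sorted(labels)
    missing = [c for c in candidates if c not in labels]
    if missing:
        raise ValueError(f"candidates missing from the labeled universe: {missing}")
    labeled = {g for g, v in labels.items() if v}
    observed = len(set(candidates) & labeled)
    rate = len(labeled) / len(universe)
    expected = len(candidates) * rate
    if rate == 0:
        return EnrichmentResult(observed, 0.0, math.nan, 1.0, n_perm, seed)
    rng = np.random.default_rng(seed)
    null = _perm_counts(labeled, universe, len(candidates), n_perm, rng)
    perm_p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    fold = observed / expected
    return EnrichmentResult(observed, expected, fold, perm_p, n_perm, seed)


def annotate_network(network: list[str], bound_regions: PeakSet,
                     de_results: pd.DataFrame | None,
                     genes: list[GeneModel], flank: int = 500) -> pd.DataFrame:
    """Per-network-gene binding and regulation summary.

    ``bound_at_tss``: a bound region within ``flank`` bp of the TSS;
    ``bound_in_gene``: within ``flank`` bp of the gene body;
    ``de_class``: the differential-expression class when supplied.
    Genes absent from the gene models are flagged missing.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for gid in network:
        g = gene_by_id.get(gid)
        if g is None:
            rows.append({"gene_id": gid, "missing": True, "bound_at_tss": False,
                         "bound_in_gene": False, "de_class": "na"})
            continue
        tss_win = g.tss_window(flank)
        bound_at_tss = any(iv.overlaps(tss_win) for iv in bound_regions)
        bound_in_gene = any(
            (d := iv.distance_to(g.body)) is not None and d <= flank
            for iv in bound_regions
        )
        de_class = "na"
        if de_results is not None and gid in de_results.index:
            de_class = str(de_results.loc[gid, "class"])
        rows.append({"gene_id": gid, "missing": False, "bound_at_tss": bound_at_tss,
                     "bound_in_gene": bound_in_gene, "de_class": de_class})
    return pd.DataFrame(rows).set_index("gene_id")
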