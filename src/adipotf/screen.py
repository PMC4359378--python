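"""Arrayed overexpression-screen analysis.

Each well of the screen reports a total cell count and the number of
differentiated cells (cells with at least four lipid droplets); their
ratio is the per-well fraction of differentiated cells (PDC).  Within
each replicate, wells are standardized against the negative-control
wells (z-score against control mean and sd).  Per-construct replicate
z-scores are combined (Stouffer by default), converted to two-sided
normal p-values, Bonferroni-corrected over all non-control constructs,
and a construct is called a hit when its fold-change over the pooled
control PDC reaches ``fc_threshold`` and the corrected p-value is at
most ``alpha``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("adipotf")


@dataclass
class ScreenResult:
    construct_id: str
    pdc_mean: float
    fc: float
    z_per_replicate: list[float] = field(default_factory=list)
    combined_p: float = math.nan
    p_bonferroni: float = math.nan
    is_hit: bool = False
    n_replicates: int = 0
    incomplete: bool = False   # missing from at least one replicate


def compute_pdc(n_diff_cells: int, n_total_cells: int) -> float:
    """Fraction of differentiated cells in a well."""
    if n_total_cells <= 0:
        raise ValueError("empty well: n_total_cells must be > 0")
    if not 0 <= n_diff_cells <= n_total_cells:
        raise ValueError("n_diff_cells must lie in [0, n_total_cells]")
    return n_diff_cells / n_total_cells


def pdc_from_droplet_counts(droplets_per_cell, threshold: int = 4) -> float:
    """PDC from per-cell lipid-droplet counts: a cell is differentiated
    when it has at least ``threshold`` droplets."""
    droplets = list(droplets_per_cell)
    if not droplets:
        raise ValueError("empty well")
    return sum(d >= threshold for d in droplets) / len(droplets)


def normalize_replicate(pdc_values: np.ndarray,
                        control_pdc_values: np.ndarray) -> np.ndarray:
    """Standardize a replicate's PDC values against its negative controls:
    z = (pdc - mean(controls)) / sd(controls)."""
    controls = np.asarray(control_pdc_values, dtype=float)
    if len(controls) < 2:
        raise ValueError("need >= 2 negative-control wells per replicate")
    mu = controls.mean()
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("negative controls have zero variance")
    return (np.asarray(pdc_values, dtype=float) - mu) / sd


def _with_pdc(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["pdc"] = table.n_diff_cells / table.n_total_cells
    return table


def fold_change_table(table: pd.DataFrame) -> pd.Series:
    """Per-construct fold-change: mean construct PDC divided by the mean
    PDC over all negative-control wells pooled across replicates."""
    table = _with_pdc(table)
    control_mean = table.loc[table.is_negative_control, "pdc"].mean()
    if not control_mean > 0:
        raise ValueError("pooled negative-control mean PDC is zero")
    means = table.loc[~table.is_negative_control].groupby("construct_id")["pdc"].mean()
    return (means / control_mean).rename("fc")


def call_hits(table: pd.DataFrame, fc_threshold: float = 1.5,
              alpha: float = 0.05, combine: str = "stouffer"
              ) -> list[ScreenResult]:
    """Call differentiation-enhancing constructs.

    ``combine`` selects the replicate-combination rule:

    * ``"stouffer"`` (default): combined z = mean(z_r) * sqrt(n_replicates),
      two-sided normal p, Bonferroni over non-control constructs.
    * ``"all-significant"``: every replicate individually significant at
      the Bonferroni-corrected two-sided level.

    Results are sorted by fold-change, descending.
    """
    table = _with_pdc(table)
    replicates = sorted(table.replicate.unique())
    z_by_construct: dict[str, list[float]] = {}
    present: dict[str, int] = {}
    for rep in replicates:
        sub = table[table.replicate == rep]
        controls = sub.loc[sub.is_negative_control, "pdc"].to_numpy()
        if len(controls) < 2:
            raise ValueError(f"replicate {rep}: needs >= 2 negative-control wells")
        tests = sub.loc[~sub.is_negative_control]
        means = tests.groupby("construct_id")["pdc"].mean()
        z = normalize_replicate(means.to_numpy(), controls)
        for cid, zval in zip(means.index, z):
            z_by_construct.setdefault(cid, []).append(float(zval))
            present[cid] = present.get(cid, 0) + 1

    n_constructs = len(z_by_construct)
    fcs = fold_change_table(table)
    pdc_means = table.loc[~table.is_negative_control].groupby("construct_id")["pdc"].mean()

    results = []
    for cid, zs in z_by_construct.items():
        n = len(zs)
        incomplete = n < len(replicates)
        if incomplete:
            logger.warning("construct %s present in %d/%d replicates",
                           cid, n, len(replicates))
        z_comb = float(np.mean(zs) * math.sqrt(n))
        p_comb = float(2.0 * stats.norm.sf(abs(z_comb)))
        p_bonf = min(1.0, p_comb * n_constructs)
        if combine == "stouffer":
            significant = p_bonf <= alpha
        elif combine == "all-significant":
            rep_p = 2.0 * stats.norm.sf(np.abs(zs))
            significant = bool((np.minimum(1.0, rep_p * n_constructs) <= alpha).all())
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
        fc = float(fcs[cid])
        results.append(
            ScreenResult(
                construct_id=cid,
                pdc_mean=float(pdc_means[cid]),
                fc=fc,
                z_per_replicate=zs,
                combined_p=p_comb,
                p_bonferroni=p_bonf,
                is_hit=bool(significant and fc >= fc_threshold),
                n_replicates=n,
                incomplete=incomplete,
            )
        )
    results.sort(key=lambda r: -r.fc)
    return results


def results_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "construct_id": [r.construct_id for r in results],
            "pdc_mean": [r.pdc_mean for r in results],
            "fc": [r.fc for r in results],
            "z_per_replicate": [",".join(f"{z:.4f}" for z in r.z_per_replicate)
                                for r in results],
            "combined_p": [r.combined_p for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "is_hit": [r.is_hit for r in results],
            "n_replicates": [r.n_replicates for r in results],
            "incomplete": [r.incomplete for r in results],
        }
    )
    return df


def control_summary(table: pd.DataFrame) -> dict:
    """Pooled negative-control PDC mean and sd (diagnostics)."""
    table = _with_pdc(table)
    controls = table.loc[table.is_negative_control, "pdc"]
    return {
        "mean_pdc": float(controls.mean()),
        "sd_pdc": float(controls.std(ddof=1)),
        "n_wells": int(len(controls)),
    }
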