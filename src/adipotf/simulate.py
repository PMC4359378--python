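"""Synthetic data with known planted structure.

Every generator is a pure function of its configuration and seed, and
every planted feature is recorded in an exact truth table, so each
downstream analysis stage can be scored against ground truth:

* a toy genome with non-overlapping genes (1-5 exons each) and i.i.d.
  background sequence at a configurable GC content;
* a four-timepoint peak time course (days -2, 0, 2, 4) with planted
  static / early-only / late-only regions, planted co-binding with a
  second factor (summits within 100 bp), and per-timepoint expected tag
  counts encoding the planted fold-change;
* negative-binomial count matrices (variance = mean + dispersion *
  mean**2) with per-sample library-size multipliers;
* peak sequences with consensus motif instances planted near summits;
* replicated screen plates with negative-control wells and planted
  differentiation enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from adipotf import io as aio
from adipotf.types import CountMatrix, GeneModel, GenomicInterval, GenomeLayout, PeakSet

logger = logging.getLogger("adipotf")

TIMEPOINTS = ("day-2", "day0", "day2", "day4")
EARLY_TIMEPOINTS = TIMEPOINTS[:2]
LATE_TIMEPOINTS = TIMEPOINTS[2:]

#: consensus E-box recognised by ZEB-family zinc-finger TFs
EBOX_CONSENSUS = "CACCTG"


@dataclass
class ScreenConfig:
    n_constructs: int = 734
    n_neg_controls: int = 16          # control wells per replicate
    n_replicates: int = 3
    control_pdc_mean: float = 0.479   # fraction of differentiated control cells
    control_pdc_sd: float = 0.05
    planted_effect_sd_units: float = 10.0
    planted_fc: float = 2.0
    n_planted_hits: int = 26
    cells_per_well: int = 1000

    def validate(self) -> None:
        if min(self.n_constructs, self.n_neg_controls, self.n_replicates,
               self.cells_per_well) <= 0:
            raise ValueError("screen counts must be > 0")
        if not 0 < self.control_pdc_mean < 1:
            raise ValueError("control_pdc_mean must be in (0, 1)")
        if (self.control_pdc_mean - 4 * self.control_pdc_sd < 0
                or self.control_pdc_mean + 4 * self.control_pdc_sd > 1):
            logger.warning(
                "control PDC mean +/- 4 sd leaves [0, 1]; truncation will bias wells"
            )
        planted = self.planted_mean_pdc()
        fc_realized = planted / self.control_pdc_mean
        if abs(fc_realized - self.planted_fc) / self.planted_fc > 0.1:
            logger.warning(
                "planted shift gives fold-change %.2f vs configured planted_fc %.2f",
                fc_realized, self.planted_fc,
            )

    def planted_mean_pdc(self) -> float:
        return min(
            0.99,
            self.control_pdc_mean
            + self.planted_effect_sd_units * self.control_pdc_sd,
        )


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 500_000
    n_genes: int = 150
    n_peaks: int = 600
    peak_len_mean: int = 300
    frac_cobound: float = 0.3
    frac_early_only: float = 0.1
    frac_late_only: float = 0.15
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    depth_mean: float = 50.0          # expected tags per peak at bound timepoints
    seq_gc: float = 0.42
    motif_plant_rate: float = 0.4
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def validate(self) -> None:
        for name in ("frac_cobound", "frac_early_only", "frac_late_only",
                     "seq_gc", "motif_plant_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_early_only + self.frac_late_only > 1:
            raise ValueError("frac_early_only + frac_late_only must be <= 1")
        if min(self.n_chrom, self.chrom_len, self.n_genes, self.n_peaks,
               self.peak_len_mean) <= 0:
            raise ValueError("all counts must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        self.screen.validate()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None):
    """Toy genome: layout, non-overlapping gene models, and sequences.

    Returns ``(layout, genes, sequences)``.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    layout = GenomeLayout({c: config.chrom_len for c in chroms})

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    max_tries = 200 * config.n_genes
    tries = 0
    for i in range(config.n_genes):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not place genes without overlap; reduce n_genes "
                    "or increase chrom_len"
                )
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(2000, 10001))
            start = int(rng.integers(0, config.chrom_len - length))
            if all(e <= start or s >= start + length
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                break
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(
            np.arange(1, length), size=2 * n_exons, replace=False))
        exons = tuple(
            GenomicInterval(chrom, start + int(cuts[2 * k]), start + int(cuts[2 * k + 1]))
            for k in range(n_exons)
        )
        body = GenomicInterval(chrom, start, start + length)
        tss = start if strand == "+" else start + length - 1
        genes.append(GeneModel(f"gene{i + 1:04d}", chrom, strand, tss, body, exons))
    genes.sort(key=lambda g: (g.chrom, g.body.start, g.gene_id))

    probs = np.array([
        (1 - config.seq_gc) / 2, config.seq_gc / 2,
        config.seq_gc / 2, (1 - config.seq_gc) / 2,
    ])
    bases = np.array(list("ACGT"))
    sequences = {
        c: "".join(bases[rng.choice(4, size=config.chrom_len, p=probs)])
        for c in chroms
    }
    return layout, genes, sequences


# ---------------------------------------------------------------------------
# peak time course
# ---------------------------------------------------------------------------

def generate_peak_timecourse(config: SyntheticConfig, layout: GenomeLayout,
                             rng: np.random.Generator | None = None):
    """Peak sets per timepoint with exact planted structure.

    Returns ``(peaks_by_timepoint, all_regions, truth, second_factor)``:

    * ``peaks_by_timepoint`` maps each timepoint to the PeakSet of regions
      present there (early-only regions appear only on days -2/0,
      late-only regions only on days 2/4);
    * ``truth`` is a DataFrame with one row per region carrying its class,
      co-binding flag and expected tag count per timepoint (the planted
      fold-change ``2**planted_log2fc``);
    * ``second_factor`` is the co-binding factor's PeakSet (summits of
      co-bound pairs within 100 bp) plus independent background peaks.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    chroms = list(layout.lengths)
    n = config.n_peaks
    n_early = int(round(config.frac_early_only * n))
    n_late = int(round(config.frac_late_only * n))
    classes = (["early_only"] * n_early + ["late_only"] * n_late
               + ["static"] * (n - n_early - n_late))
    rng.shuffle(classes)
    n_cobound = int(round(config.frac_cobound * n))
    cobound_idx = set(rng.choice(n, size=n_cobound, replace=False).tolist())

    # dynamic regions sit at depth_mean in their low state and at
    # depth_mean * 2**planted_log2fc in their bound state, so every
    # region carries at least depth_mean expected tags
    fold = 2.0 ** config.planted_log2fc
    high_depth = config.depth_mean * fold

    records = []
    intervals = []
    partner = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = max(50, int(rng.normal(config.peak_len_mean,
                                        config.peak_len_mean / 10)))
        length = min(length, layout[chrom])
        start = int(rng.integers(0, layout[chrom] - length + 1))
        summit_off = int(rng.integers(length // 4, 3 * length // 4))
        summit = start + summit_off
        iv = GenomicInterval(chrom, start, start + length,
                             name=f"peak{i + 1:05d}", score=float(rng.uniform(5, 50)),
                             summit=summit, source="sim")
        intervals.append(iv)
        klass = classes[i]
        if klass == "early_only":
            means = dict.fromkeys(EARLY_TIMEPOINTS, high_depth) | \
                dict.fromkeys(LATE_TIMEPOINTS, config.depth_mean)
        elif klass == "late_only":
            means = dict.fromkeys(EARLY_TIMEPOINTS, config.depth_mean) | \
                dict.fromkeys(LATE_TIMEPOINTS, high_depth)
        else:
            means = dict.fromkeys(TIMEPOINTS, config.depth_mean)
        is_cob = i in cobound_idx
        if is_cob:
            offset = int(rng.integers(-100, 101))
            p_summit = min(max(summit + offset, 25), layout[chrom] - 26)
            partner.append(
                GenomicInterval(
                    chrom, max(0, p_summit - length // 2),
                    min(layout[chrom], p_summit + length // 2),
                    name=f"partner_{iv.name}", score=float(rng.uniform(5, 50)),
                    summit=p_summit, source="sim2",
                )
            )
        records.append(
            {"peak_id": iv.name, "chrom": chrom, "start": iv.start, "end": iv.end,
             "summit": summit, "class": klass, "cobound": is_cob,
             **{f"mean_{tp}": means[tp] for tp in TIMEPOINTS}}
        )
    # independent background peaks for the second factor
    for j in range(n // 2):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = max(50, int(rng.normal(config.peak_len_mean,
                                        config.peak_len_mean / 10)))
        start = int(rng.integers(0, layout[chrom] - length + 1))
        partner.append(
            GenomicInterval(chrom, start, start + length,
                            name=f"partner_bg{j + 1:05d}",
                            score=float(rng.uniform(5, 50)),
                            summit=start + length // 2, source="sim2")
        )

    truth = pd.DataFrame(records).set_index("peak_id")
    peaks_by_tp = {}
    for tp in TIMEPOINTS:
        members = []
        for iv, rec in zip(intervals, records):
            klass = rec["class"]
            if klass == "static":
                members.append(iv)
            elif klass == "early_only" and tp in EARLY_TIMEPOINTS:
                members.append(iv)
            elif klass == "late_only" and tp in LATE_TIMEPOINTS:
                members.append(iv)
        peaks_by_tp[tp] = PeakSet(members, name=f"factor_{tp}")
    all_regions = PeakSet(intervals, name="factor_all")
    second = PeakSet(partner, name="second_factor")
    return peaks_by_tp, all_regions, truth, second


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def nb_draw(rng: np.random.Generator, mean: np.ndarray,
            dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean**2); Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("negative means")
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def generate_counts(means: pd.DataFrame, design: pd.DataFrame,
                    dispersion: float = 0.1,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> CountMatrix:
    """Draw a count matrix from per-feature, per-condition expected means.

    ``means`` is features x conditions; ``design`` is indexed by sample id
    with columns ``condition``, ``replicate`` and optionally
    ``lib_factor`` (per-sample library-size multiplier, default 1).
    """
    rng = rng or np.random.default_rng(seed)
    counts = {}
    for sample_id, row in design.iterrows():
        mu = means[row["condition"]].to_numpy(dtype=float)
        lib = float(row.get("lib_factor", 1.0)) if "lib_factor" in design.columns else 1.0
        counts[sample_id] = nb_draw(rng, mu * lib, dispersion)
    counts_df = pd.DataFrame(counts, index=means.index)
    samples = design[[c for c in ("condition", "replicate", "timepoint")
                      if c in design.columns]].copy()
    return CountMatrix(counts_df, samples)


def timecourse_design(replicates_per_condition: int = 2,
                      lib_factors: dict[str, float] | None = None) -> pd.DataFrame:
    """Early-vs-late design mirroring a differentiation time course in
    which pre-induction days act as 'early' replicates and post-induction
    days as 'late' replicates."""
    rows = []
    for cond in ("early", "late"):
        for r in range(1, replicates_per_condition + 1):
            rows.append({"sample_id": f"{cond}{r}", "condition": cond, "replicate": r})
    design = pd.DataFrame(rows).set_index("sample_id")
    if lib_factors:
        design["lib_factor"] = [lib_factors.get(s, 1.0) for s in design.index]
    return design


def timecourse_means(truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-timepoint truth means to early/late condition means."""
    early = truth[[f"mean_{tp}" for tp in EARLY_TIMEPOINTS]].mean(axis=1)
    late = truth[[f"mean_{tp}" for tp in LATE_TIMEPOINTS]].mean(axis=1)
    return pd.DataFrame({"early": early, "late": late})


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------

def plant_motifs(sequences: dict[str, str], peaks: PeakSet,
                 consensus: str = EBOX_CONSENSUS, rate: float | None = None,
                 max_offset: int = 50,
                 rng: np.random.Generator | None = None, seed: int = 0):
    """Insert exact consensus instances at summit +/- U(0, max_offset).

    The instance is kept entirely inside the ``2 * max_offset`` bp
    summit-centered window (offsets run from -max_offset to
    max_offset - len(consensus)), so a scan of that window can recover
    every planted copy.

    Returns ``(sequences, planted)`` where ``planted`` maps peak name to
    the absolute motif start (or None when the peak got no instance).
    """
    rng = rng or np.random.default_rng(seed)
    rate = 1.0 if rate is None else rate
    mutable = {c: list(s) for c, s in sequences.items()}
    planted: dict[str, int | None] = {}
    for iv in peaks:
        if rng.random() > rate:
            planted[iv.name] = None
            continue
        offset = int(rng.integers(-max_offset, max_offset - len(consensus) + 1))
        start = iv.effective_summit + offset
        start = min(max(start, 0), len(mutable[iv.chrom]) - len(consensus))
        mutable[iv.chrom][start:start + len(consensus)] = list(consensus)
        planted[iv.name] = start
    return {c: "".join(s) for c, s in mutable.items()}, planted


# ---------------------------------------------------------------------------
# screen plates
# ---------------------------------------------------------------------------

def generate_screen(config: ScreenConfig,
                    rng: np.random.Generator | None = None,
                    seed: int = 0):
    """Replicated screen plates with planted enhancers.

    Negative-control wells draw PDC from a truncated
    Normal(control_pdc_mean, control_pdc_sd); non-hit constructs draw
    from the same distribution; planted enhancers are shifted upward by
    ``planted_effect_sd_units * control_pdc_sd`` (with the defaults this
    realizes approximately the configured ``planted_fc``).

    Returns ``(table, truth_hits)``.
    """
    config.validate()
    rng = rng or np.random.default_rng(seed)
    construct_ids = [f"TF{i + 1:04d}" for i in range(config.n_constructs)]
    if config.n_planted_hits > config.n_constructs:
        raise ValueError("more planted hits than constructs")
    truth_hits = sorted(
        rng.choice(construct_ids, size=config.n_planted_hits, replace=False).tolist()
    )
    hit_set = set(truth_hits)
    planted_mean = config.planted_mean_pdc()

    def draw_pdc(mean: float) -> float:
        return float(np.clip(rng.normal(mean, config.control_pdc_sd), 0.0, 1.0))

    rows = []
    for rep in range(1, config.n_replicates + 1):
        for c in range(config.n_neg_controls):
            pdc = draw_pdc(config.control_pdc_mean)
            rows.append(
                {"plate": f"p{rep}", "well": f"C{c + 1:03d}", "construct_id": "CTRL",
                 "replicate": rep, "n_total_cells": config.cells_per_well,
                 "n_diff_cells": int(round(pdc * config.cells_per_well)),
                 "is_negative_control": True}
            )
        for cid in construct_ids:
            mean = planted_mean if cid in hit_set else config.control_pdc_mean
            pdc = draw_pdc(mean)
            rows.append(
                {"plate": f"p{rep}", "well": f"W{cid[2:]}", "construct_id": cid,
                 "replicate": rep, "n_total_cells": config.cells_per_well,
                 "n_diff_cells": int(round(pdc * config.cells_per_well)),
                 "is_negative_control": False}
            )
    return pd.DataFrame(rows), truth_hits


# ---------------------------------------------------------------------------
# complete fixture directory
# ---------------------------------------------------------------------------

def write_fixture_dir(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate one complete synthetic study and write every dialect.

    Returns a dict of the in-memory objects for convenience.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    layout, genes, sequences = generate_genome(config, rng)
    peaks_by_tp, all_regions, truth, second = generate_peak_timecourse(
        config, layout, rng)
    sequences, planted_motifs = plant_motifs(
        sequences, all_regions, rate=config.motif_plant_rate, rng=rng)
    design = timecourse_design()
    matrix = generate_counts(timecourse_means(truth), design,
                             dispersion=config.nb_dispersion, rng=rng)
    screen_table, screen_truth = generate_screen(config.screen, rng=rng)

    aio.write_layout(layout, out / "layout.tsv")
    aio.write_genes(genes, out / "genes.tsv")
    aio.write_sequences(sequences, out / "genome.fa")
    for tp, ps in peaks_by_tp.items():
        aio.write_peaks(ps, out / f"peaks_{tp}.bed")
    aio.write_peaks(all_regions, out / "peaks_all.bed")
    aio.write_peaks(second, out / "peaks_second_factor.bed")
    truth.to_csv(out / "peak_truth.tsv", sep="\t")
    aio.write_counts(matrix, out / "counts.tsv")
    aio.write_screen_table(screen_table, out / "screen.tsv")
    aio.write_gene_set(screen_truth, out / "screen_truth.txt")
    pd.Series(planted_motifs, name="motif_start").to_csv(
        out / "motif_truth.tsv", sep="\t", index_label="peak_id")
    return {
        "layout": layout, "genes": genes, "sequences": sequences,
        "peaks_by_timepoint": peaks_by_tp, "all_regions": all_regions,
        "truth": truth, "second_factor": second, "counts": matrix,
        "screen_table": screen_table, "screen_truth": screen_truth,
        "motif_truth": planted_motifs,
    }
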