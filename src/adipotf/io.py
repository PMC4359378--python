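"""Readers and writers for every on-disk dialect, plus configuration.

Dialects (all plain text, tab-separated unless noted):

* ``peak_bed`` — BED6+2: chrom, start, end, name, score, strand,
  summit_offset (relative to start; ``.`` if absent), source_caller.
* ``gene_table`` — gene_id, chrom, strand, tss, body_start, body_end,
  exon_starts, exon_ends (comma-joined).
* ``counts`` — features x samples with a header row, plus a sidecar
  ``<path>.samples.tsv`` with sample_id, condition, replicate.
* ``screen_table`` — plate, well, construct_id, replicate,
  n_total_cells, n_diff_cells, is_negative_control.
* ``gene_set`` — one gene id per line.
* ``sequences`` — FASTA (via Biopython).

Coordinates on disk are 0-based half-open, matching memory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from adipotf.types import CountMatrix, GeneModel, GenomicInterval, GenomeLayout, PeakSet

logger = logging.getLogger("adipotf")

#: Every analysis threshold with its default, mirrored by the config file.
DEFAULT_CONFIG: dict = {
    "fc_screen": 1.5,        # min fold-change over pooled controls for a screen hit
    "alpha_screen": 0.05,    # Bonferroni family-wise error rate for the screen
    "fc_de": 1.5,            # differential-expression fold-change threshold
    "padj_de": 0.01,         # BH-adjusted p threshold for expression
    "fc_dyn": 2.0,           # dynamic-binding fold-change threshold
    "padj_dyn": 0.1,         # BH-adjusted p threshold for dynamic binding
    "tss_window": 500,       # bp around the TSS counted as promoter
    "proximal_dist": 10000,  # bp defining gene-proximal peaks
    "pwm_cutoff": 0.85,      # fractional PWM score cutoff
    "polii_expr_threshold": 10.0,  # POLII tags per 500 bp calling a gene expressed
    "screen_combine": "stouffer",  # replicate combination rule
}


class DialectError(ValueError):
    """Raised when a file does not parse under its declared dialect."""


def _parse_error(path, lineno, msg) -> DialectError:
    return DialectError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# peaks (BED6+2)
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED6+2 peak file into a sorted :class:`PeakSet`.

    The on-disk summit_offset is relative to ``start``; it is resolved to
    an absolute summit in memory.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise _parse_error(path, lineno, f"expected 8 fields, got {len(fields)}")
            chrom, start, end, pname, score, strand, summit_off, source = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise _parse_error(path, lineno, "non-integer coordinates") from None
            if start_i >= end_i:
                raise _parse_error(path, lineno, f"start {start_i} >= end {end_i}")
            summit = None
            if summit_off != ".":
                summit = start_i + int(summit_off)
                if not (start_i <= summit < end_i):
                    raise _parse_error(
                        path, lineno, f"summit {summit} outside [{start_i},{end_i})"
                    )
            intervals.append(
                GenomicInterval(
                    chrom,
                    start_i,
                    end_i,
                    name=pname,
                    score=None if score == "." else float(score),
                    strand=strand,
                    summit=summit,
                    source=source,
                )
            )
    if not intervals:
        logger.warning("peak file %s is empty", path)
    return PeakSet(intervals, name=name or path.stem)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            score = "." if iv.score is None else f"{iv.score:g}"
            summit_off = "." if iv.summit is None else str(iv.summit - iv.start)
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        score,
                        iv.strand,
                        summit_off,
                        iv.source or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_COLS = [
    "gene_id", "chrom", "strand", "tss",
    "body_start", "body_end", "exon_starts", "exon_ends",
]


def read_genes(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLS:
            raise _parse_error(path, 1, f"bad gene-table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_GENE_COLS):
                raise _parse_error(path, lineno, "wrong field count")
            gid, chrom, strand, tss, bs, be, ex_s, ex_e = fields
            starts = [int(x) for x in ex_s.split(",") if x]
            ends = [int(x) for x in ex_e.split(",") if x]
            if len(starts) != len(ends):
                raise _parse_error(path, lineno, "exon_starts/exon_ends length mismatch")
            exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
            try:
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        chrom=chrom,
                        strand=strand,
                        tss=int(tss),
                        body=GenomicInterval(chrom, int(bs), int(be)),
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id))


def write_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tss),
                        str(g.body.start),
                        str(g.body.end),
                        ",".join(str(e.start) for e in g.exons),
                        ",".join(str(e.end) for e in g.exons),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# counts + sample sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".samples.tsv")


def read_counts(path: str | Path) -> CountMatrix:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(_sidecar(path), sep="\t", index_col="sample_id")
    return CountMatrix(counts, samples)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")
    matrix.samples.to_csv(_sidecar(path), sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# screen table
# ---------------------------------------------------------------------------

_SCREEN_COLS = [
    "plate", "well", "construct_id", "replicate",
    "n_total_cells", "n_diff_cells", "is_negative_control",
]


def read_screen_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "plate": str, "well": str, "construct_id": str, "replicate": int,
            "n_total_cells": int, "n_diff_cells": int, "is_negative_control": bool,
        },
    )
    if list(df.columns) != _SCREEN_COLS:
        raise DialectError(f"{path}: bad screen-table header: {list(df.columns)}")
    bad = df[(df.n_diff_cells < 0) | (df.n_diff_cells > df.n_total_cells)]
    if len(bad):
        raise DialectError(
            f"{path}: n_diff_cells outside [0, n_total_cells] for wells "
            f"{bad.well.tolist()}"
        )
    return df


def write_screen_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, _SCREEN_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets, sequences, layout
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    seen = set()
    out = []
    for g in ids:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_set(ids, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ids:
            fh.write(f"{g}\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sequences(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_layout(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout(dict(zip(df.chrom, df.length.astype(int))))


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ln in layout.lengths.items():
            fh.write(f"{chrom}\t{ln}\n")


# ---------------------------------------------------------------------------
# config + run manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None) -> dict:
    """Analysis thresholds; file values override the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise DialectError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_manifest(path: str | Path, *, subcommand: str, inputs: dict,
                   parameters: dict, seed: int | None) -> None:
    """Machine-readable record of a pipeline invocation."""
    from adipotf import __version__

    manifest = {
        "tool": "adipotf",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
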