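# adipotf

Statistical toolkit for transcription-factor overexpression screens and
TF binding analysis in adipocyte differentiation.

## Scientific problem

Which transcription factors drive the differentiation of fat-cell
precursors into adipocytes? A typical study combines several assays,
each with its own statistical machinery:

- an **arrayed overexpression screen**: hundreds of TF constructs, one
  per well, scored by the percentage of differentiated cells (PDC — the
  fraction of imaged cells with ≥ 4 lipid droplets). Hits are constructs
  that raise PDC ≥ 1.5-fold over negative controls with a
  Bonferroni-corrected combined p ≤ 0.05;
- **ChIP-seq time courses** of a candidate factor before and after the
  induction of differentiation: bound regions are merged across time
  points, annotated against gene models (TSS > exon > intron >
  proximal > distal), classified as early-only / late-only / static
  binding via a negative-binomial test on per-region tag counts, and
  compared with a second factor's peaks against a shifted-peak null;
- **motif analysis**: PWM scanning of summit-centered windows for
  E-box (CACCTG) instances, with positional density profiles;
- **network tests**: permutation tests asking whether a curated
  adipogenic gene-regulatory network is bound and regulated by the
  factor more often than random gene sets.

`adipotf` implements this pipeline as a tested, reusable library with a
CLI, together with a synthetic-data generator that plants known effects
(screen hits, dynamic regions, fold changes, motif instances) so every
estimator can be validated against ground truth.

## Worked example

Generate a synthetic study (734-construct screen with 26 planted hits,
a 600-region binding time course, genome with planted E-boxes), then
analyze it:

```bash
adipotf --seed 7 --out-dir demo simulate
adipotf --seed 7 --out-dir demo screen-call --screen-table demo/screen.tsv
adipotf --seed 7 --out-dir demo dyn-bind --counts demo/counts.tsv
adipotf --seed 7 --out-dir demo annotate --peaks demo/peaks_all.bed --genes demo/genes.tsv
```

which prints:

```text
fixture written to demo
26 hits / 734 constructs -> demo/screen_results.tsv
dynamic classes: {'static': 440, 'late_only': 88, 'early_only': 72} -> demo/dynamic_binding.tsv
annotated 600 peaks -> demo/annotation.tsv
```

The same analysis from Python:

```python
import numpy as np
from adipotf import io as aio, screen, counts as cs, motifs

table = aio.read_screen_table("demo/screen.tsv")
ctrl = screen.control_summary(table)
print(f"control wells: {ctrl['n_wells']}, mean PDC {100*ctrl['mean_pdc']:.1f}%")

results = screen.call_hits(table)          # z-normalize, Stouffer, Bonferroni
hits = [r for r in results if r.is_hit]
print(f"hits: {len(hits)} / {len(results)} constructs "
      f"(top fc {hits[0].fc:.2f}, construct {hits[0].construct_id})")

matrix = aio.read_counts("demo/counts.tsv")
res = cs.nb_differential_test(matrix, "early", "late")
res["dynamic_class"] = cs.classify_dynamic_regions(res)
print(res["dynamic_class"].value_counts().to_dict())

seqs = aio.read_sequences("demo/genome.fa")
peaks = aio.read_peaks("demo/peaks_all.bed")
pwm = motifs.PWM.from_consensus("CACCTG")
print(f"peaks with an E-box within 100 bp of the summit: "
      f"{motifs.peaks_with_hits(peaks, seqs, pwm, cutoff=0.85):.1%}")
```

output:

```text
control wells: 48, mean PDC 47.0%
hits: 26 / 734 constructs (top fc 2.13, construct TF0139)
{'static': 440, 'late_only': 88, 'early_only': 72}
peaks with an E-box within 100 bp of the summit: 46.3%
```

Other subcommands: `overlap-enrich` (co-binding vs a shifted-peak
null), `diff-expr` (up/down classification at FC ≥ 1.5 / ≤ 0.67,
padj ≤ 0.01), `motif-scan`, `grn-test`. Every subcommand writes TSV
results plus a JSON run manifest and is deterministic under `--seed`.

## Package layout

- `adipotf.types` — interval / gene-model / count-matrix data types
  (0-based half-open coordinates throughout)
- `adipotf.io` — TSV/BED/FASTA dialects with strict validation
- `adipotf.screen` — PDC, plate normalization, hit calling
- `adipotf.intervals` — merging, annotation, peak–gene assignment,
  shifted-peak nulls, overlap and category enrichment, signal matrices
- `adipotf.counts` — size factors, exact-style NB differential test,
  DE / dynamic-region classification, rank tests
- `adipotf.motifs` — PWMs, scanning, density profiles
- `adipotf.grn` — permutation tests for network targeting
- `adipotf.simulate` — synthetic studies with planted ground truth

See `docs/methods.md` for the statistical model, parameter defaults,
and limitations.

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities
(planted-hit recovery, null-screen FWER, dynamic-region
sensitivity/specificity, NB calibration, effect-size bias, size-factor
recovery, permutation sanity) and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

One acceptance test additionally verifies published screen numbers
against the deposited arrayed-screen PDC table. That table is an
external download and is not shipped; place it at
`data/external/screen_pdc.tsv` (columns: plate, well, construct_id,
replicate, n_total_cells, n_diff_cells, is_negative_control) or point
`ADIPOTF_DEPOSITED_SCREEN` at it. Without the file that single test
fails with an explanatory message; all synthetic-truth validation runs
offline.
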