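# mukcoloc

Quantitative analysis pipelines for studying how the *Escherichia coli* SMC
complex **MukBEF**, the Ter-macrodomain organizer **MatP/matS**, and the
decatenase **topoisomerase IV** coordinate chromosome segregation — built for
microscopists and genomicists who need the four measurements below from
fluorescence snapshots, time-lapse movies, and ChIP-seq coverage, plus a
synthetic-data generator that makes every stage testable against known ground
truth.

## What it computes

**1. Focus colocalization with a random-pixel null** (`mukcoloc.colocalization`).
For each segmented cell with foci in two channels, the statistic is the
shortest centroid distance

d(cell) = min over (a, b) pairs of ‖x_a − x_b‖ · pixel_size,

and two labels "colocalize" when d ≤ 258 nm (2 pixels at 129 nm/px,
inclusive). Percentages are conditional on cells having foci in both
channels. The null draws pixel positions uniformly from the same cell masks
and measures the distance from the nearest reference-channel centroid, so
confinement alone cannot masquerade as colocalization. Foci come from 2D
Gaussian fitting (`mukcoloc.imaging`): an isotropic Gaussian plus constant
offset, least squares, sub-pixel centroids, with per-cell brightest-pixel
extraction for sparse labels.

**2. Repletion kinetics** (`mukcoloc.repletion`). After induction of an SMC
subunit, focus formation is tracked by mean brightest-pixel intensity and
the fraction of cells with foci. Series can be adjusted to signal per
focus-competent cell (divide by the strain's steady-state focus fraction,
e.g. 0.99 vs 0.47), initial rates are OLS slopes over the linear window
(default 0–20 min), and strains are compared by slope ratios.

**3. Sister-locus cohesion time** (`mukcoloc.cohesion`). From 5-min-interval
movies: the replisome (DnaN) focus end is the start of its terminal absence
run (blink-robust); persistent separation of the terminus locus is the first
frame of the first run of ≥ K = 3 consecutive separated frames (transient
separations from precatenation links are shorter and are ignored); and

cohesion time = (t_segregation − t_replisome-end) + 7 min,

where the offset compensates for the locus replicating ~2 min before
termination and ~5 min of clamp unloading. Negative measured intervals are
legal (precocious segregation). Population summaries: step-curve t50 and the
mean cohesion time.

**4. matS-anchored ChIP enrichment** (`mukcoloc.chipseq`). Per-bin
enrichment is the ratio of medians across replicates,

E(bin) = (median_IP CPM + ε) / (median_mock CPM + ε),    ε = 0.5,

smoothed in a 2-kb window (wrapping the circular chromosome). Downstream:
top-26 peak calling with 2-kb exclusion zones, degenerate IUPAC motif
scanning on both strands (the 13-bp matS consensus is supplied via config),
peak↔motif annotation, and metagene profiles anchored at the top peaks for
comparing protein variants (fold change = ratio of profile maxima; flatness
= max/median).

`mukcoloc.simulate` generates all four input modalities with planted ground
truth: rod-shaped cells with two-channel foci at a controllable
colocalization fraction, rendered TIFF images, per-cell time-lapse tracks
with transient separations/re-merges, negative-binomial IP/mock coverage
with planted sites and shared highly-transcribed-region artifacts, and
repletion time courses with planted rates.

## Worked example

```python
from mukcoloc.simulate import SimImagingSpec, generate_cells, truth_focus_table
from mukcoloc import colocalization as cl

spec = SimImagingSpec(n_cells=2000, coloc_fraction=0.86, seed=1)
cells, truth = generate_cells(spec)          # masks + planted-focus truth table
table = truth_focus_table(truth)             # standard focus-table schema

result = cl.colocalization_fraction(table, "a", "b")       # threshold 258 nm
null, null_percent = cl.random_pixel_null(cells, table, "a", seed=2)
print(f"{result.percent_colocalized:.1f}% colocalized "
      f"(n={result.n_cells_used}), null {null_percent:.1f}%")
```

prints

```
86.7% colocalized (n=2000), null 8.7%
```

— the estimator recovers the planted 86% colocalization fraction, while
random pixel positions in the same cells sit at ~9%: the signal is far above
geometric chance. The same stages are scriptable from the shell:

```bash
mukcoloc simulate --out run1 --seed 1
mukcoloc coloc   --in run1 --out run1/coloc
mukcoloc cohesion --in run1 --out run1/cohesion --persist 3 --offset 7
mukcoloc chip    --in run1 --out run1/chip --window-bp 2000 --top-n 26
```

Each stage writes its outputs, a `summary.json`, and the exact resolved
`config.yaml` it ran with.

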