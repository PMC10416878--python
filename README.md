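# epilayer

Counting epithelial cell layers from segmented-nucleus tables.

Stratified squamous epithelium — such as the lining of the oral cavity —
thickens as dysplasia progresses, and the number of cell layers is one of
the features pathologists weigh when grading lesion severity. `epilayer`
turns the *output* of nucleus segmentation (a table of centroids with cell
classes) into a quantitative per-slide layer count, and carries that count
through to cohort-level statistics.

## Method

Given nuclei with positions $(x_i, y_i)$ (pixels at 40x magnification) and
classes (basal, other epithelial, lymphocyte, stroma, corneum, background):

1. **Neighbor graph.** The Delaunay triangulation of all points defines the
   neighbor relation; edges longer than 500 px are deleted as spurious.
2. **Edge points.** An epithelial node with a background or stratum-corneum
   neighbor is an *outer* edge point; one with a stroma neighbor is an
   *inner* edge point (the basal boundary). Connected epithelial components
   with fewer than 20 cells — slivers and crack fragments — are removed from
   the edge-point sets.
3. **Wave-front peeling.** All outer edge points form layer 1; each
   breadth-synchronous expansion step over epithelial nodes increments the
   layer index. The first wave that reaches an inner edge point assigns its
   layer count, so that

   $$\mathrm{count}(v) = 1 + \min_{s \in \text{outer}} d_{\text{hop}}(s, v)$$

   within the epithelial subgraph. The slide's thickness is the median of
   the inner-edge counts; their SD measures thickness variability.
4. **Cohort statistics.** Per-slide medians and SDs are compared across
   diagnosis groups by one-way ANOVA, and the cohort is split at the median
   layer number into equal halves for Kaplan–Meier curves and a Cox
   proportional-hazards fit on the progression-free interval.

A fusion stage assembles the input tables from whole-slide predictions:
aligned 10x semantic maps and 40x instance detections are tiled with
overlap, detection duplicates are resolved by interior ownership, each
detection takes its class from the semantic map under its centroid, and
pseudo-points are laid on a hexagonal grid in background/corneum regions so
the graph has nodes beyond the epithelial surface.

Because no segmented clinical slides ship with the package, a first-class
synthetic generator produces epithelium-like point patterns (strip or
annulus) with known layer number, jitter, cracks and lymphocytes, plus
cohorts with group-dependent thickness and thickness-dependent survival.

## Worked example

```python
from epilayer import EpitheliumSpec, count_layers, generate_epithelium, summarize_slide

cells, truth = generate_epithelium(EpitheliumSpec(n_layers=7, length=40, jitter_sd=6.0, seed=0))
print(summarize_slide(count_layers(cells)))
```

Running `python examples/01_count_layers.py` prints:

```
true layer number          : 7
cells on the slide         : 520 (280 epithelial)
median layers (thickness)  : 7.0
SD of layer counts         : 1.80
inner-edge nodes counted   : 44
```

The median layer count recovers the generator's true thickness of 7; the SD
reflects jitter and lattice-boundary effects. `examples/` holds one script
per capability (fusion, crack handling, cohort statistics), each printing
the numbers it computes. A thin CLI mirrors the library:
`epilayer simulate|fuse|count-layers|analyze|run --help`.

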