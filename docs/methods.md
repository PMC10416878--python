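# Methods

## The model of the tissue

The package treats a histology slide as a planar point cloud of nucleus
centroids, each carrying one of six classes: `basal`, `epithelial_other`
and `lymphocyte` (together "epithelial"), `stroma` (connective tissue under
the basal layer), and `corneum` / `background` (the keratinized surface and
empty slide, which contain no true nuclei and are populated by synthetic
grid points, flagged `is_pseudo`). All geometry is expressed in pixels at
40x magnification, raster convention (x = column, y = row, 0-based,
y downward); semantic label maps live at 10x and carry a scale factor of 4,
and are only ever sampled at 40x coordinates, never resampled.

## Layer counting

Neighborhood is the Delaunay edge relation, pruned at a maximum edge length
of 500 px (40x). The threshold is inclusive — an edge of exactly 500 px is
kept — and pruning is applied once, globally, before classification and
traversal; a traversal that instead skips long edges on the fly yields the
same counts (asserted by test), since both realize breadth-first search on
the same pruned adjacency.

Edge-point classification is purely local: an epithelial node with at least
one background/corneum neighbor is an outer edge point, with at least one
stroma neighbor an inner edge point, with both a `both` node (a one-cell
sheet must count 1). Components of the *epithelial induced subgraph* with
fewer than 20 cells are re-labeled `non_edge`; the induced subgraph matters
because the full graph is typically connected through stroma and
pseudo-points, which would make the filter vacuous. The filter is monotone
in its threshold.

The peel seeds all outer/both nodes at layer 1 and expands the whole
frontier synchronously, one layer per step, over epithelial nodes only
(stroma, corneum and background are classification context, never
traversed — letting the wave cross the stroma would short-circuit folds).
The recorded count at an inner edge node is the first wave index that
reaches it, i.e. 1 + the minimum hop distance from the seed set. Peeling
outward-in versus inward-out changes only where counts are recorded, not
their values, because min-hop distances between the two boundary sets are
symmetric; counts are recorded at the inner (basal) edge. Inner edge nodes
in components with no outer seed are reported as unreachable and excluded
from summaries — never imputed.

The slide summary is the 0.5 quantile (linear-interpolation convention) of
the reached inner-edge counts, with the population SD (ddof = 0). Both
conventions are fixed for reproducibility; the data never dictate a choice
here, so the numpy defaults are used.

## Fusion of semantic and instance predictions

Whole-slide predictions arrive per tile: a 500x500 semantic patch at 10x
aligned with a 2000x2000 region at 40x, the latter covered by partially
overlapping 500x500 instance windows. Windows step by `500 − 2·margin`
(default margin 50 px ≈ two nucleus diameters) and each discards its
margin; ownership boundaries sit at `{0} ∪ {margin + i·step} ∪ {W}` so
retained interiors abut exactly, with boundary windows clamped to the
region edge keeping their outer rim. Every point of the region is owned by
exactly one window of exactly one tile, which is how duplicate detections
in overlap zones resolve to a single record. The final class of each
detection is the semantic class under its centroid (mapping: basal→basal,
epithelium-other→epithelial_other, corneum→corneum, non-epithelium→stroma,
background→background); its geometry is untouched. Collapsing all
non-epithelial tissue to `stroma` preserves the inner-edge rule, which only
asks "is there non-epithelial tissue on this side". The lymphocyte class
cannot be produced by fusion (the semantic map has no such region); it
survives only in ingested tables from instance models that emit it, and
lymphocyte nodes are traversable but acquire edge roles by the same
neighbor rules.

Pseudo-points are laid on a hexagonal grid (default pitch 60 px at 40x,
about one nucleus spacing) inside background and corneum regions, so that
Delaunay edges across the epithelial surface exist. This is a modeling
device of this package: segmentation produces no nuclei there, yet the
outer-edge rule needs neighbors of those classes.

## The synthetic generator

`generate_epithelium` emulates what the segmentation stack would emit for a
stratified epithelium at desk scale: K rows (strip) or rings (annulus) of
epithelial nuclei on a hexagonal lattice with spacing 60 px, the row
touching the stroma relabeled basal; at least two rows each of stroma
below and corneum/background above. The hexagonal (offset-row) lattice is
chosen because its triangulation has no ambiguous cocircular quadruples, so
row adjacency is stable and the true min-hop count equals K − 1. Annulus
rings each carry as many points as keep the arc pitch at the cell spacing;
a fixed per-ring count would let the triangulation skip rings at large
radii. Optional Gaussian jitter perturbs real nuclei (not pseudo-points),
lymphocytes replace a stated fraction of epithelial cells, and cracks are
axis-aligned rectangular deletions measured from the corneum side — depth
fraction 1 severs the sheet. Note that a crack only *disconnects* the graph
when its gap exceeds the 500-px prune length, since Delaunay edges bridge
any gap narrower than the cutoff; fixtures that need detached fragments use
600-px cracks.

Known departures from real tissue: no nucleus-shape or staining variation,
uniform thickness per slide (no true thickness profile variance beyond
jitter), straight or circular geometry rather than folded epithelium, and
cracks as clean rectangles. Passing the recovery tests therefore shows the
counting machinery is correct on its stated model, not that segmentation
noise on clinical slides is handled.

One lattice artifact is worth naming: on a jitter-free strip, columns on
the convex hull acquire vertical Delaunay edges that skip a row (an empty
circumcircle always exists in the outward half-plane), so a few boundary
inner-edge nodes count less than K. The slide *median* is unaffected —
those nodes are a small minority — which is why exactness is asserted on
medians for generated sheets and on every node only for hand-built regular
graphs; it is also why the per-slide SD is slightly positive even without
jitter.

`generate_cohort` draws per-slide median layers from group-specific normal
distributions (defaults 8/11/15 ± 2 layers for the three severity groups of
45/82/8 slides), per-slide SD as |N(0.2·median, 0.3)|, and
progression-free-interval times as exponential with log-hazard
`intercept + beta·median` (defaults −7.5 and 0.15 per layer, giving event
times on the order of hundreds of days). Censoring is independent: with
probability `censor_rate` (default 0.3) the slide is censored at a uniform
fraction of its event time.

## Statistics stage

Group comparison is a one-way ANOVA F-test (scipy) on the chosen per-slide
statistic; the degenerate cases scipy leaves as NaN are resolved from the
sums of squares (all-constant input → F = 0, p = 1; zero within-group
variance with separated means → F = ∞, p = 0). The survival split
stable-sorts slides by (median layers, slide id) and assigns the first
⌊n/2⌋ to the low group — ties at the threshold are broken by slide id, so
a 135-slide cohort always splits 67/68. Kaplan–Meier curves come from
lifelines, as does the Cox proportional-hazards fit (Efron tie handling,
lifelines' default) of event hazard on the high-group indicator; the model
accepts extra covariate columns, but none are fitted by default since the
per-slide summaries are the only covariates the package computes.

## Problem sizes and tolerances

Default verification scales, chosen to exercise the properties at desk
scale: random-graph oracle checks use up to 200 nodes per graph; recovery
sweeps cover K = 1..15 noise-free and K ∈ {3, 6, 10} × 50 seeds at jitter
σ = 15% of spacing (recovery within one layer in ≥ 95% of runs, R² ≥ 0.95
against truth); cohort simulations use the 45/82/8 group structure.
Numerical tie-breaks are documented above; co-located input points are
perturbed by a deterministic seeded jitter of 1e-6 px before triangulation,
with original coordinates retained.

## Limitations

The counts are integer hop counts, not micron thickness; stratum corneum
layers are not counted (the region is anuclear); heavily folded epithelium
where the same physical fold is crossed twice is summarized as-is; and the
fusion stage assumes the stated tile/window geometry rather than inferring
it from files.
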