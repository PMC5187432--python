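# Methods

`leafmorph` implements a morphometric framework for asking whether a
katydid forewing (tegmen) — in particular an incomplete fossil wing —
belongs with the leaf-mimicking or the non-leaf-mimicking wing shapes of
the modern fauna. This note records the models, the conventions and the
numerical choices, and what the synthetic data can and cannot show.

## Shape descriptors

Ten raw measurements are taken on a wing outline split by the radius vein
into an anterior and a posterior field: maximal length; width on the
middle; the two field widths; total, anterior and posterior areas; total,
anterior and posterior perimeters. Four dimension-free descriptors are
derived:

| descriptor | definition | leaf-mimicking tendency |
|---|---|---|
| `ratio_wl` | width / length | high (broad wing) |
| `ratio_field_width` | anterior / posterior field width | near 1 (symmetric) |
| `ratio_field_area` | anterior / posterior field area | near 1 |
| `circularity_anterior` | 4π·area / perimeter² of the anterior field | higher (rounder field) |

Circularity is the isoperimetric ratio: 1 for a disk, < 1 for anything
else. A fifth, binary character codes a tegmen as leaf-like iff its
maximum width exceeds the thorax height; it is `unknown` for specimens
without a preserved thorax (the fossil case).

Measurement conventions the source protocol leaves open were fixed as
follows: outlines are orientation-normalised by the principal axis of the
polygon's area moments; *all* widths are read on the single transect
perpendicular to that axis at 50% of the maximal length (reproducible and
rotation-invariant, though possibly not identical to measuring each field
at its own widest point); field areas and perimeters come from the two
faces produced by splitting the polygon along the radius polyline, with
the anterior field taken as the face left of the directed polyline. Areas
use the shoelace formula, perimeters polyline arc length. Mirror- and
rotation-transformed outlines yield identical records (the split polyline
transforms with the outline and keeps encoding which side is anterior).

## Completing an incomplete wing

A wing missing its apex is measured twice: once on the clipped polygon
closed by the straight cut chord (no extrapolation), and once after
completing the apex with a single circular arc through the two cut points
whose tangent-chord angle is the least-squares compromise between the two
boundary tangents at the cut (by the inscribed-angle theorem the optimal
angle is simply their mean). When the two tangent-chord angles disagree
by more than 30° a tangent-continuous biarc is used instead; coincident
endpoints or antiparallel tangents raise an explicit error.

Accuracy, measured on synthetic truncations: completing a circle with 15%
of its length removed recovers the disk area to 0.04%. For the default
tegmen shape truncated by 10%, area is recovered to ~1.6% but maximal
length only to ~6%: a superelliptic apex is blunter than any circular arc
matched to the cut tangents, so circular completion systematically
under-reaches the true apex. This is an intrinsic limit of circle-segment
completion, not of the implementation; extrapolated measurements still
strictly improve on chord closure in every tested case, and both variants
are always reported side by side.

## Empirical-CDF mixture models

Each descriptor's distribution across species is summarised by its
empirical cumulative distribution — sorted values against Hazen plotting
positions (i − 0.5)/n, which avoids probabilities of exactly 0 or 1 that
no normal CDF can attain and loses no information to binning. Two models
are fitted by bounded least squares:

* **One component:** F(x) = ½(1 + erf((x − A1)/(A2√2))), A1 the mean, A2
  the standard deviation; initialised at the sample moments.
* **Forced two components:** F(x) = (1 − A5)·Φ((x − A1)/A2) +
  A5·Φ((x − A3)/A4), where A1 is *frozen* at the mean fitted (with the
  one-component model) on the reference subfamily Pterochrozinae — the
  only katydid subfamily consisting entirely of leaf-mimicking species —
  so the first component is anchored to the leaf-mimicking shape. A2, A4
  > 0 and A5 ∈ [0, 1] by box constraints. Multi-start over A5 ∈ {0.25,
  0.5, 0.75} × A3 ∈ {q25, q50, q75}, plus a start at the one-component
  solution with A5 = 1 that guarantees the nested fit cannot end worse
  than the null in practice. Analytic Jacobians; convergence tolerance
  1e-10 on the residual sum of squares, at most 500 iterations per start.

Setting A5 = 0 reduces the second model to the first exactly, so the pair
is compared with the extra sum-of-squares F test, F = ((rss₁ −
rss₂)/2)/(rss₂/(n − 4)) on (2, n − 4) degrees of freedom at P < 0.01,
together with AIC and BIC in their least-squares Gaussian-error form
n·ln(rss/n) + penalty·(k + 1) (k + 1 counts the error variance). The
two-component model is "preferred" only when all three criteria agree;
disagreements are reported, never silently resolved.

**Caveat.** The F test (and the information criteria) treat CDF-fit
residuals as independent, which cumulative residuals are not. The
procedure is therefore strongly anticonservative: in simulations at
n = 253 it prefers the two-component model for ~90% of datasets drawn
from a *single* normal (and for 100% of well-separated mixtures). The
comparison is reproduced as defined because it is the method under study;
its outcome should be read as a descriptive fit comparison, not a
calibrated hypothesis test, and the pipeline output carries this note.

A brute-force cross-check (`mixture.grid_search_rss`) evaluates the rss
surface on an exhaustive (A3, A5) grid with the two SDs profiled and
polishes the best cells; the constrained optimizer matches or beats it on
every tested dataset.

## Sharing fractions

A query specimen (the fossil) is classified per descriptor and group as
the fraction of the group's species whose value lies in a closed interval
around the query value. "Shared" has no canonical definition; the default
half-width is max(half the Pterochrozinae fitted SD, the span between the
fossil's chord-closed and extrapolated values), so the interval is never
narrower than the fossil's own measurement uncertainty. The rule and the
interval are logged with every result, and alternative rules (fixed
half-width, k·SD) plug in through `SharingRule`.

## Morphospace

Correlation-matrix PCA (each descriptor centred, scaled to unit SD with
ddof = 1) of the modern species; eigenvalues then sum to the number of
variables and match the eigendecomposition of the correlation matrix.
Loading signs are fixed so the largest-magnitude weight on each axis is
positive, making results platform-deterministic. The binary leaf-like
character is *not* an active variable by default — it is unknown for the
fossil and would forbid projection — but defines the two groups whose
clouds are summarised by centroids (M, nM) and normal-theory confidence
ellipses: axes along the group score covariance eigenvectors, semi-axes
√(eigenvalue · χ²₂(level)), level 0.95 by default. Queries are projected
as supplementary individuals (centred/scaled with the training
statistics, multiplied by the loadings) by default; an `active` mode
refits the axes with the queries included, since the original ordination
may have done either. Degenerate group covariances produce a flagged
segment-like ellipse rather than an error; centroid ties are reported
explicitly.

## Synthetic data

The generator emulates the study design: `n_species` (default 253)
species whose four descriptors are drawn independently from one of two
normal components — leaf-mimicking (default mixing fraction 0.3,
including 20 Pterochrozinae) or non-mimicking — with the group size fixed
deterministically at round(fraction × n) so counts are assertable. An
optional correlation matrix across descriptors is exposed (identity by
default; no covariance structure is reported for the real data). Default
means put the mimicking component at a broad leaf-like geometry
(width/length ≈ 0.36, i.e. ~2.8× longer than wide, symmetric fields) and
the non-mimicking component three SDs away on every descriptor — the
separation the mixture analysis is designed to resolve, and the
configuration used in all simulation studies. These defaults are
plausibility choices, not estimates of the real comparative dataset,
for which no per-group moments are available.

Raw measurement columns are generated analytically from the drawn
descriptors (widths from the ratios and a length drawn uniformly from
25–60 mm; areas from a fixed lobe fill factor; perimeters from the
circularity identity), so they satisfy every record invariant by
construction. Full outlines use a two-lobe family: anterior and posterior
superellipse lobes over a shared straight radius chord, with lobe heights
set by the width descriptors and each lobe's exponent solved by bisection
so the *measured* circularity and field-area ratio hit their targets
(round-trip error < 1e-3 relative per descriptor). Descriptor
combinations outside the family's reach raise an error reporting the
achievable range. Tip truncation clips perpendicular to the long axis at
(1 − fraction) × length and records the cut points and boundary tangents
for later completion.

What passing synthetic tests do **not** show: real tegmina have venation,
colour and 3D curvature the planar outline family ignores; real
descriptor distributions need not be normal within groups, need not be
independent across descriptors, and the real group separation is unknown.
The pipeline's statistical behaviour under the defaults (e.g. 4/4
descriptors preferring two components; non-mimicking sharing ≤ 3%)
demonstrates that the machinery resolves a 3-SD separation at n = 253,
not that the real fauna is so separated.

## Problem sizes and reproducibility

Simulation studies use the sizes natural to the design: 200 replicates
for model-selection rates, 50 for parameter recovery, 100 for morphospace
placement, 10 instances for the grid-search oracle; the full pipeline at
n = 253 runs in seconds. Every random draw flows from a single
`numpy.random.default_rng` seed carried in the config; reports embed the
config hash and seed, and rerunning a config reproduces the report
byte-for-byte apart from timestamps.
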