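# leafmorph

Morphometrics of leaf-mimicking katydid forewings: shape descriptors
from wing outlines, forced-mean two-component mixture fits on empirical
CDFs, circular-arc completion of incomplete (fossil) wings,
sharing-fraction classification, and a PCA morphospace with group
confidence ellipses.

## The problem

Leaf mimicry in katydids (Tettigoniidae) shows in the forewing (tegmen):
leaf-mimicking species have broad, leaf-shaped tegmina with nearly
symmetric anterior/posterior fields, while non-mimicking species have
narrow, asymmetric ones. Given a comparative table of modern species —
including the Pterochrozinae, the only subfamily that is entirely
leaf-mimicking — and a fossil wing whose apex is missing, the question is
whether the fossil's shape belongs with the leaf-mimicking wings. This
package provides the full chain of tools for that analysis, for
palaeoentomologists and morphometricians alike:

1. **Descriptors** — ten raw measurements per wing reduce to four
   dimension-free ratios: width/length, anterior/posterior field width,
   anterior/posterior field area, and anterior-field circularity
   4πA/P². A binary leaf-like coding (wing width > thorax height)
   labels the modern groups.
2. **Mixture model** — each descriptor's empirical CDF is fitted with a
   one-component normal CDF, F(x) = ½(1 + erf((x − A1)/(A2√2))), and
   with a two-component version whose first mean is frozen at the
   Pterochrozinae fit:
   F(x) = (1 − A5)·Φ((x − A1)/A2) + A5·Φ((x − A3)/A4).
   The nested pair is compared with the extra sum-of-squares F test
   (P < 0.01) plus AIC/BIC decreases.
3. **Fossil completion** — the missing apex is completed with a circular
   arc matched to the cut tangents (biarc fallback), and every quantity
   is reported both with and without extrapolation.
4. **Classification** — sharing fractions: the proportion of each group
   whose descriptor value falls within a stated interval of the
   fossil's.
5. **Morphospace** — correlation PCA with 95% confidence ellipses and
   centroids for the mimetic (M) and non-mimetic (nM) clouds; the fossil
   is projected as a supplementary individual.

A synthetic-data generator stands in for the comparative measurement
table (which has no public accession): two normal components per
descriptor, three SDs apart by default, plus geometrically consistent
outlines and fossil-like truncated wings. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

```sh
leafmorph run-all --seed 7 --out out/
```

runs the whole pipeline on a synthetic 253-species population and prints
(abridged):

```
- 253 species analysed
- two-component model preferred for 4/4 descriptors

| descriptor | F | p | dAIC | dBIC | preferred | A5 |
|---|---|---|---|---|---|---|
| ratio_wl | 1606.85 | 4.67e-143 | -662.0 | -654.9 | two_component | 0.666 |
...

## Fossil sharing fractions (extrapolated measurements)
| descriptor | mimicking | non-mimicking |
|---|---|---|
| ratio_wl | 0.068 | 0.006 |
| ratio_field_width | 0.270 | 0.017 |
...
- fossil_extrapolated: PC1 +3.047, PC2 +0.379, nearest group mimetic
```

Reading: on every descriptor the species table is far better described
by two components (one anchored to the Pterochrozinae mean) than by one;
the reconstructed fossil's values are shared by ≤ 2% of non-mimicking
but up to ~30% of mimicking species; and in the factorial map the fossil
lands near the mimetic centroid. `out/` holds the report JSON, the
per-descriptor fit figures with their underlying CSVs, and the
morphospace plot.

The same analysis as a step-by-step narrative lives in `analysis/`
(`01_simulate_population.py` … `05_morphospace.py`), each script writing
its tables under `results/`. Library use:

```python
from leafmorph import (SyntheticPopulationConfig, draw_shape_parameters,
                       empirical_cdf, fit_one_component,
                       fit_forced_two_component, compare_models)

table = draw_shape_parameters(SyntheticPopulationConfig(rng_seed=1))
ecdf = empirical_cdf(table["ratio_wl"])
one = fit_one_component(ecdf)
two = fit_forced_two_component(ecdf, forced_mean=0.357, one_fit=one)
print(compare_models(one, two, ecdf=ecdf).preferred)  # two_component
```

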