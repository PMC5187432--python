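#!/usr/bin/env python
"""Classify the fossil analog by sharing fractions: for each descriptor,
the proportion of leaf-mimicking and of non-mimicking species whose
value falls inside an interval around the fossil's value (half-width =
max of half the Pterochrozinae fitted SD and the fossil's
extrapolation span).

Reads results/species_table.csv and results/fossil_measurements.csv
(run 01 and 03 first); writes results/sharing_fractions.csv.
"""

import os

import pandas as pd

from leafmorph import mixture
from leafmorph.io import read_species_table
from leafmorph.morphometry import DESCRIPTOR_NAMES

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    table = read_species_table(os.path.join(OUT, "species_table.csv"))
    fossil = pd.read_csv(os.path.join(OUT, "fossil_measurements.csv"),
                         index_col="variant")
    rows = []
    for name in DESCRIPTOR_NAMES:
        ref = mixture.fit_pterochrozinae_reference(table, name)
        span = abs(fossil.loc["extrapolated", name]
                   - fossil.loc["no_extrapolation", name])
        rule = mixture.SharingRule(half_width=max(0.5 * ref.a2, span),
                                   description="max(ref sd / 2, span)")
        for variant in ("no_extrapolation", "extrapolated"):
            query = float(fossil.loc[variant, name])
            mim = mixture.sharing_fraction(
                query, table.loc[table.is_mimicking, name], rule)
            non = mixture.sharing_fraction(
                query, table.loc[~table.is_mimicking, name], rule)
            rows.append({"descriptor": name, "variant": variant,
                         "half_width": rule.half_width,
                         "share_mimicking": mim, "share_non_mimicking": non})
    frame = pd.DataFrame(rows)
    frame.to_csv(os.path.join(OUT, "sharing_fractions.csv"), index=False)
    print(frame.round(4).to_string(index=False))
    ext = frame[frame.variant == "extrapolated"]
    print(f"\nfossil values shared by at most "
          f"{100 * ext.share_non_mimicking.max():.1f}% of non-mimicking "
          f"species and by up to {100 * ext.share_mimicking.max():.1f}% "
          "of leaf-mimicking species")


if __name__ == "__main__":
    main()
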