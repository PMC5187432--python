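#!/usr/bin/env python
"""Place the fossil analog in the PCA morphospace of the modern species:
correlation PCA on the four descriptors, 95% confidence ellipses for the
mimetic (M) and non-mimetic (nM) clouds, fossil projected as a
supplementary individual.

Reads results/species_table.csv and results/fossil_measurements.csv;
writes results/morphospace.json and results/morphospace_scores.csv.
"""

import json
import os

import numpy as np
import pandas as pd

from leafmorph import morphospace
from leafmorph.io import read_species_table
from leafmorph.morphometry import DESCRIPTOR_NAMES

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    table = read_species_table(os.path.join(OUT, "species_table.csv"))
    fossil = pd.read_csv(os.path.join(OUT, "fossil_measurements.csv"),
                         index_col="variant")
    model = morphospace.fit_pca(table, list(DESCRIPTOR_NAMES))
    labels = np.where(table["leaf_like"], "mimetic", "non_mimetic")
    ellipses = morphospace.group_ellipse(model, labels, level=0.95)

    queries = {}
    for variant in ("no_extrapolation", "extrapolated"):
        q = {k: float(fossil.loc[variant, k]) for k in DESCRIPTOR_NAMES}
        coords = morphospace.project(model, q)
        queries[variant] = {
            "coords": coords.tolist(),
            **morphospace.centroid_distances(model, coords, labels,
                                             ellipses=ellipses)}

    payload = {"model": model.to_dict(),
               "ellipses": {k: v.to_dict() for k, v in ellipses.items()},
               "queries": queries}
    with open(os.path.join(OUT, "morphospace.json"), "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
    pd.DataFrame({"taxon_id": table["taxon_id"], "group": labels,
                  "pc1": model.scores[:, 0],
                  "pc2": model.scores[:, 1]}).to_csv(
        os.path.join(OUT, "morphospace_scores.csv"), index=False)

    print("explained variance fractions:",
          np.round(model.explained_fraction, 3).tolist())
    for variant, q in queries.items():
        d = q["distances"]
        print(f"fossil ({variant}): PC1 {q['coords'][0]:+.3f} "
              f"PC2 {q['coords'][1]:+.3f}; distance to M "
              f"{d['mimetic']:.3f}, to nM {d['non_mimetic']:.3f} "
              f"-> nearest {q['nearest']}, inside M ellipse: "
              f"{q['inside']['mimetic']}")


if __name__ == "__main__":
    main()
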