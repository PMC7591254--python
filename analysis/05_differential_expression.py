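"""Hurdle-model DE of MAC2+ cells against the homeostatic cluster.

Contrasts gated MAC2+ cells with MAC2- cells of the cluster scoring
highest on the homeostatic panel, at |logFC| > 0.5 — the comparison behind
the immature-signature claims. Also writes the Ctrl-only MAC2+ contrast
used for the Venn comparison downstream.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microrepop.clustering import panel_detection_fractions
from microrepop.de import contrast_de
from microrepop.io import read_params, read_tenx
from microrepop.preprocess import log_normalize

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    matrix = read_tenx(DATA / "tenx_myeloid")
    params = read_params(DATA / "gen_params.yaml")
    norm = log_normalize(matrix)
    gate = pd.read_csv(DATA / "gate_labels.tsv", sep="\t")
    mac2 = gate.set_index("cell_id")["mac2_positive"].loc[
        matrix.cell_meta["cell_id"]
    ].to_numpy(dtype=bool)

    clusters = matrix.cell_meta["cluster"].to_numpy()
    scores = panel_detection_fractions(
        matrix, clusters, {"homeostatic": params.panels["homeostatic"]}
    )
    homeo = max(scores, key=lambda c: scores[c]["homeostatic"])
    homeo_cells = (clusters == homeo) & ~mac2
    print(f"homeostatic reference: cluster {homeo} "
          f"({int(homeo_cells.sum())} MAC2- cells)")

    table = contrast_de(
        norm, np.flatnonzero(mac2), np.flatnonzero(homeo_cells), logfc_min=0.5
    )
    table.to_csv(OUT / "de_mac2_vs_homeostatic.csv", index=False)
    sig = table[table["p_adj"] < 0.05]
    print(f"{len(table)} genes tested; "
          f"{(sig['direction'] == 'up').sum()} up / "
          f"{(sig['direction'] == 'down').sum()} down at adjusted p < 0.05")

    ctrl = (matrix.cell_meta["condition"] == "Ctrl").to_numpy()
    table_ctrl = contrast_de(
        norm, np.flatnonzero(mac2 & ctrl),
        np.flatnonzero(homeo_cells & ctrl), logfc_min=0.5,
    )
    table_ctrl.to_csv(OUT / "de_mac2_ctrl_vs_homeostatic.csv", index=False)
    print(f"Ctrl-only contrast: {len(table_ctrl)} genes tested")


if __name__ == "__main__":
    main()
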