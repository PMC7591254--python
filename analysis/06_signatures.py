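"""Developmental-signature overlap of the MAC2+ DEGs, plus Venn comparison.

Scores up- and down-regulated MAC2+ DEGs against the seven developmental
stage sets (YS, E1, E2, P1, P2, A1, A2): the immature claim predicts up-DEGs
concentrated in YS/E1 and down-DEGs in A1/A2. Then compares all-MAC2+ vs
Ctrl-only MAC2+ up-DEG lists the way the study's Venn diagrams do.
"""

import json
from pathlib import Path

import pandas as pd

from microrepop.io import read_params
from microrepop.signatures import StageSets, overlap_fractions, venn_compare
from microrepop.simulate import stage_sets_from_panels

DATA = Path("results/data")
OUT = Path("results")


def _degs(path, direction):
    table = pd.read_csv(path)
    sig = table[(table["p_adj"] < 0.05) & (table["direction"] == direction)]
    return sig["gene"].tolist()


def main() -> None:
    params = read_params(DATA / "gen_params.yaml")
    sets = StageSets.from_lists(stage_sets_from_panels(params.panels))

    rows = []
    for direction in ("up", "down"):
        degs = _degs(OUT / "de_mac2_vs_homeostatic.csv", direction)
        profile = overlap_fractions(degs, sets)
        frame = profile.to_frame()
        frame.insert(0, "direction", direction)
        rows.append(frame)
        print(f"{direction}-DEGs (n={profile.n_degs_total}):")
        print(frame.to_string(index=False))
    pd.concat(rows).to_csv(OUT / "signature_overlap.csv", index=False)

    up_all = _degs(OUT / "de_mac2_vs_homeostatic.csv", "up")
    up_ctrl = _degs(OUT / "de_mac2_ctrl_vs_homeostatic.csv", "up")
    common, all_only, ctrl_only = venn_compare(up_all, up_ctrl)
    print(f"up-DEG Venn (all MAC2+ vs Ctrl MAC2+): common {common}, "
          f"all-only {all_only}, Ctrl-only {ctrl_only}")
    with open(OUT / "venn_up_degs.json", "w") as fh:
        json.dump({"common": common, "all_only": all_only,
                   "ctrl_only": ctrl_only}, fh, indent=2)


if __name__ == "__main__":
    main()
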