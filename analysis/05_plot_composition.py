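#!/usr/bin/env python
"""Plot per-individual genome composition as stacked bars.

Reads results/composition.tsv (written by 03_place_and_profile.py) and draws
the proportion of placed reads assigned to each nuclear clade per individual,
the figure summarizing subgenome ancestry of the polyploids next to the
diploid leave-one-out calibrations. Writes results/composition.png.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"
CLADE_COLORS = {"I": "#4477aa", "II": "#66ccee", "III": "#ccbb44", "IV": "#ee6677"}


def main() -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pd.read_csv(RESULTS / "composition.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(1.2 * len(table) + 2, 4))
    bottom = [0.0] * len(table)
    for clade, color in CLADE_COLORS.items():
        values = table[f"pct_{clade}"].fillna(0.0)
        ax.bar(table["individual"], values, bottom=bottom,
               label=f"clade {clade}", color=color)
        bottom = [b + v for b, v in zip(bottom, values)]
    ax.set_ylabel("% of placed reads")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.set_title("Genome composition from phylogenetic read placement")
    fig.tight_layout()
    out = RESULTS / "composition.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
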