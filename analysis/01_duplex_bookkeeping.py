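#!/usr/bin/env python
"""Watson-Crick bookkeeping of the GAACTC:RNA hexamer duplex.

Builds the antiparallel duplex from the study sequences (PNA written
N- to C-terminus, RNA 5' to 3'), tabulates per-pair H-bond
multiplicities, the 7-vs-8 half totals, and the counterions needed to
neutralize the RNA backbone.  Writes results/bookkeeping.tsv.
"""

from pathlib import Path

import pandas as pd

from pnadyn.core import build_duplex, counterion_count, half_hbond_total

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    duplex = build_duplex("GAACTC", "GAGTTC")
    rows = [{"pair": i, "label": duplex.pair_label(i),
             "hbonds": duplex.pair_hbond_count(i)}
            for i in range(duplex.n_pairs)]
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "bookkeeping.tsv", sep="\t", index=False)

    first = half_hbond_total(duplex, "first")
    second = half_hbond_total(duplex, "second")
    print(table.to_string(index=False))
    print(f"\nN-terminal half: {first} H-bonds; "
          f"C-terminal half: {second} H-bonds")
    print(f"counterions to neutralize: {counterion_count(duplex)}")
    print("The C-terminal half is the H-bond-richer one (8 vs 7), the "
          "basis of the sequence-asymmetry analyses downstream.")


if __name__ == "__main__":
    main()
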