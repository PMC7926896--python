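"""Rank the 8 candidate reference genes by expression stability M.

Reads the simulated Ct table, computes per-candidate M (mean pairwise SD
of log2 ratios) and runs the iterative geNorm exclusion down to the three
most stable genes, which all later stages use for normalization.
"""

import argparse
from pathlib import Path

from carpstress import qpcr_io
from carpstress.panel import default_panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/ct_table.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = default_panel()
    ct = qpcr_io.read_ct_table(args.data, panel)
    ranking = qpcr_io.select_reference_genes(ct, panel, qpcr_io.PipelineSettings())

    frame = ranking.to_frame()
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "stability.csv", index=False)

    print(frame.to_string(index=False))
    print(f"\nselected reference genes: {', '.join(ranking.selected)}")
    print(f"exclusion order (least stable first): {', '.join(ranking.exclusion_order)}")


if __name__ == "__main__":
    main()
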