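"""Per-region PCA of the normalized expression for each gene subset.

Runs correlation-matrix PCA per region for the immediate-early-gene,
HPI-axis, neurotransmitter and final marker-candidate subsets, reporting
the variance explained by the first two components, each gene's cos2
(quality of representation), and per-group score ellipses.
"""

import argparse
from pathlib import Path

from carpstress import qpcr_io, synthdata
from carpstress.panel import default_panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/ct_table.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    panel = default_panel()
    ct = qpcr_io.read_ct_table(args.data, panel)
    settings = qpcr_io.PipelineSettings(seed=args.seed)
    bundle = qpcr_io.run_pipeline(ct, panel, settings)
    qpcr_io.write_report(bundle, args.out)

    print("percent variance on Dim1+Dim2 per region and gene subset:")
    for region, rep in bundle.regions.items():
        parts = ", ".join(
            f"{name}: {res.percent_variance[:2].sum():.1f}%"
            for name, res in rep.pca.items()
        )
        print(f"  {region}: {parts}")
    print("\nbest-represented gene (highest Dim1+Dim2 cos2) in the final subset:")
    for region, rep in bundle.regions.items():
        cos2 = rep.pca_cos2["final"]
        top = (cos2["Dim1"] + cos2["Dim2"]).idxmax()
        print(f"  {region}: {top}")
    print(f"\nfull report (eigenvalues, scores, cos2, ellipses) in {args.out}/")


if __name__ == "__main__":
    main()
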