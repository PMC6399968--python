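"""Change-point segmentation of the developmental series: exact dynamic-
programming segmentation of each DE gene's replicate-ordered profile with
breaks pinned to stage boundaries, interval averaging, clustering into 7
change-point groups, and maternal/EGA labels.

Writes per-gene breakpoints and group profiles under results/.
"""

from pathlib import Path

import pandas as pd

import embryonet as en
from embryonet import changepoints as cp
from embryonet.barcodes import fit_mixture

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "synthetic_study"
OUT = ROOT / "results"


def main() -> None:
    matrix = en.load_expression(STUDY / "stage_expression.tsv",
                                STUDY / "stage_meta.tsv")
    truth = en.SyntheticTruth.from_json(STUDY / "truth.json")

    de = en.anova_stage_de(matrix)
    profs, averaged, stage_bps = cp.segment_stage_series(
        matrix, genes=sorted(de.de_genes))

    groups = cp.cluster_changepoint_groups(averaged, k=7, profiles=profs)
    threshold = fit_mixture(matrix.values.to_numpy().ravel()).midpoint
    _, per_stage = en.call_presence(matrix, threshold=threshold)
    labels = cp.label_changepoint_groups(groups, per_stage, matrix.stages)

    cp.changepoint_table(profs).to_csv(OUT / "changepoints.csv", index=False)
    groups.group_profiles.to_csv(OUT / "changepoint_group_profiles.csv")

    exact = sum(stage_bps[g] == truth.true_changepoints[g] for g in profs)
    print(f"segmented {len(profs)} DE genes on the replicate series "
          f"(breaks at stage boundaries); planted breakpoints exactly "
          f"recovered for {exact} ({100 * exact / len(profs):.1f}%)")
    sizes = pd.Series(groups.assignment).value_counts().sort_index()
    for grp, size in sizes.items():
        print(f"  group {grp}: {size} genes, label {labels[grp]!r}")


if __name__ == "__main__":
    main()
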