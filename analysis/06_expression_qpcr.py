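"""qPCR quantification and tissue-specificity on simulated expression data.

Simulates a Ct table (TIP41 reference, 0-h calibrator, 3 biological x 3
technical replicates, 0.15-cycle noise) with known fold changes over the
six treatment timepoints, quantifies with 2^-ddCt, then builds a
gene x tissue matrix with planted tissue dominance and computes the tau
specificity index and heatmap gene ordering.

Writes results/fold_changes.tsv and results/tissue_specificity.tsv.
"""

from pathlib import Path

from famevol import expression, simulate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240918


def main() -> None:
    true_folds = {
        "geneA": {"1h": 2.0, "3h": 4.0, "6h": 8.0, "12h": 4.0, "24h": 2.0},
        "geneB": {"1h": 1.0, "3h": 0.5, "6h": 0.25, "12h": 0.5, "24h": 1.0},
    }
    table, truth = simulate.simulate_ct(seed=SEED, true_folds=true_folds)
    folds = expression.ddct(table, "TIP41", "0h")
    OUT.mkdir(exist_ok=True)
    folds.to_csv(OUT / "fold_changes.tsv", sep="\t", index=False)
    print("estimated fold changes (true in parentheses):")
    for r in folds.itertuples():
        print(f"  {r.gene} @ {r.condition}: {r.fold:.2f} +/- {r.se:.2f} "
              f"({truth[r.gene][r.condition]:g})")

    matrix, top_truth = simulate.simulate_tissue_matrix(seed=SEED, n_genes=35)
    tau = expression.tissue_specificity(matrix)
    _, order = expression.tissue_profile(matrix)
    tau["true_top"] = [top_truth[g] for g in tau.index]
    tau.to_csv(OUT / "tissue_specificity.tsv", sep="\t")
    correct = (tau["top_tissue"] == tau["true_top"]).sum()
    print(f"\ntissue specificity: {correct}/{len(tau)} dominant tissues "
          f"recovered; tau range {tau['tau'].min():.2f}-{tau['tau'].max():.2f}")
    print("heatmap gene order (first 5):", ", ".join(order[:5]))


if __name__ == "__main__":
    main()
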