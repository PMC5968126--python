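"""Clustering, validation and classification of the BSPiM datasets.

Ward-clusters each model's integral maps for K = 2..10, maps clusters back
to atrial regions through the ectopic graph, computes the persistence /
overlapped-regions / connection-ratio / region-area metrics, selects
electrodes by the chi-squared score and reports stratified 4-fold RBF-SVM
accuracies.  Writes the metric and accuracy grids under results/.
"""

import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402

from fibrofocal import experiments as ex  # noqa: E402
from fibrofocal.config import ExperimentConfig  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def plot_dendrogram(report, model):
    fig, ax = plt.subplots(figsize=(9, 4))
    hierarchy.dendrogram(report.linkage, ax=ax, no_labels=True,
                         color_threshold=0.0)
    ax.set_title(f"Ward dendrogram, model {model}")
    ax.set_ylabel("merge distance")
    fig.tight_layout()
    fig.savefig(OUT / f"dendrogram_{model}.png", dpi=120)
    plt.close(fig)


def plot_accuracy_vs_n(accuracy, model):
    sub = accuracy[accuracy.model == model]
    fig, ax = plt.subplots(figsize=(6, 4))
    for K, grp in sub.groupby("K"):
        ax.plot(grp["N"], grp["CA"], marker="o", label=f"K={K}")
    ax.axhline(0.90, ls=":", color="k")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("number of electrodes N")
    ax.set_ylabel("classification accuracy")
    ax.set_title(f"model {model}")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(OUT / f"accuracy_{model}.png", dpi=120)
    plt.close(fig)


def main():
    cfg = ExperimentConfig(fast_svm=True)  # fixed SVM for the full grid
    result = ex.run_pipeline_suite(cfg, n_list=(16, 64, 256))
    metrics, accuracy = result["metrics"], result["accuracy"]
    print("cluster metrics (256 electrodes):")
    print(metrics.round(2).to_string(index=False))
    print("\naccuracy by electrode count:")
    pivot = accuracy.pivot_table(index=["model", "K"], columns="N",
                                 values="CA")
    print(pivot.round(3).to_string())
    OUT.mkdir(exist_ok=True)
    metrics.to_csv(OUT / "cluster_metrics.csv", index=False)
    accuracy.to_csv(OUT / "classification_accuracy.csv", index=False)
    plot_dendrogram(result["reports"]["M1"], "M1")
    for m in ("M0", "M5"):
        plot_accuracy_vs_n(accuracy, m)
    print(f"\nwrote {OUT / 'cluster_metrics.csv'}, "
          f"{OUT / 'classification_accuracy.csv'} and figures")


if __name__ == "__main__":
    sys.exit(main())
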