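"""Plot mean accuracy and F1 against channel count, per SVM kernel.

Reads results/ablation/results.json (from 02_run_ablation.py) and writes a
two-panel bar chart to results/figures/ablation_means.png, mirroring the
summary-figure style of channel-ablation studies.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from mi_esi.core_io import ResultsTable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    rj = RESULTS / "ablation" / "results.json"
    if not rj.exists():
        print(f"no ablation results at {rj}; run 02_run_ablation.py first")
        return 1
    df = ResultsTable.read_json(rj)
    means = df[df.subject == "mean"].sort_values("n_channels")

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, metric in zip(axes, ("Acc", "F1")):
        for kernel, offset in (("linear", -0.2), ("rbf", 0.2)):
            sub = means[means.kernel == kernel]
            x = range(len(sub))
            ax.bar([i + offset for i in x], sub[metric], width=0.4, label=kernel)
        ax.set_xticks(range(means.n_channels.nunique()))
        ax.set_xticklabels(sorted(means.n_channels.unique()))
        ax.set_xlabel("number of channels")
        ax.set_title(f"mean {metric} (%)")
        ax.set_ylim(50, 100)
    axes[0].legend()
    fig.tight_layout()
    out = RESULTS / "figures" / "ablation_means.png"
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
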