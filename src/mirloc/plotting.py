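"""ROC and precision-recall curve plots for cross-validation reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datamodel import COMPARTMENTS


def plot_curves(y: np.ndarray, probs: np.ndarray, outdir: str | Path) -> list[Path]:
    """Write per-compartment ROC and PR curve figures; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import precision_recall_curve, roc_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind in ("roc", "pr"):
        fig, ax = plt.subplots(figsize=(6, 5))
        for j, name in enumerate(COMPARTMENTS):
            yj = y[:, j]
            if yj.min() == yj.max():
                continue
            if kind == "roc":
                fpr, tpr, _ = roc_curve(yj, probs[:, j])
                ax.plot(fpr, tpr, label=name)
            else:
                prec, rec, _ = precision_recall_curve(yj, probs[:, j])
                ax.plot(rec, prec, label=name)
        if kind == "roc":
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
        else:
            ax.set_xlabel("recall")
            ax.set_ylabel("precision")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"{kind}_curves.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
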