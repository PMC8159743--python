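"""Signed-LOD genome-scan profile figure.

Positive values mean the FVB allele increases the trait; horizontal lines
mark genome-wide permutation thresholds (drawn symmetrically since the
profile is signed).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scan import ScanResult, ThresholdSet

__all__ = ["plot_scan"]


def plot_scan(scan: ScanResult, thresholds: ThresholdSet | None = None, path=None):
    """Plot the signed-lod profile with alternating chromosome shading."""
    fig, ax = plt.subplots(figsize=(11, 3.2))
    tab = scan.table
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(tab.groupby("chrom", sort=False)):
        x = grp["pos_cm"].to_numpy() + offset
        ax.plot(x, grp["signed_lod"], color="C0" if i % 2 == 0 else "C2", lw=0.8)
        ticks.append(offset + grp["pos_cm"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos_cm"].max() + 5
    if thresholds is not None:
        for alpha, thr in sorted(thresholds.thresholds.items()):
            for sign in (1, -1):
                ax.axhline(sign * thr, ls="--", lw=0.7,
                           color="orange" if alpha >= 0.05 else "green")
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(f"signed −log10 p ({scan.trait})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
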