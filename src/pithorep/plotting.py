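"""Visual QC plots (content is for inspection, not asserted by tests)."""

from __future__ import annotations

import numpy as np

from .clustering import Clustering


def _dot_coords(a: str, b: str, k: int = 8):
    """Coordinates of shared k-mers between two sequences (forward only)."""
    from collections import defaultdict

    index = defaultdict(list)
    for i in range(len(a) - k + 1):
        index[a[i : i + k]].append(i)
    xs, ys = [], []
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            xs.append(i)
            ys.append(j)
    return xs, ys


def reference_dotplot_matrix(clustering: Clustering, path, k: int = 8,
                             max_clusters: int = 8) -> None:
    """Matrix of dotplots of cluster reference sequences against each other.

    Used to spot diverged relatives of the main repeat families (e.g. a
    small cluster whose reference still aligns to the M1 reference).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = clustering.clusters[:max_clusters]
    refs = [clustering.units[c.reference].seq for c in clusters]
    n = len(refs)
    fig, axes = plt.subplots(n, n, figsize=(2 * n, 2 * n), squeeze=False)
    for i in range(n):
        for j in range(n):
            ax = axes[i][j]
            xs, ys = _dot_coords(refs[i], refs[j], k=k)
            ax.plot(xs, ys, ".", markersize=1)
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(f"{clusters[j].label or clusters[j].cluster_id}",
                             fontsize=8)
            if j == 0:
                ax.set_ylabel(f"{clusters[i].label or clusters[i].cluster_id}",
                              fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def coverage_plot(profile, regions, path) -> None:
    """Coverage vector, smoothed profile, threshold and detected regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3))
    x = np.arange(len(profile.y))
    ax.plot(x, profile.y, lw=0.3, color="0.7", label="y")
    ax.plot(x, profile.ys, lw=0.8, color="C0", label="ys")
    ax.axhline(profile.tau, color="C3", ls="--", lw=0.8, label="tau")
    for r in regions:
        ax.axvspan(r.start, r.end, color="C1", alpha=0.2)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("alignment multiplicity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
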