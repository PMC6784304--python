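"""Figure side-artifacts: embedding scatters and the MI heatmap.

Figures are outputs only; no later stage reads them back.
"""

from __future__ import annotations

import numpy as np

__all__ = ["embedding_scatter", "mi_heatmap"]


def embedding_scatter(coords, participants, roles, path, title="NMDS embedding"):
    """First two embedding axes, coloured by participant, marker by role
    (star = giver, disc = receiver)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    participants = np.asarray(participants)
    roles = np.asarray(roles)
    fig, ax = plt.subplots(figsize=(6, 5))
    people = sorted(set(participants), key=lambda s: (len(s), s))
    cmap = plt.get_cmap("tab10")
    for i, pid in enumerate(people):
        for role, marker in (("giver", "*"), ("receiver", "o")):
            m = (participants == pid) & (roles == role)
            if m.any():
                ax.scatter(coords[m, 0], coords[m, 1], s=28, marker=marker,
                           color=cmap(i % 10), label=f"{pid} {role}", alpha=0.8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mi_heatmap(mi_frame, path):
    """MI matrix with a percentile-based colour scale: each cell is coloured by
    the percentile rank of its value among all matrix entries."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import rankdata

    vals = mi_frame.to_numpy(float)
    pct = rankdata(vals.ravel(), method="average").reshape(vals.shape)
    pct = 100.0 * pct / pct.size
    n = vals.shape[0]
    fig, ax = plt.subplots(figsize=(0.28 * n + 2, 0.28 * n + 1.5))
    im = ax.imshow(pct, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(n), labels=mi_frame.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(n), labels=mi_frame.index, fontsize=5)
    cbar = fig.colorbar(im, ax=ax, fraction=0.04)
    cbar.set_label("percentile of MI (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
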