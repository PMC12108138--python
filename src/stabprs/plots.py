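"""Optional figure output: score-trait scatter and score distribution.

Matplotlib is imported lazily so the rest of the package works without it.
"""

from __future__ import annotations


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def score_trait_scatter(profile, ph, trait: str = "height_cm", path=None):
    """Scatter of scaled PRS vs trait with the least-squares trend line."""
    import numpy as np

    plt = _pyplot()
    df = ph.data.join(profile.table[["scaled_score"]], how="inner").dropna(subset=[trait])
    x = df["scaled_score"].to_numpy(float)
    y = df[trait].to_numpy(float)
    r = np.corrcoef(x, y)[0, 1] if x.std() > 0 else 0.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=8, alpha=0.5, edgecolors="none")
    if x.std() > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, color="crimson", lw=1.5)
    ax.set_xlabel("PRS (scaled to [0, 1])")
    ax.set_ylabel(trait)
    ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def score_histogram(profile, bins: int = 40, path=None):
    """Distribution of the scaled PRS across the cohort."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(profile.table["scaled_score"], bins=bins, color="steelblue", edgecolor="white")
    ax.set_xlabel("PRS (scaled to [0, 1])")
    ax.set_ylabel("samples")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
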