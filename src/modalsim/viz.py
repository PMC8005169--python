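"""Violin, kernel-density, trace and time-lapse plotting.

Violins are built directly from :func:`modalsim.modality.kde`, so the
density a reader sees is bit-identical to the density the mode-counting
statistics run on.  Rendering contains no randomness of its own: point
jitter is seeded from the run seed, so rerunning a config reproduces the
same figure data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .io import TidyTable  # noqa: E402
from .modality import Kde, kde  # noqa: E402
from .samplers import GroupSpec, child_rngs, sample_group  # noqa: E402
from .trios import SignificanceTrace  # noqa: E402

logger = logging.getLogger(__name__)


def _violin_one(ax, pos, values, bandwidth, rng, width=0.4, color="C0"):
    k = kde(values, bandwidth=bandwidth)
    dens = k.density / k.density.max() * width
    ax.fill_betweenx(k.grid, pos - dens, pos + dens, alpha=0.35, color=color, lw=0.8)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    ax.plot([pos, pos], [q1, q3], color="k", lw=3, solid_capstyle="round")
    ax.plot(pos, med, "o", color="white", mec="k", ms=5, zorder=5)
    jitter = rng.uniform(-width / 4, width / 4, size=len(values))
    ax.plot(pos + jitter, values, ".", color="k", ms=2.5, alpha=0.5)
    return k


def render_violin(table: TidyTable, bandwidth="auto", out_path=None,
                  seed: int = 0) -> tuple[plt.Figure, dict[str, Kde]]:
    """One mirrored-KDE violin per group with median, IQR and data points.

    Returns the figure and the per-group Kde objects actually plotted.
    Empty groups are skipped with a warning.
    """
    groups = table.groups()
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
    kdes: dict[str, Kde] = {}
    rngs = child_rngs(seed, max(len(groups), 1))
    pos = 0
    labels = []
    for (name, values), rng in zip(groups.items(), rngs):
        if values.size == 0:
            logger.warning("render_violin: group %r is empty; skipped", name)
            continue
        kdes[name] = _violin_one(ax, pos, values, bandwidth, rng, color=f"C{pos % 10}")
        labels.append(name)
        pos += 1
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel("outcome (disease severity)")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
    return fig, kdes


def render_trace(trace: SignificanceTrace, out_path=None) -> plt.Figure:
    """Trio-p bars plus the cumulative-p line with the alpha reference.

    The bar layer shows each matched trio-vs-trio comparison; the line
    layer shows the p-value of the accumulating study; crossings of the
    alpha line are the erratic significance flips.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(trace.n_values, trace.trio_p, width=trace.n_values[0] * 0.7,
           color="lightsteelblue", label="trio vs trio p")
    ax.plot(trace.n_values, trace.cumulative_p, "o-", color="crimson",
            label="cumulative p")
    ax.axhline(trace.alpha, color="k", ls="--", lw=1, label=f"alpha = {trace.alpha}")
    ax.set_xlabel("N per group")
    ax.set_ylabel("p-value")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
    return fig


def export_timelapse_frames(specs: list[GroupSpec], n_list, out_dir,
                            bandwidth="auto", seed: int = 101) -> list[Path]:
    """One violin frame per N, lexicographically ordered filenames.

    Emulates watching group distributions take shape as a study grows;
    frame i uses its own child stream of the run seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    paths = []
    rngs = child_rngs(seed, len(n_list))
    for i, (n, rng) in enumerate(zip(n_list, rngs)):
        rows = []
        for spec in specs:
            vals = sample_group(spec, int(n), rng)
            rows.append(pd.DataFrame({"group": spec.name, "value": vals}))
        table = TidyTable(pd.concat(rows, ignore_index=True))
        path = out_dir / f"frame_{i:03d}_n{int(n):06d}.png"
        fig, _ = render_violin(table, bandwidth=bandwidth, out_path=path, seed=seed)
        plt.close(fig)
        paths.append(path)
    return paths
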