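"""Minimal matplotlib renderers for correlation maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .correlation import DCCMatrix  # noqa: E402
from .domains import DomainMap  # noqa: E402


def dccm_heatmap(dccm: DCCMatrix, path, domain_map: DomainMap | None = None,
                 vmin: float = -1.0, vmax: float = 1.0, title: str = ""):
    """Red–white–blue DCCM heatmap with optional domain-boundary ticks."""
    fig, ax = plt.subplots(figsize=(6, 5))
    res = dccm.residue_ids
    im = ax.imshow(dccm.matrix, cmap="RdBu", vmin=vmin, vmax=vmax,
                   origin="lower", extent=[res[0], res[-1], res[0], res[-1]])
    if domain_map is not None:
        bounds = sorted(r[0] for _n, ranges in domain_map.entries for r in ranges)
        for b in bounds[1:]:
            ax.axhline(b - 0.5, color="k", lw=0.4)
            ax.axvline(b - 0.5, color="k", lw=0.4)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="cross-correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
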