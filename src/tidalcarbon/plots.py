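"""Per-core diagnostic profile panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core_io import SoilCore

__all__ = ["plot_core_panels"]


def plot_core_panels(core: SoilCore, ensemble=None, supported_level=None, path=None):
    """Five-panel depth-profile figure: OM, DBD, 137Cs, 210Pb (with the
    supported level), and the age-depth model with a 95% band."""
    fig, axes = plt.subplots(1, 5, figsize=(15, 4.5), sharey=True)
    mids = core.midpoints
    df = core.data

    axes[0].plot(df["loi"] * 100, mids, "o-", ms=3)
    axes[0].set_xlabel("organic matter (%)")
    axes[0].set_ylabel("depth (cm)")

    axes[1].plot(df["dry_bulk_density"], mids, "o-", ms=3, color="tab:brown")
    axes[1].set_xlabel("DBD (g cm$^{-3}$)")

    axes[2].errorbar(df["cs137"], mids, xerr=df["cs137_sd"], fmt="o", ms=3, color="tab:green")
    axes[2].set_xlabel("$^{137}$Cs (Bq kg$^{-1}$)")

    axes[3].errorbar(df["pb210_total"], mids, xerr=df["pb210_total_sd"], fmt="o", ms=3, color="tab:blue",
                     label="total $^{210}$Pb")
    axes[3].errorbar(df["ra226"], mids, xerr=df["ra226_sd"], fmt="s", ms=3, color="tab:orange",
                     label="$^{226}$Ra")
    if supported_level is not None:
        axes[3].axvline(supported_level, ls="--", color="gray", label="supported")
    axes[3].set_xlabel("activity (Bq kg$^{-1}$)")
    axes[3].legend(fontsize=7)

    if ensemble is not None:
        q = np.quantile(ensemble.draws, [0.025, 0.5, 0.975], axis=0)
        z = ensemble.section_boundaries
        axes[4].fill_betweenx(z, q[0], q[2], alpha=0.3, color="tab:purple")
        axes[4].plot(q[1], z, color="tab:purple")
    axes[4].set_xlabel("age (yr before collection)")

    axes[0].invert_yaxis()
    fig.suptitle(core.core_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
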