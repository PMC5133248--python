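"""Optional per-OTU profile figures (control vs labeled, ratio of quantities)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import io as gio
from . import shifts as sh


def plot_pair_profiles(
    table: gio.OtuCountTable,
    runs: dict[str, gio.GradientRun],
    entry: gio.PairEntry,
    outdir: str | Path,
    otu_ids: list[str] | None = None,
) -> list[Path]:
    """One figure per OTU: normalized profiles of control and labeled gradients."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_c = table.for_gradient(entry.control_gradient_id)
    counts_l = table.for_gradient(entry.labeled_gradient_id)
    paths = []
    for otu in otu_ids or table.otu_ids:
        prof_c = sh.build_profile(counts_c.loc[otu].to_numpy(), runs[entry.control_gradient_id], otu)
        prof_l = sh.build_profile(counts_l.loc[otu].to_numpy(), runs[entry.labeled_gradient_id], otu)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(prof_c.densities, prof_c.ratios, "D-", color="tab:blue", label="control (14N)")
        ax.plot(prof_l.densities, prof_l.ratios, "s-", color="tab:red", label="labeled (15N)")
        ax.set_xlabel("buoyant density (g/ml)")
        ax.set_ylabel("ratio of quantities")
        ax.set_title(f"{otu} — {entry.treatment_name}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"profile_{entry.treatment_name}_{otu}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
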