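"""Figure output: force–time / cumulative-work panels and energy profiles."""

from __future__ import annotations

from typing import Dict, List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .energetics import EnergyProfile  # noqa: E402
from .smd import ForceRecord  # noqa: E402
from .work import com_displacement, cumulative_work  # noqa: E402
from .units import work_pn_ang_to_kcal  # noqa: E402


def plot_direction_comparison(records: Dict[str, List[ForceRecord]], path,
                              show_repeats: bool = True) -> None:
    """Two panels per experiment: |F|(t) and cumulative work vs displacement.

    Per-repeat curves are drawn faint with the repeat mean bold, so both
    the spread and the aggregate are visible.
    """
    fig, (ax_f, ax_w) = plt.subplots(2, 1, figsize=(7, 7), sharex=False)
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(records), 3)))
    for color, (label, recs) in zip(colors, records.items()):
        n_min = min(len(r) for r in recs)
        fmag = np.array([np.linalg.norm(r.spring_force[:n_min], axis=1)
                         for r in recs])
        works = np.array([work_pn_ang_to_kcal(cumulative_work(r)[:n_min])
                          for r in recs])
        t = recs[0].time[:n_min]
        disp = com_displacement(recs[0])[:n_min]
        if show_repeats:
            for row_f, row_w in zip(fmag, works):
                ax_f.plot(t, row_f, color=color, alpha=0.25, lw=0.7)
                ax_w.plot(disp, row_w, color=color, alpha=0.25, lw=0.7)
        ax_f.plot(t, fmag.mean(axis=0), color=color, lw=1.8, label=label)
        ax_w.plot(disp, works.mean(axis=0), color=color, lw=1.8, label=label)
    ax_f.set_xlabel("time (ps)")
    ax_f.set_ylabel("|F| (pN)")
    ax_w.set_xlabel("pulled-COM displacement (Å)")
    ax_w.set_ylabel("cumulative work (kcal/mol)")
    ax_w.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_energy_profile(profile: EnergyProfile, path, window: int = 50) -> None:
    """Electrostatic / van der Waals / total interaction energy vs time."""
    sm = profile.smoothed(window)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.time, profile.e_total, color="green", alpha=0.2, lw=0.6)
    ax.plot(sm.time, sm.e_total, color="green", lw=1.8, label="total")
    ax.plot(sm.time, sm.e_elec, color="tab:blue", lw=1.5, label="electrostatic")
    ax.plot(sm.time, sm.e_vdw, color="tab:orange", lw=1.5, label="van der Waals")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("time (ps)")
    ax.set_ylabel("ligand–receptor interaction energy (kcal/mol)")
    ax.legend(fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
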