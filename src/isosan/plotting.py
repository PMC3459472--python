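"""Figure-style plots of control/treated trace pairs."""

from __future__ import annotations

__all__ = ["plot_trace_pair"]

#: Current panels drawn under the voltage trace when available.
PANEL_CURRENTS = ("i_cal", "i_f", "i_k", "i_st", "i_kr", "i_naca")


def plot_trace_pair(bundle: dict, path, *, window_ms: float = 1000.0):
    """Stacked panels (Vm, selected currents, [Ca2+]_i) for a control +
    treated trace bundle from ``export_figure_traces``; saved to `path`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    control, treated = bundle["control"], bundle["treated"]
    currents = [c for c in PANEL_CURRENTS if c in control.currents]
    n_panels = 1 + len(currents) + (1 if control.cai is not None else 0)
    fig, axes = plt.subplots(n_panels, 1, sharex=True,
                             figsize=(7, 1.6 * n_panels))
    axes = [axes] if n_panels == 1 else list(axes)

    def seg(tr):
        n = min(len(tr.time), int(round(window_ms / tr.dt)) + 1)
        return tr.time[:n] - tr.time[0], slice(0, n)

    for tr, label, style in ((control, "control", "k-"),
                             (treated, f"{bundle['dose_nm']:g} nM ISO", "r-")):
        t, sl = seg(tr)
        axes[0].plot(t, tr.vm[sl], style, lw=0.9, label=label)
        for ax, cur in zip(axes[1:], currents):
            ax.plot(t, tr.currents[cur][sl] * 1000.0, style, lw=0.9)
        if tr.cai is not None:
            axes[-1].plot(t, tr.cai[sl] * 1e3, style, lw=0.9)

    axes[0].set_ylabel("Vm (mV)")
    axes[0].legend(loc="upper right", fontsize=7, frameon=False)
    for ax, cur in zip(axes[1:], currents):
        ax.set_ylabel(f"{cur} (pA)", fontsize=8)
    if control.cai is not None:
        axes[-1].set_ylabel("[Ca2+]i (uM)", fontsize=8)
    axes[-1].set_xlabel("time (ms)")
    fig.suptitle(f"{bundle['model']} — {bundle['scenario']}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
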