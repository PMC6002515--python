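"""Plot helpers for simulation traces and reconstructions."""

from __future__ import annotations


def plot_trace(trace, path=None):
    """Panel layout of a closed-loop run: control C and its rate, the
    perceptual quantities P / P_r / P_p, and the accumulator activation
    with adjustment onsets marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = trace.times
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 8))
    axes[0].plot(t, trace.C, "k")
    axes[0].set_ylabel("C")
    axes[1].plot(t, trace.Cdot, "k")
    axes[1].set_ylabel("dC/dt")
    axes[2].plot(t, trace.Pr, label="P_r")
    axes[2].plot(t, trace.Pp, label="P_p")
    axes[2].plot(t, trace.P, ":", label="P")
    axes[2].legend(loc="upper right", fontsize=8)
    axes[2].set_ylabel("control error")
    axes[3].plot(t, trace.A, "k")
    axes[3].set_ylabel("A")
    axes[3].set_xlabel("t (s)")
    for ev in trace.events:
        for ax in axes:
            ax.axvline(ev.t, color="0.8", lw=0.5, zorder=0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_reconstruction(series, result, path=None):
    """Recorded vs reconstructed signal with adjustment onsets marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(series.times, series.values, "k", lw=0.8, label="recorded")
    ax.plot(result.reconstructed.times, result.reconstructed.values, "r",
            lw=0.8, label="reconstructed")
    for t, flag in zip(result.onsets, result.overfit_flags):
        ax.axvline(t, color="orange" if flag else "0.85", lw=0.5, zorder=0)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("C")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
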