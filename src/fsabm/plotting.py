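"""Minimal charts for scenario summaries (adoption curves, cash flow)."""

from __future__ import annotations

from .runner import SummaryTable


def plot_series(table: SummaryTable, column: str, ylabel: str | None = None, path=None):
    """Plot the per-tick mean of ``column`` for every scenario, with the
    2.5-97.5 percentile band across repeats; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, frame in table.per_tick.items():
        ax.plot(frame["tick"], frame[f"{column}_mean"], label=name)
        ax.fill_between(frame["tick"], frame[f"{column}_q025"], frame[f"{column}_q975"], alpha=0.15)
    ax.set_xlabel("tick (days)")
    ax.set_ylabel(ylabel or column)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_adoption(table: SummaryTable, path=None):
    return plot_series(table, "installed", "households with Skyloo installed", path)


def plot_cash(table: SummaryTable, path=None):
    column = "cash" if table.model == "skyloo" else "council_cash"
    return plot_series(table, column, "cash (MK)", path)
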