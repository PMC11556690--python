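"""Optional figure output: tornado chart, incremental plane, acceptability curve."""
from __future__ import annotations

import pathlib
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .sensitivity import TornadoEntry

__all__ = ["tornado_plot", "psa_scatter_plot", "ceac_plot"]


def tornado_plot(
    entries: Iterable[TornadoEntry],
    base_icer: float,
    path: str | pathlib.Path,
    top: int = 15,
) -> None:
    entries = list(entries)[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted([e.icer_low, e.icer_high])
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=7)
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def psa_scatter_plot(
    draws: pd.DataFrame, wtp: float, path: str | pathlib.Path
) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        draws["incremental_qaly"], draws["incremental_cost"], s=4, alpha=0.25
    )
    q = draws["incremental_qaly"]
    lim = max(abs(q.min()), abs(q.max()))
    xs = [-lim, lim]
    ax.plot(xs, [wtp * x for x in xs], "r--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(acceptability: Mapping[float, float], path: str | pathlib.Path) -> None:
    wtps = sorted(acceptability)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(wtps, [acceptability[w] for w in wtps], marker="o")
    ax.set_xlabel("Willingness-to-pay (USD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
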