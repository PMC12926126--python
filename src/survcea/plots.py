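"""Matplotlib figures for the sensitivity and threshold analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import PSAResult, TornadoEntry


def tornado_plot(entries: list[TornadoEntry], base_icer: float,
                 path: str | Path, top: int = 12) -> None:
    sel = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(sel) + 1.5))
    for i, e in enumerate(sel):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
    ax.set_yticks(range(len(sel)))
    ax.set_yticklabels([e.parameter for e in sel], fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_scatter(result: PSAResult, wtp: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_effect, result.delta_cost, s=6, alpha=0.4)
    grid = np.linspace(min(0, result.delta_effect.min()),
                       result.delta_effect.max() * 1.05, 50)
    ax.plot(grid, wtp * grid, "k--", lw=1, label=f"WTP {wtp:,.0f}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: list[tuple[float, float]], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    xs, ys = zip(*curve)
    ax.plot(xs, ys)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def threshold_plot(fractions: np.ndarray, icers: np.ndarray, wtp: float,
                   path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(fractions, icers)
    ax.axhline(wtp, color="k", ls="--", lw=1, label=f"WTP {wtp:,.0f}")
    ax.set_xlabel("fraction of nominal ramucirumab price")
    ax.set_ylabel("ICER (USD/QALY)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
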