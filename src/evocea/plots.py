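"""Optional figures: CE plane scatter, acceptability curve, tornado diagram."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cea import CeacCurve, DsaResult, PsaSample

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(samples: Sequence[PsaSample], path, names=("a", "b")) -> None:
    """Incremental cost vs incremental effectiveness of the PSA draws."""
    d_eff = [s.eff_b - s.eff_a for s in samples]
    d_cost = [s.cost_b - s.cost_a for s in samples]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d_eff, d_cost, s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel(f"Δ effectiveness ({names[1]} − {names[0]})")
    ax.set_ylabel("Δ cost (BRL)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path, names=("a", "b")) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.wtp, curve.prob_a, label=names[0])
    ax.plot(curve.wtp, curve.prob_b, label=names[1])
    ax.set_xlabel("Willingness to pay (BRL per outcome avoided)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(dsa: DsaResult, path) -> None:
    entries = [e for e in dsa.entries if e.icer_low is not None and e.icer_high is not None]
    labels = [e.parameter for e in entries][::-1]
    lows = [min(e.icer_low, e.icer_high) for e in entries][::-1]
    highs = [max(e.icer_low, e.icer_high) for e in entries][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(entries), 4) + 1))
    ax.barh(labels, [h - l for l, h in zip(lows, highs)], left=lows, color="#4878d0")
    if dsa.base_icer is not None:
        ax.axvline(dsa.base_icer, color="black", lw=1, ls="--", label="base ICER")
        ax.legend()
    ax.set_xlabel("ICER (BRL per outcome avoided)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
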