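"""File outputs: CSV/JSON tables, plots, and the run manifest."""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse

from . import __version__
from .cea import CEATable
from .engine import CohortTrace
from .sensitivity import CEACCurve, ICEScatter, PSAOutcomes, TornadoEntry, tornado_frame


@dataclass
class RunManifest:
    """Audit record written next to every command's outputs."""

    command: str
    config: str
    seed: int | None
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def write_cea_table(table: CEATable, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    csv_path = out_dir / "cea_table.csv"
    table.to_frame().to_csv(csv_path, index=False, float_format="%.2f")
    json_path = out_dir / "cea_table.json"
    json_path.write_text(json.dumps({
        "comparator": table.comparator,
        "wtp": table.wtp,
        "recommended": table.recommended,
        "frontier": table.frontier,
        "entries": json.loads(table.to_frame().to_json(orient="records")),
    }, indent=2) + "\n")
    return [csv_path, json_path]


def write_trace(trace: CohortTrace, out_dir: Path) -> Path:
    path = Path(out_dir) / f"trace_{trace.strategy}.csv"
    trace.to_frame().to_csv(path, index=False)
    return path


def write_tornado(entries: Sequence[TornadoEntry], out_dir: Path) -> Path:
    path = Path(out_dir) / "tornado.csv"
    tornado_frame(entries).to_csv(path, index=False)
    return path


def plot_tornado(entries: Sequence[TornadoEntry], out_dir: Path) -> Path:
    """Horizontal-bar tornado: ICER range per parameter around the base ICER."""
    numeric = [e for e in entries
               if not isinstance(e.icer_at_low, str)
               and not isinstance(e.icer_at_high, str)
               and e.swing > 0]
    path = Path(out_dir) / "tornado.png"
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.4 * len(numeric) + 1)))
    if numeric:
        base = numeric[0].base_icer
        order = numeric[::-1]  # widest bar on top
        for i, e in enumerate(order):
            lo = min(e.icer_at_low, e.icer_at_high)
            hi = max(e.icer_at_low, e.icer_at_high)
            ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
        ax.axvline(base, color="black", lw=1, label=f"base ICER = {base:,.2f}")
        ax.set_yticks(range(len(order)), [e.parameter for e in order])
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_psa_draws(psa: PSAOutcomes, out_dir: Path) -> Path:
    path = Path(out_dir) / "psa_draws.csv"
    psa.to_frame().to_csv(path, index=False)
    return path


def write_ceac(curve: CEACCurve, out_dir: Path) -> Path:
    path = Path(out_dir) / "ceac.csv"
    curve.to_frame().to_csv(path, index=False)
    return path


def plot_ceac(curve: CEACCurve, out_dir: Path, wtp: float | None = None) -> Path:
    path = Path(out_dir) / "ceac.png"
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s in curve.strategies:
        ax.plot(curve.wtp_grid, curve.probability(s), label=s)
    if wtp is not None:
        ax.axvline(wtp, color="grey", ls="--", lw=1, label=f"WTP = {wtp:,.0f}")
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    ax.set_title("Cost-effectiveness acceptability curves")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ice_scatter(scatter: ICEScatter, out_dir: Path,
                     wtp: float | None = None,
                     label: str = "rivaroxaban vs warfarin") -> Path:
    path = Path(out_dir) / "ice_scatter.png"
    fig, ax = plt.subplots(figsize=(6.5, 5))
    ax.scatter(scatter.delta_qaly, scatter.delta_cost, s=6, alpha=0.4,
               color="#4878a8", label=label)
    semi, _, angle = scatter.ellipse_axes()
    ax.add_patch(Ellipse(xy=scatter.center, width=2 * semi[0], height=2 * semi[1],
                         angle=angle, fill=False, color="crimson", lw=1.5,
                         label=f"{scatter.coverage:.0%} ellipse"))
    if wtp is not None:
        xs = ax.get_xlim()
        ax.plot(xs, [wtp * x for x in xs], color="grey", ls="--", lw=1,
                label=f"WTP = {wtp:,.0f}")
        ax.set_xlim(xs)
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title("Incremental cost-effectiveness plane")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
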