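"""Report rendering: run manifests, plain-text tables, delimited data files
and the standard figures (tornado, cost-effectiveness plane, ICER histogram,
acceptability curve, price-prevalence contour).

Data files never carry currency symbols or thousands separators; those
appear only in the human-readable summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .economics import StrategyResult, icer
from .sensitivity import PSAResult, ThresholdGrid, TornadoEntry

__all__ = [
    "RunManifest",
    "format_thb",
    "strategy_table_text",
    "write_manifest",
    "plot_tornado",
    "plot_ce_plane",
    "plot_icer_histogram",
    "plot_ceac",
    "plot_threshold",
]


@dataclass(frozen=True)
class RunManifest:
    """Provenance record attached to every output bundle."""

    command: str
    parameter_digest: str
    seed: Optional[int]
    accounting_mode: str
    version: str = field(default="")
    timestamp: str = field(default="")

    @staticmethod
    def create(
        command: str,
        params_path: Optional[Path],
        seed: Optional[int],
        mode: str,
    ) -> "RunManifest":
        if params_path is not None and Path(params_path).exists():
            digest = hashlib.sha256(Path(params_path).read_bytes()).hexdigest()[:16]
        else:
            digest = "builtin-base-case"
        return RunManifest(
            command=command,
            parameter_digest=digest,
            seed=seed,
            accounting_mode=mode,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return path


def format_thb(amount: float) -> str:
    """Whole-baht rendering with thousands separators, e.g. ฿1,986,200."""
    return f"฿{amount:,.0f}"


def strategy_table_text(
    results: dict[str, StrategyResult],
    wtp_lower: float,
    wtp_upper: float,
    reference: str = "none",
) -> str:
    """Published-style summary: QALYs, cost and ICER vs. no routine screening."""
    from .economics import wtp_verdict  # local import to avoid cycle at module load

    ref = results[reference]
    lines = [
        f"Cost and QALY summary ({ref.accounting_mode} accounting, "
        f"cohort of {ref.cohort_size:g}, ICERs vs. No routine screening)",
        f"{'Strategy':<22}{'QALYs':>12}{'Total cost':>16}{'ICER (THB/QALY)':>20}",
    ]
    order = [reference] + [k for k in results if k != reference]
    for name in order:
        res = results[name]
        if name == reference:
            icer_txt = "Reference"
        else:
            inc = icer(ref, res)
            icer_txt = format_thb(inc.icer) if inc.icer is not None else inc.dominance
        lines.append(
            f"{name:<22}{res.qalys:>12.2f}{format_thb(res.cost):>16}{icer_txt:>20}"
        )
    for name in order:
        if name == reference:
            continue
        inc = icer(ref, results[name])
        if inc.icer is not None or inc.dominance in ("dominant", "dominated"):
            verdict = wtp_verdict(inc, wtp_lower, wtp_upper)
            lines.append(
                f"{name} vs. {reference}: {verdict.replace('_', ' ')} at WTP "
                f"{format_thb(wtp_lower)}-{format_thb(wtp_upper)}/QALY"
            )
    return "\n".join(lines)


def plot_tornado(
    base_nmb: float, entries: list[TornadoEntry], path: Path, top: int = 12
) -> None:
    entries = entries[:top][::-1]
    names = [e.parameter for e in entries]
    lows = np.array([min(e.nmb_low, e.nmb_high) for e in entries])
    highs = np.array([max(e.nmb_low, e.nmb_high) for e in entries])
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    ax.barh(names, highs - lows, left=lows, color="#4878cf")
    ax.axvline(base_nmb, color="k", lw=1)
    ax.set_xlabel("Net monetary benefit (THB, cohort)")
    ax.set_title("One-way sensitivity analysis")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(psa: PSAResult, wtp_lines: tuple[float, ...], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.25, color="#4878cf")
    q = np.linspace(min(psa.delta_qaly.min(), 0), psa.delta_qaly.max(), 50)
    for wtp, style in zip(wtp_lines, ("--", ":")):
        ax.plot(q, wtp * q, style, color="gray", label=f"WTP {wtp:,.0f}")
    ax.axhline(0, color="k", lw=0.7)
    ax.axvline(0, color="k", lw=0.7)
    ax.set_xlabel("Incremental QALYs (cohort)")
    ax.set_ylabel("Incremental cost (THB, cohort)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_icer_histogram(psa: PSAResult, wtp_lines: tuple[float, ...], path: Path) -> None:
    icers = psa.icers
    icers = icers[np.isfinite(icers)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(icers, bins=60, color="#4878cf")
    for wtp, color in zip(wtp_lines, ("green", "red")):
        ax.axvline(wtp, color=color, ls="--", label=f"WTP {wtp:,.0f}")
    ax.set_xlabel("ICER (THB/QALY)")
    ax.set_ylabel("Simulations")
    ax.set_title("ICER distribution")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(lambda_grid: np.ndarray, prob: np.ndarray, wtp_lines: tuple[float, ...], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lambda_grid, prob, color="#4878cf")
    for wtp in wtp_lines:
        ax.axvline(wtp, color="gray", ls="--")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness-to-pay (THB/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_threshold(grid: ThresholdGrid, base_price: float, base_prev: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        grid.price_grid,
        100 * grid.prevalence_grid,
        np.where(grid.cost_effective, 1.0, 0.0),
        cmap="RdYlGn",
        shading="nearest",
        vmin=0,
        vmax=1,
    )
    ax.plot([base_price], [100 * base_prev], "o", color="blue", label="base case")
    ax.set_xlabel("AChR-Ab test price (THB)")
    ax.set_ylabel("MG prevalence (%)")
    ax.set_title(f"Cost-effective region at WTP {grid.wtp:,.0f} THB/QALY")
    ax.legend()
    fig.colorbar(mesh, ax=ax, label="cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def threshold_frame(grid: ThresholdGrid) -> pd.DataFrame:
    rows = []
    for r, prev in enumerate(grid.prevalence_grid):
        for c, price in enumerate(grid.price_grid):
            rows.append(
                {
                    "prevalence": prev,
                    "price_thb": price,
                    "icer_thb_per_qaly": grid.icer[r, c],
                    "cost_effective": bool(grid.cost_effective[r, c]),
                }
            )
    return pd.DataFrame(rows)
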