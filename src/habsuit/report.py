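"""Artifact writing: CSV/GeoTIFF outputs, PNG charts, and the HTML report.

Every CSV starts with a comment line recording the master seed and the
configuration hash so outputs are traceable to their run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curves import curve_to_lookup, curve_to_text
from .fitting import aic as fitting_aic
from .histograms import histograms_to_frame
from .model import HSModel, ROCResult
from .montecarlo import MCResult
from .raster import Raster, write_raster

__all__ = [
    "write_csv",
    "write_fit_outputs",
    "write_mc_outputs",
    "render_html_report",
]


def write_csv(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# habsuit seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _plot(fig, path: Path) -> None:
    fig.savefig(path, dpi=110, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)


def _model_graph_png(var, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    c = var.hist_all.centers
    ax.fill_between(c, var.hist_all.rescaled(), color="green", alpha=0.35, label="f (all pixels)")
    ax.fill_between(c, var.hist_occ.rescaled(), color="red", alpha=0.35, label="f1 (occurrences)")
    ax.plot(c, var.hist_ratio.rescaled(), color="blue", lw=1, label="f1/f")
    ax.plot(c, curve_to_lookup(var.curve), color="black", lw=2, label="model")
    ax.set_xlabel(var.name)
    ax.set_ylabel("rescaled frequency / suitability")
    ax.legend(fontsize=7)
    _plot(fig, path)


def _map_png(r: Raster, path: Path, title: str) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(
        r.values,
        extent=(r.extent[0], r.extent[2], r.extent[1], r.extent[3]),
        cmap="viridis",
        vmin=0.0,
    )
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title, fontsize=9)
    _plot(fig, path)


def write_fit_outputs(
    model: HSModel, roc: ROCResult, suit: Raster, outdir: Path,
    seed: int, config_hash: str, aic_convention: str = "paper",
) -> None:
    """Per-variable model graphs and curves, combined map, ROC, statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in model.variables:
        write_csv(
            histograms_to_frame(v.hist_all, v.hist_occ, v.hist_ratio).assign(
                model=curve_to_lookup(v.curve)
            ),
            outdir / f"model_graph_{v.name}.csv",
            seed, config_hash,
        )
        (outdir / f"curve_{v.name}.txt").write_text(curve_to_text(v.curve))
        _model_graph_png(v, outdir / f"model_graph_{v.name}.png")
        rows.append(
            {
                "variable": v.name,
                "loglik": v.fit.loglik,
                "aic": v.fit.aic,
                "evaluations": v.fit.evaluations,
            }
        )
    stats = pd.DataFrame(rows)
    stats.loc[len(stats)] = {
        "variable": "(combined)",
        "loglik": model.loglik,
        "aic": model.aic(),
        "evaluations": np.nan,
    }
    stats["auc"] = np.nan
    stats.loc[stats["variable"] == "(combined)", "auc"] = roc.auc
    write_csv(stats, outdir / "statistics.csv", seed, config_hash)
    levels = pd.DataFrame(
        [
            {
                "variable": v.name,
                "level": level,
                "loglik": lnl,
                "aic": fitting_aic(lnl, 6, aic_convention),
                "evaluations": n_eval,
            }
            for v in model.variables
            for (level, lnl, n_eval) in v.fit.levels
        ]
    )
    write_csv(levels, outdir / "fit_levels.csv", seed, config_hash)
    write_csv(
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]),
        outdir / "roc.csv", seed, config_hash,
    )
    write_raster(suit, outdir / "suitability.tif")
    _map_png(suit, outdir / "suitability.png", "habitat suitability")


def write_mc_outputs(res: MCResult, outdir: Path, seed: int, config_hash: str) -> None:
    """Uncertainty maps, envelopes, iteration and running statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, r in res.maps.items():
        write_raster(r, outdir / f"suitability_{name}.tif")
        _map_png(r, outdir / f"suitability_{name}.png", f"suitability ({name})")
    write_csv(res.stats, outdir / "iterations.csv", seed, config_hash)
    write_csv(res.running, outdir / "running.csv", seed, config_hash)
    for stat in ("loglik", "aic", "auc"):
        counts, edges = np.histogram(res.stats[stat], bins=20)
        write_csv(
            pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}),
            outdir / f"{stat}_histogram.csv", seed, config_hash,
        )
    for name, env in res.envelopes.items():
        write_csv(env, outdir / f"envelope_{name}.csv", seed, config_hash)
    if res.jackknife is not None:
        write_csv(res.jackknife, outdir / "jackknife.csv", seed, config_hash)
    _mc_charts(res, outdir)
    render_html_report(outdir, res)


def _mc_charts(res: MCResult, outdir: Path) -> None:
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].plot(res.running["iteration"], res.running["auc_mean"])
    axes[0].set_title("running mean AUC", fontsize=9)
    axes[1].plot(res.running["iteration"], res.running["aic_mean"])
    axes[1].set_title("running mean AIC", fontsize=9)
    for ax in axes:
        ax.set_xlabel("iteration")
    _plot(fig, outdir / "running.png")

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].hist(res.stats["auc"], bins=20, color="steelblue")
    axes[0].set_title("AUC histogram", fontsize=9)
    axes[1].hist(res.stats["aic"], bins=20, color="indianred")
    axes[1].set_title("AIC histogram", fontsize=9)
    _plot(fig, outdir / "histograms.png")

    for name, env in res.envelopes.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.fill_between(env["center"], env["min"], env["max"], alpha=0.25, label="min-max")
        ax.fill_between(env["center"], env["lo95"], env["hi95"], alpha=0.35, label="95% interval")
        ax.plot(env["center"], env["mean"], color="black", lw=1.5, label="mean")
        ax.set_xlabel(name)
        ax.set_ylabel("suitability")
        ax.legend(fontsize=7)
        _plot(fig, outdir / f"envelope_{name}.png")


def render_html_report(outdir: Path, res: MCResult | None = None) -> Path:
    """Single-page HTML linking the charts and maps in an output directory."""
    outdir = Path(outdir)
    pngs = sorted(p.name for p in outdir.glob("*.png"))
    csvs = sorted(p.name for p in outdir.glob("*.csv"))
    parts = ["<html><head><title>habsuit report</title></head><body>"]
    parts.append("<h1>Monte Carlo habitat suitability report</h1>")
    if res is not None:
        s = res.stats
        parts.append(
            "<p>iterations: %d | mean AUC %.4f (sd %.4f) | mean AIC %.1f (sd %.1f)</p>"
            % (len(s), s["auc"].mean(), s["auc"].std(ddof=0), s["aic"].mean(), s["aic"].std(ddof=0))
        )
    for png in pngs:
        parts.append(f'<div><h3>{png}</h3><img src="{png}" /></div>')
    parts.append("<h2>Tables</h2><ul>")
    for csv in csvs:
        parts.append(f'<li><a href="{csv}">{csv}</a></li>')
    parts.append("</ul></body></html>")
    path = outdir / "report.html"
    path.write_text("\n".join(parts), encoding="utf-8")
    return path
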