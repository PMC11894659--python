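"""Contour plots, bootstrap bands, threshold selection and orchestration.

The contour report draws one pFDP-vs-FDR line per QF threshold (colour-graded
by threshold, dashed when fewer than the recommended number of PSMs survived
filtering) against the x = y reference.  The optimised single-line plot shows
the most stable scenario with bootstrapped 68% pointwise confidence bands
(16th/84th percentiles of resampled pFDP).  ``run_validation`` executes the
whole pipeline from a configuration file and writes TSV twins of every
figure, so headless environments can run data-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import estimators as est  # noqa: E402
from .errors import ConfigError  # noqa: E402
from .labeling import QfGrid  # noqa: E402
from .model import PartitionValidation, ValidationResults, default_fdr_grid  # noqa: E402
from .psm_io import read_config, read_psm_table  # noqa: E402


@dataclass
class QfScan:
    """Ordered collection of validation curves across the QF grid."""

    curves: list
    level: str = "psm"

    def __post_init__(self):
        if not self.curves:
            raise ConfigError("a QF scan needs at least one curve")
        thr = [c.qf_threshold for c in self.curves]
        if not all(b > a for a, b in zip(thr, thr[1:])):
            raise ConfigError("QF thresholds must be strictly increasing")


@dataclass
class BandedCurve:
    """Single pFDP-vs-FDR line with bootstrapped pointwise bands.

    ``grid`` columns: fdr_threshold, pfdp, band_low, band_high, masked.
    """

    qf_threshold: float
    grid: pd.DataFrame
    n_bootstrap: int

    @property
    def mean_width(self) -> float:
        g = self.grid[~self.grid["masked"]]
        return float((g["band_high"] - g["band_low"]).mean())


def bootstrap_band(labeled: pd.DataFrame, qvalues, fdr_grid, B: int = 1000,
                   seed: int = 0, qf_threshold: float = float("nan"),
                   level: tuple = (16.0, 84.0)) -> BandedCurve:
    """Percentile bootstrap bands for pFDP at each FDR grid point.

    PSMs are resampled with replacement B times; at each grid point the band
    is the 16th/84th percentile of the resampled pFDP (a symmetric 68%
    pointwise interval) around the full-sample point estimate.  Points whose
    acceptance set is empty in more than half of the resamples are masked.
    """
    if B < 100:
        raise ConfigError("B must be >= 100 for stable percentile bands")
    q = np.asarray(qvalues, dtype=float)
    inc = (labeled["status"].to_numpy() == "incorrect").astype(np.float64)
    n = len(q)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    inc_rs = inc[idx]
    rows = []
    for g in np.asarray(fdr_grid, dtype=float):
        acc = q <= g
        n_acc = int(acc.sum())
        point = float(inc[acc].sum() / n_acc) if n_acc else float("nan")
        acc_rs = acc[idx]
        den = acc_rs.sum(axis=1)
        ok = den > 0
        masked = ok.sum() <= B / 2 or n_acc == 0
        if masked:
            lo = hi = float("nan")
        else:
            vals = (inc_rs * acc_rs).sum(axis=1)[ok] / den[ok]
            lo, hi = np.percentile(vals, level)
        rows.append({"fdr_threshold": float(g), "pfdp": point,
                     "band_low": float(lo), "band_high": float(hi),
                     "masked": bool(masked)})
    return BandedCurve(qf_threshold=float(qf_threshold),
                       grid=pd.DataFrame(rows), n_bootstrap=B)


def select_stable_threshold(results, min_psms: int = 1000,
                            B: int = 200, seed: int = 0) -> float:
    """QF threshold with the narrowest mean bootstrap band.

    Only curves retaining at least ``min_psms`` labeled PSMs compete (the
    recommended floor for a usable subset search); ties go to the larger
    threshold.  Invariant to the ordering of the curves.
    """
    curves = results.curves if isinstance(results, ValidationResults) \
        else list(results)
    eligible = [c for c in curves if c.n_labeled >= min_psms]
    if not eligible:
        raise ConfigError(
            f"no QF threshold retains {min_psms} labeled PSMs; widen the QF "
            f"range toward lower thresholds")
    fdr_grid = None
    if isinstance(results, ValidationResults):
        fdr_grid = results.model.fdr_grid
    best_thr, best_width = None, None
    for c in sorted(eligible, key=lambda c: c.qf_threshold):
        grid = fdr_grid if fdr_grid is not None else \
            c.grid["fdr_threshold"].to_numpy()
        band = bootstrap_band(c.labeled, c.qvalues, grid, B=B, seed=seed,
                              qf_threshold=c.qf_threshold)
        w = band.mean_width
        if best_width is None or w <= best_width:  # <=: tie -> larger threshold
            best_thr, best_width = c.qf_threshold, w
    return float(best_thr)


# ---------------------------------------------------------------------------
# figures (TSV twins carry exactly the plotted numbers)
# ---------------------------------------------------------------------------

def plot_contour(results, ax=None, cmap: str = "viridis"):
    """One pFDP-vs-FDR line per QF threshold, x = y reference, dashed when
    the curve is unstable (too few retained PSMs)."""
    curves = results.curves if isinstance(results, ValidationResults) \
        else list(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    thr = np.array([c.qf_threshold for c in curves])
    cm = plt.get_cmap(cmap)
    span = np.ptp(thr) or 1.0
    for c in curves:
        color = cm((c.qf_threshold - thr.min()) / span)
        ax.plot(c.grid["fdr_threshold"], c.grid["pfdp"],
                color=color, linestyle="-" if c.stable else "--",
                label=f"QF {c.qf_threshold:.3g}" if len(curves) <= 12 else None)
    lims = ax.get_xlim()
    ref = np.linspace(0, max(lims[1], 0.5), 10)
    ax.plot(ref, ref, color="orange", lw=1, zorder=0)
    ax.set_xlabel("FDR estimate threshold")
    ax.set_ylabel("proxy FDP")
    if len(curves) <= 12:
        ax.legend(fontsize=7)
    return ax


def plot_band(band: BandedCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    g = band.grid[~band.grid["masked"]]
    ax.plot(g["fdr_threshold"], g["pfdp"], color="C0",
            label=f"QF {band.qf_threshold:.3g}")
    ax.fill_between(g["fdr_threshold"], g["band_low"], g["band_high"],
                    alpha=0.3, color="C0", label="68% band")
    ref = np.linspace(0, g["fdr_threshold"].max(), 10)
    ax.plot(ref, ref, color="orange", lw=1, zorder=0)
    ax.set_xlabel("FDR estimate threshold")
    ax.set_ylabel("proxy FDP")
    ax.legend(fontsize=8)
    return ax


def contour_report(results, out_dir, name: str = "contour",
                   formats=("png", "svg")) -> dict[str, Path]:
    """Write the contour figure and its TSV twin."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves = results.curves if isinstance(results, ValidationResults) \
        else list(results)
    if not curves:
        raise ConfigError("empty scan")
    frame = results.curves_frame() if isinstance(results, ValidationResults) \
        else pd.concat(
            [c.grid.assign(qf_threshold=c.qf_threshold) for c in curves],
            ignore_index=True)
    paths = {"tsv": out / f"{name}.tsv"}
    frame.to_csv(paths["tsv"], sep="\t", index=False)
    ax = plot_contour(results)
    fig = ax.figure
    fig.tight_layout()
    for ext in formats:
        p = out / f"{name}.{ext}"
        fig.savefig(p)
        paths[ext] = p
    plt.close(fig)
    return paths


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

def _model_from_config(cfg: dict) -> tuple[PartitionValidation, dict]:
    try:
        inp = cfg["input"]
        table = read_psm_table(
            inp["psm_table"],
            score_name=inp.get("score_name", "score"),
            score_orientation=inp.get("score_orientation", "higher_better"))
        decoy_table = None
        if "decoy_table" in inp:
            decoy_table = read_psm_table(
                inp["decoy_table"],
                score_orientation=inp.get("score_orientation", "higher_better"))
        run = cfg.get("run", {})
        part = cfg.get("partition", {})
        qf = cfg.get("qf", {})
        fdr = cfg.get("fdr", {})
        if "thresholds" in qf:
            grid = QfGrid(tuple(qf["thresholds"]),
                          min_retained_psms=qf.get("min_retained", 1000))
        else:
            lo, hi, npts = qf.get("quantiles", [0.5, 0.99, 10])
            grid = QfGrid.from_quantiles(
                table, np.linspace(lo, hi, int(npts)),
                min_retained_psms=qf.get("min_retained", 1000))
        fdr_grid = np.logspace(np.log10(fdr.get("grid_min", 0.001)),
                               np.log10(fdr.get("grid_max", 0.5)),
                               int(fdr.get("grid_points", 50)))
        null_table = None
        if "null_table" in fdr:
            null_table = est.load_null_table(fdr["null_table"])
        model = PartitionValidation(
            table,
            decoy_table=decoy_table,
            mode=run.get("mode", "postsearch"),
            level=run.get("level", "psm"),
            seed=int(run.get("seed", 0)),
            k=int(part.get("k", 2)),
            top_n=part.get("top_n"),
            qf_grid=grid,
            fdr_method=fdr.get("method", "tdc"),
            fdr_grid=fdr_grid,
            score_kind=fdr.get("score_kind", "space_independent"),
            gumbel_scale=fdr.get("gumbel_scale"),
            storey=est.StoreyConfig(pi0_lambda=fdr.get("pi0_lambda", 0.5)),
            null_table=null_table,
            n_candidates=fdr.get("n_candidates"),
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration key: {exc}") from exc
    return model, cfg.get("report", {})


def save_results(results: ValidationResults, out_dir, plots: bool = True,
                 B: int = 200, seed: int = 0) -> dict[str, Path]:
    """Write curves, labels, diagnostics, figures and a run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = results.model
    paths: dict[str, Path] = {}

    paths["curves"] = out / "curves.tsv"
    results.curves_frame().to_csv(paths["curves"], sep="\t", index=False)

    best = results.select_stable_threshold(B=B, seed=seed)
    band = results.bootstrap_band(best, B=max(B, 100), seed=seed)
    paths["band"] = out / "banded_curve.tsv"
    band.grid.assign(qf_threshold=best).to_csv(paths["band"], sep="\t",
                                               index=False)
    paths["labels"] = out / "labels.tsv"
    results.curve(best).labeled[
        ["spectrum_id", "peptide", "validation_score", "status"]
    ].to_csv(paths["labels"], sep="\t", index=False)

    if len(results.ks_table):
        paths["ks"] = out / "ks_diagnostics.tsv"
        results.ks_table.to_csv(paths["ks"], sep="\t", index=False)

    paths["summary"] = out / "summary.json"
    summary = {
        "mode": m.mode, "level": m.level, "k": m.k, "seed": m.seed,
        "fdr_method": m.fdr_method, "score_kind": m.score_kind,
        "n_spectra": int(m.table.n_spectra),
        "qf_thresholds": [float(t) for t in m.qf_grid.thresholds],
        "selected_qf_threshold": float(best),
        "mean_band_width": band.mean_width,
        "n_labeled": {f"{c.qf_threshold:g}": int(c.n_labeled)
                      for c in results.curves},
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    paths["log"] = out / "run.log"
    paths["log"].write_text(results.summary() + "\n")

    if plots:
        paths.update(contour_report(results, out))
        ax = plot_band(band)
        fig = ax.figure
        fig.tight_layout()
        for ext in ("png", "svg"):
            p = out / f"banded_curve.{ext}"
            fig.savefig(p)
            paths[f"band_{ext}"] = p
        plt.close(fig)
    return paths


def run_validation(config_path, out_dir=None, plots: bool | None = None):
    """Execute the full validation pipeline described by a config file.

    Returns the output directory; writes curves/labels/diagnostics TSVs, the
    contour and banded figures, a machine-readable summary and a run log.
    Identical configuration and seed produce byte-identical TSV outputs.
    """
    cfg = read_config(config_path) if not isinstance(config_path, dict) \
        else config_path
    model, report_cfg = _model_from_config(cfg)
    if out_dir is None:
        out_dir = cfg.get("run", {}).get("out_dir", "partval_out")
    if plots is None:
        plots = report_cfg.get("plots", "both") != "none"
    results = model.fit()
    save_results(results, out_dir, plots=plots,
                 B=int(report_cfg.get("bootstrap", 200)), seed=model.seed)
    return Path(out_dir)
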