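"""Model/Results interface to the partition validation pipeline.

:class:`PartitionValidation` is built from data (a ranked PSM table plus the
channels the chosen FDR estimator needs) and configuration; ``fit()`` runs
quality filtering over the QF grid, partitions the search space, labels the
subset hits and pairs proxy FDP with the estimator's q-values, returning a
:class:`ValidationResults` that carries the curves, KS diagnostics, bootstrap
bands and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from . import labeling, partition
from .errors import ConfigError
from .labeling import QfGrid, ValidationCurve
from .psm_io import RankedPsmTable, SearchSpace

FDR_METHODS = ("tdc", "storey_decoy", "storey_sidak",
               "storey_null_table", "storey_pcolumn")


def default_fdr_grid() -> np.ndarray:
    """Log-spaced FDR thresholds, 0.001-0.5, 50 points."""
    return np.logspace(np.log10(0.001), np.log10(0.5), 50)


class PartitionValidation:
    """Validation-by-partition analysis of one search result.

    Parameters
    ----------
    table:
        Full-search ranked PSM table (the universal input).
    decoy_table:
        Rank-1 decoy hits per spectrum; required by the decoy-based
        estimators (``tdc``, ``storey_decoy``).
    mode:
        ``postsearch`` partitions the union of top-N candidates and scans the
        existing ranked lists; ``presearch`` partitions ``search_space`` and
        re-scores via ``scorer`` (defaulting to a lookup into the table's own
        deeper candidate list).
    fdr_method:
        One of ``tdc``, ``storey_decoy``, ``storey_sidak``,
        ``storey_null_table``, ``storey_pcolumn``.
    score_kind:
        How the validation score depends on search-space size (for the
        subset-size adjustment): ``e_value``, ``tev``, ``gumbel`` or
        ``space_independent``.
    """

    def __init__(self, table: RankedPsmTable, *,
                 decoy_table: RankedPsmTable | None = None,
                 mode: str = "postsearch",
                 k: int = 2,
                 top_n: int | None = None,
                 seed: int = 0,
                 qf_grid: QfGrid | None = None,
                 fdr_method: str = "tdc",
                 fdr_grid=None,
                 score_kind: str = "space_independent",
                 gumbel_scale: float | None = None,
                 tev_params: est.TevParams = est.TevParams(),
                 storey: est.StoreyConfig = est.StoreyConfig(),
                 level: str = "psm",
                 min_retained_psms: int = 1000,
                 search_space: SearchSpace | None = None,
                 scorer=None,
                 null_table: pd.DataFrame | None = None,
                 n_candidates: int | None = None,
                 reference_null=None):
        if mode not in ("presearch", "postsearch"):
            raise ConfigError(f"unknown mode {mode!r}")
        if fdr_method not in FDR_METHODS:
            raise ConfigError(
                f"unknown fdr method {fdr_method!r}; expected one of {FDR_METHODS}")
        if level not in ("psm", "peptide"):
            raise ConfigError(f"unknown level {level!r}")
        if fdr_method in ("tdc", "storey_decoy") and decoy_table is None:
            raise ConfigError(f"{fdr_method} requires a decoy table")
        if fdr_method == "storey_null_table" and null_table is None:
            raise ConfigError("storey_null_table requires a null table")
        if mode == "presearch" and search_space is None:
            raise ConfigError("presearch mode requires a search space")
        self.table = table
        self.decoy_table = decoy_table
        self.mode = mode
        self.k = k
        self.top_n = top_n if top_n is not None else table.top_n
        self.seed = seed
        self.qf_grid = qf_grid if qf_grid is not None else \
            QfGrid.from_quantiles(table, min_retained_psms=min_retained_psms)
        self.fdr_method = fdr_method
        self.fdr_grid = np.asarray(
            fdr_grid if fdr_grid is not None else default_fdr_grid(), dtype=float)
        self.score_kind = score_kind
        self.gumbel_scale = gumbel_scale
        self.tev_params = tev_params
        self.storey = storey
        self.level = level
        self.min_retained_psms = min_retained_psms
        self.search_space = search_space
        self.scorer = scorer
        self.null_table = null_table
        self.n_candidates = n_candidates
        self.reference_null = reference_null

    # -- pipeline pieces --------------------------------------------------

    def _partition(self):
        if self.mode == "postsearch":
            space = partition.candidate_union(self.table, self.top_n)
        else:
            space = self.search_space
        return partition.partition_space(space, self.k, self.seed)

    def _subset_hits(self, qf_table: RankedPsmTable, gamma):
        if self.mode == "postsearch":
            return partition.postsearch_scan(qf_table, gamma, self.top_n)
        scorer = self.scorer
        if scorer is None:
            scorer = partition.table_scorer(qf_table, self.top_n)
        return partition.presearch_rescore(qf_table, gamma, scorer)

    def _adjusted(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(est.adjust_score_for_subset(
            scores, self.k, self.score_kind,
            tev_params=self.tev_params, gumbel_scale=self.gumbel_scale))

    def _qvalues(self, labeled: pd.DataFrame, qf_table: RankedPsmTable,
                 adjusted: np.ndarray) -> np.ndarray:
        method = self.fdr_method
        if method in ("tdc", "storey_decoy"):
            dec = self.decoy_table.rank1()
            dec = dec[dec["spectrum_id"].isin(set(qf_table.spectra()))]
            if method == "tdc":
                # concatenated-search semantics: the (adjusted) subset target
                # competes per spectrum with its decoy; losers are never
                # accepted (q = 1) and only winning decoys are counted.
                dmap = dec.set_index("spectrum_id")["oriented_score"]
                dscores = dmap.reindex(labeled["spectrum_id"]).to_numpy()
                dscores = np.where(np.isnan(dscores), -np.inf, dscores)
                target_wins = adjusted >= dscores
                q = np.ones(len(labeled))
                q[target_wins] = est.tdc_qvalues(
                    adjusted[target_wins], dscores[~target_wins])
                return q
            dscores = dec["oriented_score"].to_numpy()
            p = est.decoy_pvalues(adjusted, dscores)
            return est.storey_qvalues(p, self.storey)
        if method == "storey_null_table":
            p = np.asarray(est.empirical_null_pvalue(adjusted, self.null_table))
            return est.storey_qvalues(np.clip(p, 1e-300, 1.0), self.storey)
        # p-value-column methods need the per-record p of each labeled PSM
        rec = qf_table.df[["spectrum_id", "peptide", "p_value"]]
        merged = labeled.merge(rec.drop_duplicates(["spectrum_id", "peptide"]),
                               on=["spectrum_id", "peptide"], how="left")
        p = merged["p_value"].to_numpy(dtype=float)
        if np.isnan(p).any():
            raise ConfigError(
                f"{method} requires a p_value for every labeled PSM")
        if method == "storey_sidak":
            n = self.n_candidates
            if n is None:
                raise ConfigError("storey_sidak requires n_candidates")
            p = np.asarray(est.sidak_adjust(p, n))
        return est.storey_qvalues(np.clip(p, 1e-300, 1.0), self.storey)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "ValidationResults":
        part = self._partition()
        gamma = part.selected
        curves: list[ValidationCurve] = []
        ks_rows = []
        for tau in self.qf_grid.thresholds:
            qf_table = labeling.quality_filter(self.table, tau)
            if qf_table.n_spectra == 0:
                continue
            hits = self._subset_hits(qf_table, gamma)
            labeled = labeling.label_hits(hits)
            if self.level == "peptide":
                labeled = labeling.peptide_rollup(labeled)
            if len(labeled) == 0:
                continue
            adjusted = self._adjusted(
                labeled["validation_score"].to_numpy(dtype=float))
            q = self._qvalues(labeled, qf_table, adjusted)
            curve = labeling.build_curve(
                labeled.assign(adjusted_score=adjusted), q, self.fdr_grid,
                qf_threshold=tau,
                min_retained_psms=self.qf_grid.min_retained_psms)
            curves.append(curve)
            if self.reference_null is not None:
                inc = labeled.loc[labeled["status"] == "incorrect",
                                  "validation_score"].to_numpy()
                if len(inc) >= 2:
                    D, pv = labeling.ks_null_check(inc, self.reference_null)
                    ks_rows.append({"qf_threshold": tau, "ks_statistic": D,
                                    "ks_pvalue": pv, "n_incorrect": len(inc),
                                    "n_labeled": len(labeled)})
        if not curves:
            raise ConfigError("no QF threshold retained any labeled PSM")
        ks = pd.DataFrame(ks_rows, columns=["qf_threshold", "ks_statistic",
                                            "ks_pvalue", "n_incorrect",
                                            "n_labeled"])
        return ValidationResults(model=self, partition=part, curves=curves,
                                 ks_table=ks)


@dataclass
class ValidationResults:
    """Fitted validation: curves over the QF grid plus diagnostics."""

    model: PartitionValidation
    partition: partition.Partition
    curves: list
    ks_table: pd.DataFrame
    _bands: dict = field(default_factory=dict, repr=False)

    @property
    def qf_thresholds(self) -> list[float]:
        return [c.qf_threshold for c in self.curves]

    def curves_frame(self) -> pd.DataFrame:
        """Long-format table of every (QF threshold, FDR grid) point."""
        rows = []
        for c in self.curves:
            g = c.grid.copy()
            g.insert(0, "qf_threshold", c.qf_threshold)
            g["n_labeled"] = c.n_labeled
            g["stable"] = c.stable
            rows.append(g)
        return pd.concat(rows, ignore_index=True)

    def curve(self, qf_threshold: float):
        for c in self.curves:
            if np.isclose(c.qf_threshold, qf_threshold):
                return c
        raise KeyError(f"no curve at QF threshold {qf_threshold}")

    # -- bands and stability ----------------------------------------------

    def bootstrap_band(self, qf_threshold: float | None = None,
                       B: int = 1000, seed: int = 0):
        from .reporting import bootstrap_band
        if qf_threshold is None:
            qf_threshold = self.select_stable_threshold()
        key = (float(qf_threshold), B, seed)
        if key not in self._bands:
            c = self.curve(qf_threshold)
            self._bands[key] = bootstrap_band(
                c.labeled, c.qvalues, self.model.fdr_grid, B=B, seed=seed,
                qf_threshold=c.qf_threshold)
        return self._bands[key]

    def select_stable_threshold(self, min_psms: int | None = None,
                                B: int = 200, seed: int = 0) -> float:
        from .reporting import select_stable_threshold
        if min_psms is None:
            min_psms = self.model.qf_grid.min_retained_psms
        return select_stable_threshold(self, min_psms=min_psms, B=B, seed=seed)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted validation scan."""
        m = self.model
        lines = [
            "Partition validation results",
            "=" * 64,
            f"mode: {m.mode}   k: {m.k}   seed: {m.seed}   level: {m.level}",
            f"fdr method: {m.fdr_method}   score kind: {m.score_kind}",
            f"spectra: {m.table.n_spectra}   top_n: {m.top_n}",
            "-" * 64,
            f"{'QF thr':>10} {'n_labeled':>10} {'stable':>7} "
            f"{'pFDP@0.01':>10} {'pFDP@0.05':>10} {'pFDP@0.10':>10}",
        ]

        def pfdp_at(c, g):
            sub = c.grid[c.grid["fdr_threshold"] <= g]
            return f"{sub['pfdp'].iloc[-1]:10.4f}" if len(sub) else " " * 9 + "-"

        for c in self.curves:
            lines.append(
                f"{c.qf_threshold:>10.4g} {c.n_labeled:>10d} "
                f"{str(c.stable):>7} {pfdp_at(c, 0.01)} {pfdp_at(c, 0.05)} "
                f"{pfdp_at(c, 0.1)}")
        lines.append("-" * 64)
        return "\n".join(lines)

    def plot_contour(self, ax=None, **kwargs):
        from .reporting import plot_contour
        return plot_contour(self, ax=ax, **kwargs)

    def save(self, out_dir, plots: bool = True, B: int = 200, seed: int = 0):
        from .reporting import save_results
        return save_results(self, out_dir, plots=plots, B=B, seed=seed)
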