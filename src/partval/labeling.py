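"""Quality filtering, quasi-ground-truth labels and proxy FDP.

The subset search produces, per spectrum, the best-scoring candidate from the
selected partition subset.  If that candidate equals the top hit of the full
search, the PSM is labeled *correct*, otherwise *incorrect*.  The proxy false
discovery proportion (pFDP) is the fraction of incorrect labels among PSMs
above a validation-score threshold; it converges to the true FDP once the
quality-filtering (QF) step has removed the unidentifiable spectra whose
labels are unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .psm_io import RankedPsmTable

LABEL_COLUMNS = ("spectrum_id", "peptide", "validation_score", "status")


@dataclass(frozen=True)
class QfGrid:
    """Grid of QF thresholds applied to the full-search top score."""

    thresholds: tuple
    qf_score_name: str = "score"
    min_retained_psms: int = 1000

    def __post_init__(self):
        if len(self.thresholds) == 0:
            raise ConfigError("QF grid must contain at least one threshold")
        t = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ConfigError("QF thresholds must be strictly increasing")
        if self.min_retained_psms < 1:
            raise ConfigError("min_retained_psms must be >= 1")

    @classmethod
    def from_quantiles(cls, table: RankedPsmTable, quantiles=None, **kwargs):
        """Default grid: quantiles 0.5-0.99 of the rank-1 QF scores, 10 points."""
        if quantiles is None:
            quantiles = np.linspace(0.5, 0.99, 10)
        scores = table.rank1(include_decoys=False)["oriented_score"].to_numpy()
        thr = np.unique(np.quantile(scores, np.asarray(quantiles, dtype=float)))
        return cls(tuple(thr.tolist()), **kwargs)


@dataclass
class ValidationCurve:
    """pFDP paired with FDR estimates over an FDR-threshold grid.

    ``grid`` has columns ``fdr_threshold, fdr_estimate, pfdp, n_accepted``.
    ``labeled``/``qvalues`` retain the underlying labeled PSMs so bootstrap
    bands can be recomputed without re-running the pipeline.
    """

    qf_threshold: float
    grid: pd.DataFrame
    n_labeled: int
    stable: bool = True
    labeled: pd.DataFrame | None = field(default=None, repr=False)
    qvalues: np.ndarray | None = field(default=None, repr=False)


def quality_filter(table: RankedPsmTable, threshold: float,
                   qf_scores=None) -> RankedPsmTable:
    """Keep whole spectrum groups whose rank-1 QF score is >= threshold.

    ``qf_scores`` optionally maps spectrum_id to an alternative oriented QF
    score (e.g. a TEV computed from e-values); by default the rank-1 oriented
    search score is used.
    """
    top = table.rank1(include_decoys=False)
    if qf_scores is None:
        qf = top.set_index("spectrum_id")["oriented_score"]
    else:
        qf = pd.Series(qf_scores)
        qf = qf.reindex(top["spectrum_id"])
    keep = qf.index[qf.to_numpy() >= threshold]
    if len(keep) == 0:
        warnings.warn(f"QF threshold {threshold} retains zero spectra")
    return table.filter_spectra(keep)


def label_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Assign correct/incorrect status to non-excluded subset hits.

    correct  <=> the subset top peptide equals the full-search rank-1 peptide.
    The validation score carried forward is the subset-search score.
    """
    kept = hits[~hits["excluded"]]
    status = np.where(kept["subset_peptide"] == kept["full_top_peptide"],
                      "correct", "incorrect")
    out = pd.DataFrame({
        "spectrum_id": kept["spectrum_id"].to_numpy(),
        "peptide": kept["subset_peptide"].to_numpy(),
        "validation_score": kept["subset_score"].to_numpy(dtype=float),
        "status": status,
    })
    return out.reset_index(drop=True)


def pfdp(labeled: pd.DataFrame, t: float) -> float:
    """Proportion of incorrect labels among PSMs with validation score >= t."""
    acc = labeled["validation_score"].to_numpy() >= t
    n = int(acc.sum())
    if n == 0:
        warnings.warn(f"no labeled PSM at or above validation threshold {t}")
        return float("nan")
    inc = (labeled["status"].to_numpy() == "incorrect") & acc
    return float(inc.sum()) / n


def build_curve(labeled: pd.DataFrame, qvalues, fdr_grid,
                qf_threshold: float = float("nan"),
                min_retained_psms: int = 1000) -> ValidationCurve:
    """Pair pFDP with FDR estimates over a grid of FDR thresholds.

    At each grid point, PSMs with q-value <= threshold are accepted; the
    recorded FDR estimate is the largest accepted q-value.  Grid points with
    empty acceptance are skipped.
    """
    q = np.asarray(qvalues, dtype=float)
    if len(q) != len(labeled):
        raise ValueError("qvalues must align with the labeled PSMs")
    inc = labeled["status"].to_numpy() == "incorrect"
    rows = []
    for g in np.asarray(fdr_grid, dtype=float):
        acc = q <= g
        n = int(acc.sum())
        if n == 0:
            continue
        rows.append({
            "fdr_threshold": float(g),
            "fdr_estimate": float(q[acc].max()),
            "pfdp": float(inc[acc].sum()) / n,
            "n_accepted": n,
        })
    grid = pd.DataFrame(rows, columns=["fdr_threshold", "fdr_estimate",
                                       "pfdp", "n_accepted"])
    return ValidationCurve(
        qf_threshold=float(qf_threshold), grid=grid, n_labeled=len(labeled),
        stable=len(labeled) >= min_retained_psms, labeled=labeled, qvalues=q)


def peptide_rollup(obj):
    """Collapse to one record per unique peptide, keeping the best score.

    Accepts either a labeled-PSM frame (``validation_score``) or a
    :class:`RankedPsmTable` (rank-1 hits, oriented score).  Ties go to the
    lexicographically smaller spectrum_id.
    """
    if isinstance(obj, RankedPsmTable):
        top = obj.rank1()
        top = top.sort_values(["oriented_score", "spectrum_id"],
                              ascending=[False, True], kind="stable")
        best = top.drop_duplicates(subset="peptide", keep="first")
        return RankedPsmTable(
            best.assign(rank=1), score_name=obj.score_name,
            score_orientation=obj.score_orientation, validate=False)
    df = obj.sort_values(["validation_score", "spectrum_id"],
                         ascending=[False, True], kind="stable")
    return df.drop_duplicates(subset="peptide", keep="first").reset_index(drop=True)


def ks_null_check(labeled_incorrect_scores, reference_null_scores):
    """Two-sample two-sided KS test of labeled-incorrect vs reference null.

    Diagnoses whether the empirical null proposed by the partition labels is
    distinguishable from a reference null distribution; along a QF grid the
    statistic should fall as mislabeled spectra are sieved out and rise again
    once too few spectra remain.
    """
    x = np.asarray(labeled_incorrect_scores, dtype=float)
    y = np.asarray(reference_null_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if min(len(x), len(y)) < 5:
        warnings.warn("KS check on fewer than 5 observations is unreliable")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
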