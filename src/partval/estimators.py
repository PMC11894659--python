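"""FDR estimation methods under validation.

Decoy-based: target-decoy competition (TDC) with the +1-corrected estimator,
and empirical decoy p-values fed into Storey's q-value framework.
Decoy-free: Sidak-corrected spectrum-level exact p-values, tabulated
empirical-null (common decoy distribution) p-values, or a precomputed
p-value column, all through the same Storey machinery.

All score comparisons use the >= convention on oriented (higher-better)
scores.  The transformed e-value TEV(e) = a * ln(e / N0) with a = -0.02 and
N0 = 1000 makes e-value-based scores comparable across spectra, and the
subset-size score adjustment maps subset-search scores onto their full-space
equivalents so that full-space nulls (decoys, CDD tables) remain applicable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .psm_io import RankedPsmTable


@dataclass(frozen=True)
class TevParams:
    """Constants of the transformed e-value: TEV(e) = a * ln(e / N0)."""

    a: float = -0.02
    N0: int = 1000

    def __post_init__(self):
        if self.a == 0:
            raise ConfigError("TEV slope a must be non-zero")
        if self.N0 < 1:
            raise ConfigError("TEV N0 must be >= 1")


@dataclass(frozen=True)
class StoreyConfig:
    """pi0 estimation settings for Storey's q-values."""

    pi0_lambda: float = 0.5
    pi0_method: str = "fixed_lambda"  # or "smoother"
    pi0_override: float | None = None

    def __post_init__(self):
        if not 0 < self.pi0_lambda < 1:
            raise ConfigError("pi0_lambda must be in (0, 1)")
        if self.pi0_method not in ("fixed_lambda", "smoother"):
            raise ConfigError(f"unknown pi0_method {self.pi0_method!r}")
        if self.pi0_override is not None and not 0 < self.pi0_override <= 1:
            raise ConfigError("pi0_override must be in (0, 1]")


def _n_ge(sorted_asc: np.ndarray, x) -> np.ndarray:
    """Count of elements >= x in an ascending-sorted array (vectorised)."""
    return len(sorted_asc) - np.searchsorted(sorted_asc, x, side="left")


# ---------------------------------------------------------------------------
# target-decoy competition
# ---------------------------------------------------------------------------

def tdc_fdr(target_scores, decoy_scores, x: float) -> float:
    """TDC FDR estimate at score threshold x: (N_D(x) + 1) / N_T(x).

    The +1 in the numerator gives the corrected (unbiased) estimator; the
    result is clipped to [0, 1].  Counts use scores >= x.  Returns NaN when
    no target reaches x.
    """
    t = np.sort(np.asarray(target_scores, dtype=float))
    d = np.sort(np.asarray(decoy_scores, dtype=float))
    nt = int(_n_ge(t, x))
    if nt == 0:
        return float("nan")
    nd = int(_n_ge(d, x))
    return min(1.0, (nd + 1) / nt)


def tdc_qvalues(target_scores, decoy_scores) -> np.ndarray:
    """Monotonised TDC q-values, aligned with ``target_scores``.

    q(x) = min over thresholds x' <= x of the TDC FDR estimate, so acceptance
    sets nest and q is non-increasing in the score.
    """
    x = np.asarray(target_scores, dtype=float)
    t = np.sort(x)
    d = np.sort(np.asarray(decoy_scores, dtype=float))
    order = np.argsort(-x, kind="stable")
    xs = x[order]  # descending
    nt = _n_ge(t, xs)
    nd = _n_ge(d, xs)
    fdr = np.minimum(1.0, (nd + 1) / nt)
    # running minimum from the worst score upward
    q_desc = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_desc)
    q[order] = q_desc
    return q


def compete(target_table: RankedPsmTable, decoy_table: RankedPsmTable) -> pd.DataFrame:
    """Per-spectrum competition between target and decoy top hits.

    Emulates the concatenated target-decoy search from separate channels: the
    higher oriented score wins.  Returns one row per spectrum with columns
    ``spectrum_id, peptide, score, is_decoy`` (score oriented).
    """
    t = target_table.rank1(include_decoys=False)[
        ["spectrum_id", "peptide", "oriented_score"]]
    d = decoy_table.rank1()[["spectrum_id", "peptide", "oriented_score"]]
    m = t.merge(d, on="spectrum_id", how="inner", suffixes=("_t", "_d"))
    decoy_wins = m["oriented_score_d"].to_numpy() > m["oriented_score_t"].to_numpy()
    out = pd.DataFrame({
        "spectrum_id": m["spectrum_id"],
        "peptide": np.where(decoy_wins, m["peptide_d"], m["peptide_t"]),
        "score": np.where(decoy_wins, m["oriented_score_d"], m["oriented_score_t"]),
        "is_decoy": decoy_wins,
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# decoy-based p-values and Storey's framework
# ---------------------------------------------------------------------------

def decoy_pvalues(scores, decoy_scores) -> np.ndarray:
    """Empirical decoy-based p-values: p(x) = (n_D(x) + 1) / (N_D + 1).

    n_D(x) counts decoy matches with score >= x.  The +1s guarantee p in
    (0, 1] (the Granholm-Kall recommendation for search-engine scores).
    """
    d = np.asarray(decoy_scores, dtype=float)
    if d.size == 0:
        raise ValueError("decoy score set must be non-empty")
    ds = np.sort(d)
    nd = _n_ge(ds, np.asarray(scores, dtype=float))
    return (nd + 1) / (d.size + 1)


def decoy_pvalue(x: float, decoy_scores) -> float:
    return float(decoy_pvalues([x], decoy_scores)[0])


def estimate_pi0(pvalues, cfg: StoreyConfig = StoreyConfig()) -> float:
    """Estimate pi0, the fraction of incorrect PSMs among all analysed PSMs.

    Default: the fixed-lambda estimator #{p > lambda} / ((1 - lambda) m),
    capped into (0, 1].  The ``smoother`` option evaluates the estimator on a
    lambda grid and extrapolates a cubic smoothing spline at the right end.
    """
    if cfg.pi0_override is not None:
        return float(cfg.pi0_override)
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")

    def at(lam):
        return np.count_nonzero(p > lam) / ((1.0 - lam) * m)

    if cfg.pi0_method == "fixed_lambda":
        pi0 = at(cfg.pi0_lambda)
    else:
        lams = np.arange(0.05, 0.96, 0.05)
        vals = np.array([at(l) for l in lams])
        from scipy.interpolate import UnivariateSpline
        spl = UnivariateSpline(lams, vals, k=3)
        pi0 = float(spl(lams[-1]))
    pi0 = min(1.0, pi0)
    if pi0 <= 0:
        pi0 = 1.0 / m  # degenerate: all p small; keep pi0 in (0, 1]
    return float(pi0)


def storey_qvalues(pvalues, cfg: StoreyConfig = StoreyConfig(),
                   pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min over t >= p_i of pi0 * m * t / #{p_j <= t}.

    With pi0 = 1 this reduces exactly to Benjamini-Hochberg adjusted
    p-values.  Output is aligned with the input and non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, cfg)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    # #{p_j <= t} at t = each sorted p, tie-aware
    cnt = np.searchsorted(ps, ps, side="right")
    fdr = pi0 * m * ps / cnt
    q_sorted = np.minimum(1.0, np.minimum.accumulate(fdr[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# decoy-free ingredients
# ---------------------------------------------------------------------------

def sidak_adjust(p, n_candidates: int):
    """Sidak correction p' = 1 - (1 - p)^n for a best-of-n candidates test."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(n_candidates * np.log1p(-p))
    out = np.where(p >= 1.0, 1.0, out)
    return out if out.ndim else float(out)


def tev(e_value, params: TevParams = TevParams()):
    """Transformed e-value: TEV(e) = a * ln(e / N0), a = -0.02, N0 = 1000.

    Strictly decreasing in the e-value and log-linear:
    TEV(e) - TEV(c*e) = -a * ln(c) for any c.
    """
    e = np.asarray(e_value, dtype=float)
    if np.any(e <= 0):
        raise ValueError("e-values must be > 0")
    out = params.a * np.log(e / params.N0)
    return out if out.ndim else float(out)


def tev_to_evalue(t, params: TevParams = TevParams()):
    return np.exp(np.asarray(t, dtype=float) / params.a) * params.N0


SCORE_KINDS = ("e_value", "tev", "gumbel", "space_independent")


def adjust_score_for_subset(value, k: int, score_kind: str, *,
                            tev_params: TevParams = TevParams(),
                            gumbel_scale: float | None = None):
    """Map a subset-search score to its full-search-space equivalent.

    A subset search sees |Omega|/k candidates, which changes the null
    distribution of search-space-dependent scores; the adjustment restores
    comparability with full-space references (decoy score sets, tabulated
    nulls).  Kinds:

    * ``e_value``: multiply by k — an e-value computed against the subset
      counts k-fold fewer candidates, so the full-space per-match expectation
      is k times larger.
    * ``tev``: add |a| * ln k — the top hit over k-fold fewer candidates sits
      lower by the Gumbel location shift |a| * ln k, so adding it matches the
      subset top-hit TEV null to the full-space one.
    * ``gumbel``: add ``gumbel_scale`` * ln k (raw similarity scores whose
      per-candidate null is Gumbel with that scale).
    * ``space_independent``: returned unchanged (e.g. dot products).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if score_kind not in SCORE_KINDS:
        raise ConfigError(
            f"unknown score_kind {score_kind!r}; expected one of {SCORE_KINDS}")
    v = np.asarray(value, dtype=float)
    if score_kind == "e_value":
        out = v * k
    elif score_kind == "tev":
        out = v + abs(tev_params.a) * np.log(k)
    elif score_kind == "gumbel":
        if gumbel_scale is None or gumbel_scale <= 0:
            raise ConfigError("gumbel score_kind requires a positive gumbel_scale")
        out = v + gumbel_scale * np.log(k)
    else:
        out = v
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# tabulated empirical null (common decoy distribution)
# ---------------------------------------------------------------------------

def load_null_table(path) -> pd.DataFrame:
    """Read a tabulated empirical null: TSV with columns score, tail_prob."""
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("score", "tail_prob"):
        if col not in df.columns:
            raise FormatError(f"null table missing column {col!r}")
    validate_null_table(df)
    return df[["score", "tail_prob"]]


def validate_null_table(table: pd.DataFrame) -> None:
    s = table["score"].to_numpy(dtype=float)
    t = table["tail_prob"].to_numpy(dtype=float)
    if len(s) < 2:
        raise FormatError("null table needs at least two knots")
    if not np.all(np.diff(s) > 0):
        raise FormatError("null table scores must be strictly increasing")
    if np.any(np.diff(t) > 0):
        raise FormatError("null table tail probabilities must be non-increasing")
    if np.any((t <= 0) | (t > 1)):
        raise FormatError("tail probabilities must lie in (0, 1]")


def empirical_null_pvalue(score, null_table: pd.DataFrame):
    """Right-tail p-value from a tabulated survival function, interpolated.

    Scores below the table range clamp to 1, above it to the smallest
    tabulated tail (with a warning); linear interpolation between knots.
    """
    validate_null_table(null_table)
    s = null_table["score"].to_numpy(dtype=float)
    t = null_table["tail_prob"].to_numpy(dtype=float)
    x = np.asarray(score, dtype=float)
    if np.any(x < s[0]) or np.any(x > s[-1]):
        warnings.warn("score(s) outside the tabulated null range; clamped")
    out = np.interp(x, s, t, left=1.0, right=t[-1])
    return out if out.ndim else float(out)
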