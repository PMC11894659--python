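"""Random partition of the search space and the subset search.

The validation protocol splits the set of unique peptide candidates (Omega)
into k equal-sized disjoint subsets and re-matches the quality-filtered
spectra against one selected subset (gamma).  Two modes exist:

* presearch: Omega itself (e.g. a digested FASTA) is partitioned and the
  subset search is an actual re-scoring of spectra against gamma;
* postsearch: the union of each spectrum's top-N candidates from the full
  search is partitioned, and the "subset search" is a scan through the
  already-ranked candidate lists.

A spectrum none of whose top-N candidates falls in gamma is excluded from
further analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .psm_io import RankedPsmTable, SearchSpace

SUBSET_HIT_COLUMNS = (
    "spectrum_id", "subset_peptide", "subset_score",
    "full_top_peptide", "full_top_score", "excluded",
)


@dataclass(frozen=True)
class SubsetHit:
    """Per-spectrum outcome of the subset search."""

    spectrum_id: str
    full_top_peptide: str
    full_top_score: float
    subset_peptide: str | None = None
    subset_score: float | None = None
    excluded: bool = False


@dataclass(frozen=True)
class Partition:
    """k disjoint, equal-sized (+-1) subsets covering the input space."""

    subsets: tuple
    k: int
    seed: int
    selected_index: int = 0

    @property
    def selected(self) -> frozenset:
        return self.subsets[self.selected_index]

    def __iter__(self):
        return iter(self.subsets)


def partition_space(space, k: int = 2, seed: int = 0,
                    selected_index: int = 0) -> Partition:
    """Uniformly random equal-sized partition of the candidate space.

    Sizes differ by at most one; the remainder goes to the lowest-indexed
    subsets after the seeded shuffle.  Deterministic for a fixed seed
    regardless of the input container's iteration order.
    """
    peptides = sorted(space.peptides if isinstance(space, SearchSpace) else space)
    n = len(peptides)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of candidates ({n})")
    if not 0 <= selected_index < k:
        raise ConfigError("selected_index out of range")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    subsets = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        subsets.append(frozenset(peptides[j] for j in order[start:start + size]))
        start += size
    return Partition(tuple(subsets), k=k, seed=seed, selected_index=selected_index)


def candidate_union(table: RankedPsmTable, n: int | None = None,
                    include_decoys: bool = False) -> SearchSpace:
    """Unique peptides appearing at rank <= n for any spectrum.

    Decoy records are excluded by default: the partition defines target
    ground truth, decoys belong to the estimator stage.
    """
    if n is None:
        n = table.top_n
    if n < 1:
        raise ConfigError("n must be >= 1")
    if n > table.top_n:
        raise ConfigError(f"n={n} exceeds the table depth top_n={table.top_n}")
    df = table.df
    mask = df["rank"] <= n
    if not include_decoys:
        mask &= ~df["is_decoy"]
    return SearchSpace(frozenset(df.loc[mask, "peptide"]), source="candidate_union")


def postsearch_scan(table: RankedPsmTable, gamma, n: int | None = None) -> pd.DataFrame:
    """Best in-gamma candidate per spectrum from the ranked top-n lists.

    Returns one row per spectrum with columns
    ``spectrum_id, subset_peptide, subset_score, full_top_peptide,
    full_top_score, excluded``; spectra with no candidate in gamma are marked
    excluded.  Ties cannot occur: ranks are unique and the best in-gamma
    candidate is the lowest-ranked one.
    """
    if n is None:
        n = table.top_n
    gamma = gamma.peptides if isinstance(gamma, SearchSpace) else frozenset(gamma)
    df = table.df
    tgt = df[~df["is_decoy"] & (df["rank"] <= n)]
    # full-search top hit: lowest-rank target record per spectrum
    full_idx = tgt.groupby("spectrum_id", sort=False)["rank"].idxmin()
    full = tgt.loc[full_idx, ["spectrum_id", "peptide", "oriented_score"]].rename(
        columns={"peptide": "full_top_peptide", "oriented_score": "full_top_score"})
    ing = tgt[tgt["peptide"].isin(gamma)]
    if len(ing):
        sub_idx = ing.groupby("spectrum_id", sort=False)["rank"].idxmin()
        sub = ing.loc[sub_idx, ["spectrum_id", "peptide", "oriented_score"]].rename(
            columns={"peptide": "subset_peptide", "oriented_score": "subset_score"})
    else:
        sub = pd.DataFrame(columns=["spectrum_id", "subset_peptide", "subset_score"])
    out = full.merge(sub, on="spectrum_id", how="left")
    out["excluded"] = out["subset_peptide"].isna()
    out = out[list(SUBSET_HIT_COLUMNS)].sort_values("spectrum_id", kind="stable")
    return out.reset_index(drop=True)


def presearch_rescore(qf_table: RankedPsmTable, subset, scorer) -> pd.DataFrame:
    """Re-match filtered spectra against a peptide subset with a scorer.

    ``scorer(spectrum_id, peptide)`` returns an oriented score, or ``None``
    when the pair cannot be scored (candidate simply not considered).  A
    scorer exception skips the whole spectrum with a warning.  Tie-breaking
    matches :func:`postsearch_scan`: equal scores go to the lexicographically
    smaller peptide.

    In this package the scorer is supplied by the simulator or by a lookup
    into a deeper ranked candidate list; invoking real search engines is
    out-of-band (partitioned FASTA in, canonical TSV back).
    """
    subset = sorted(subset.peptides if isinstance(subset, SearchSpace) else subset)
    rows = []
    full = qf_table.rank1(include_decoys=False)
    for row in full.itertuples(index=False):
        sid = row.spectrum_id
        best_pep, best_score = None, None
        try:
            for pep in subset:
                s = scorer(sid, pep)
                if s is None:
                    continue
                if best_score is None or s > best_score or (
                        s == best_score and pep < best_pep):
                    best_pep, best_score = pep, float(s)
        except Exception as exc:  # noqa: BLE001 - contract: skip with warning
            warnings.warn(f"scorer failed for spectrum {sid!r} ({exc}); skipped")
            continue
        rows.append({
            "spectrum_id": sid,
            "subset_peptide": best_pep,
            "subset_score": best_score,
            "full_top_peptide": row.peptide,
            "full_top_score": row.oriented_score,
            "excluded": best_pep is None,
        })
    out = pd.DataFrame(rows, columns=list(SUBSET_HIT_COLUMNS))
    return out.sort_values("spectrum_id", kind="stable").reset_index(drop=True)


def table_scorer(table: RankedPsmTable, n: int | None = None):
    """Scorer that looks up (spectrum, peptide) in an existing ranked table.

    Restricting a deeper candidate list this way makes presearch re-scoring
    equivalent to :func:`postsearch_scan` on the same gamma.
    """
    if n is None:
        n = table.top_n
    df = table.df
    sel = df[~df["is_decoy"] & (df["rank"] <= n)]
    lut = {(s, p): sc for s, p, sc in zip(
        sel["spectrum_id"], sel["peptide"], sel["oriented_score"])}

    def scorer(spectrum_id, peptide):
        return lut.get((spectrum_id, peptide))

    return scorer
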