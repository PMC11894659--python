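"""Comparison validation protocols re-expressed as labeling rules.

Three protocols from the literature produce FDP curves comparable to the
partition-based proxy FDP:

* entrapment databases — matches mapped to the entrapment (foreign-organism)
  component of a bipartite database are deemed incorrect, matches to sample
  sequences correct;
* intersection of multiple engines — a PSM is correct when every engine
  assigns the spectrum the same top candidate; disagreeing spectra are
  re-searched after a fixed precursor mass shift (19.5 Th) and every match of
  that re-search is incorrect by construction;
* synthetic origin — for synthetic-peptide data sets, a top match is correct
  iff its peptide is on the synthesis list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .labeling import build_curve
from .psm_io import RankedPsmTable, peptide_key

#: fixed precursor mass shift (Thomson) applied before the control re-search
PRECURSOR_SHIFT_TH = 19.5


@dataclass(frozen=True)
class EntrapmentSpec:
    """Bipartite database description: entrapment side, optional sample side.

    Membership may be declared by protein accessions or by peptide
    sequences.  When the sample side is omitted, everything not mapping to
    the entrapment side is treated as sample.
    """

    entrapment_protein_ids: frozenset = frozenset()
    entrapment_peptides: frozenset = frozenset()
    sample_protein_ids: frozenset = frozenset()
    sample_peptides: frozenset = frozenset()

    def __post_init__(self):
        if not (self.entrapment_protein_ids or self.entrapment_peptides):
            raise ConfigError("entrapment specification is empty")
        if self.entrapment_protein_ids & self.sample_protein_ids:
            raise ConfigError("entrapment and sample protein sets overlap")
        if self.entrapment_peptides & self.sample_peptides:
            raise ConfigError("entrapment and sample peptide sets overlap")


def _split_protein_ids(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    return tuple(p for p in str(value).split(";") if p)


def entrapment_label(table: RankedPsmTable, spec: EntrapmentSpec) -> pd.DataFrame:
    """Label rank-1 PSMs by which side of the bipartite database they map to.

    A record mapping to both sides is ambiguous and a record mapping to
    neither (when an explicit sample side exists) is unmappable; both raise,
    naming the offending spectrum.
    """
    top = table.rank1(include_decoys=False)
    rows = []
    has_sample = bool(spec.sample_protein_ids or spec.sample_peptides)
    for row in top.itertuples(index=False):
        prots = set(_split_protein_ids(row.protein_ids))
        in_ent = bool(prots & spec.entrapment_protein_ids) or \
            row.peptide in spec.entrapment_peptides
        if has_sample:
            in_sam = bool(prots & spec.sample_protein_ids) or \
                row.peptide in spec.sample_peptides
        else:
            in_sam = not in_ent
        if in_ent and in_sam:
            raise IntegrityError(
                f"spectrum {row.spectrum_id!r}: maps to both sample and "
                f"entrapment components")
        if not in_ent and not in_sam:
            raise IntegrityError(
                f"spectrum {row.spectrum_id!r}: top match maps to neither "
                f"component (proteins: {';'.join(sorted(prots)) or 'none'})")
        rows.append({
            "spectrum_id": row.spectrum_id,
            "peptide": row.peptide,
            "validation_score": row.oriented_score,
            "status": "incorrect" if in_ent else "correct",
        })
    return pd.DataFrame(rows, columns=["spectrum_id", "peptide",
                                       "validation_score", "status"])


@dataclass
class IntersectionResult:
    """Outcome of the multi-engine consensus protocol."""

    correct_ids: frozenset
    to_shift_ids: frozenset
    labels: pd.DataFrame | None = None


def intersection_label(tables: dict[str, RankedPsmTable],
                       shifted_results: RankedPsmTable | None = None,
                       reference: str | None = None,
                       keep_modifications: bool = False) -> IntersectionResult:
    """Consensus labeling across >= 2 engines plus the mass-shift control.

    Spectra whose rank-1 peptide agrees across all engines are correct; all
    others (including spectra reported by only some engines, with a warning)
    go to the to-shift set.  When shifted re-search results are supplied,
    every rank-1 PSM therein is labeled incorrect and the returned labels
    combine both, scored with the ``reference`` engine's top scores.
    """
    if len(tables) < 2:
        raise ConfigError("intersection protocol needs at least two engines")
    if reference is None:
        reference = next(iter(tables))
    tops = {}
    for name, tab in tables.items():
        t = tab.rank1(include_decoys=False)
        tops[name] = dict(zip(
            t["spectrum_id"],
            (peptide_key(p, keep_modifications) for p in t["peptide"])))
    all_ids = sorted(set().union(*[set(t) for t in tops.values()]))
    correct, to_shift = set(), set()
    n_partial = 0
    for sid in all_ids:
        peps = [t.get(sid) for t in tops.values()]
        present = [p for p in peps if p is not None]
        if len(present) < len(tables):
            n_partial += 1
            to_shift.add(sid)
        elif len(set(present)) == 1:
            correct.add(sid)
        else:
            to_shift.add(sid)
    if n_partial:
        warnings.warn(
            f"{n_partial} spectra reported by only some engines; "
            f"assigned to the mass-shift set")

    labels = None
    if shifted_results is not None:
        ref_top = tables[reference].rank1(include_decoys=False)
        ref_top = ref_top[ref_top["spectrum_id"].isin(correct)]
        ok = pd.DataFrame({
            "spectrum_id": ref_top["spectrum_id"].to_numpy(),
            "peptide": ref_top["peptide"].to_numpy(),
            "validation_score": ref_top["oriented_score"].to_numpy(),
            "status": "correct",
        })
        sh_top = shifted_results.rank1(include_decoys=False)
        sh_top = sh_top[sh_top["spectrum_id"].isin(to_shift)]
        bad = pd.DataFrame({
            "spectrum_id": sh_top["spectrum_id"].to_numpy(),
            "peptide": sh_top["peptide"].to_numpy(),
            "validation_score": sh_top["oriented_score"].to_numpy(),
            "status": "incorrect",
        })
        labels = pd.concat([ok, bad], ignore_index=True).sort_values(
            "spectrum_id", kind="stable").reset_index(drop=True)
    return IntersectionResult(frozenset(correct), frozenset(to_shift), labels)


def write_shift_manifest(to_shift_ids, path) -> None:
    """Manifest of spectra to re-search after the precursor mass shift."""
    df = pd.DataFrame({"spectrum_id": sorted(to_shift_ids)})
    df["shift_Th"] = PRECURSOR_SHIFT_TH
    df.to_csv(Path(path), sep="\t", index=False)


def synthetic_origin_label(table: RankedPsmTable,
                           synthetic_peptides,
                           keep_modifications: bool = False) -> pd.DataFrame:
    """Correct iff the rank-1 peptide is on the synthetic-peptide list."""
    synthetic_peptides = {peptide_key(p, keep_modifications)
                          for p in synthetic_peptides}
    if not synthetic_peptides:
        raise ConfigError("synthetic peptide list is empty")
    top = table.rank1(include_decoys=False)
    keys = np.array([peptide_key(p, keep_modifications)
                     for p in top["peptide"]], dtype=object)
    status = np.where(np.isin(keys, list(synthetic_peptides)),
                      "correct", "incorrect")
    return pd.DataFrame({
        "spectrum_id": top["spectrum_id"].to_numpy(),
        "peptide": top["peptide"].to_numpy(),
        "validation_score": top["oriented_score"].to_numpy(),
        "status": status,
    }).reset_index(drop=True)


def fdp_curve(labels: pd.DataFrame, fdr_estimates, fdr_grid,
              min_retained_psms: int = 1000):
    """FDP-vs-FDR curve from fully labeled PSMs (same contract as build_curve)."""
    return build_curve(labels, fdr_estimates, fdr_grid,
                       min_retained_psms=min_retained_psms)
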