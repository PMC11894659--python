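"""I/O for ranked PSM tables, FASTA search spaces and auxiliary inputs.

The canonical PSM format is a UTF-8 TSV with header columns

    spectrum_id  rank  peptide  charge  score  e_value  p_value  is_decoy  protein_ids

one row per candidate, ranks contiguous from 1 within each spectrum and the
score monotone along rank.  Missing optional values are encoded as ``NA``;
``protein_ids`` is semicolon-joined (``NA`` for an empty list).  The format is
engine-neutral: search engines emit incompatible native outputs, so every
pipeline entry point converts to this table first.

Scores are normalised internally to *higher is better*: when a table is
declared ``lower_better`` (e-value-like scores), the oriented score is the
negation of the stored value.  All downstream comparisons use oriented scores;
the on-disk representation is untouched, so read/write round-trips are
byte-identical for canonical files.
"""

from __future__ import annotations

import math
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import parser as _parser

from .errors import ConfigError, FormatError, IntegrityError

CANONICAL_COLUMNS = (
    "spectrum_id",
    "rank",
    "peptide",
    "charge",
    "score",
    "e_value",
    "p_value",
    "is_decoy",
    "protein_ids",
)

#: standard amino acids plus ambiguity codes tolerated in FASTA input
VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | set("BJOUXZ")

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


@dataclass(frozen=True)
class PsmRecord:
    """One candidate match of a spectrum (a single row of the table)."""

    spectrum_id: str
    rank: int
    peptide: str
    score: float
    is_decoy: bool = False
    charge: int | None = None
    e_value: float | None = None
    p_value: float | None = None
    protein_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SearchSpace:
    """The set of unique peptide candidates (Omega)."""

    peptides: frozenset
    source: str = "explicit_list"

    def __post_init__(self):
        if not self.peptides:
            raise ValueError("search space must be non-empty")

    def __len__(self):
        return len(self.peptides)

    def __contains__(self, peptide):
        return peptide in self.peptides


class RankedPsmTable:
    """Per-spectrum ranked candidate lists with scores.

    Wraps a :class:`pandas.DataFrame` in the canonical column layout plus an
    ``oriented_score`` column (higher = better regardless of the declared
    orientation).  Construction validates the structural invariants: unique,
    contiguous ranks from 1 per spectrum and oriented scores non-increasing
    along rank.
    """

    def __init__(self, df: pd.DataFrame, *, score_name: str = "score",
                 score_orientation: str = HIGHER_BETTER, top_n: int | None = None,
                 validate: bool = True):
        if score_orientation not in (HIGHER_BETTER, LOWER_BETTER):
            raise ConfigError(f"unknown score orientation {score_orientation!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["rank"] = df["rank"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        df["is_decoy"] = df["is_decoy"].astype(bool)
        sign = -1.0 if score_orientation == LOWER_BETTER else 1.0
        df["oriented_score"] = sign * df["score"].to_numpy()
        df = df.sort_values(["spectrum_id", "rank"], kind="stable").reset_index(drop=True)
        self.df = df
        self.score_name = score_name
        self.score_orientation = score_orientation
        self._top_n = top_n
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PsmRecord], **kwargs) -> "RankedPsmTable":
        rows = [
            {
                "spectrum_id": r.spectrum_id,
                "rank": r.rank,
                "peptide": r.peptide,
                "charge": r.charge,
                "score": r.score,
                "e_value": r.e_value,
                "p_value": r.p_value,
                "is_decoy": r.is_decoy,
                "protein_ids": ";".join(r.protein_ids) if r.protein_ids else None,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(df, **kwargs)

    def _validate(self):
        df = self.df
        dup = df.duplicated(subset=["spectrum_id", "rank"])
        if dup.any():
            bad = df.loc[dup, "spectrum_id"].iloc[0]
            raise IntegrityError(f"duplicate (spectrum_id, rank) in spectrum {bad!r}")
        grp = df.groupby("spectrum_id", sort=False)["rank"]
        sizes = grp.size()
        if (grp.min() != 1).any() or (grp.max() != sizes).any():
            bad = sizes.index[(grp.min() != 1) | (grp.max() != sizes)][0]
            raise IntegrityError(f"ranks not contiguous from 1 in spectrum {bad!r}")
        if self._top_n is not None and sizes.max() > self._top_n:
            raise IntegrityError(
                f"spectrum group larger than declared top_n={self._top_n}")
        # oriented score must be non-increasing along rank within a spectrum
        ds = df.groupby("spectrum_id", sort=False)["oriented_score"].diff()
        if (ds.dropna() > 1e-9).any():
            bad = df.loc[ds.index[ds > 1e-9][0], "spectrum_id"]
            raise IntegrityError(
                f"oriented score increases with rank in spectrum {bad!r}")

    # -- accessors --------------------------------------------------------

    @property
    def top_n(self) -> int:
        if self._top_n is not None:
            return self._top_n
        return int(self.df["rank"].max()) if len(self.df) else 0

    @property
    def n_spectra(self) -> int:
        return self.df["spectrum_id"].nunique()

    def spectra(self) -> np.ndarray:
        return self.df["spectrum_id"].unique()

    def rank1(self, include_decoys: bool = True) -> pd.DataFrame:
        """Best hit per spectrum (lowest rank; non-decoy when excluded)."""
        df = self.df
        if not include_decoys:
            df = df[~df["is_decoy"]]
        idx = df.groupby("spectrum_id", sort=False)["rank"].idxmin()
        return df.loc[idx]

    def filter_spectra(self, spectrum_ids) -> "RankedPsmTable":
        keep = self.df["spectrum_id"].isin(set(spectrum_ids))
        return RankedPsmTable(
            self.df.loc[keep, list(CANONICAL_COLUMNS)],
            score_name=self.score_name,
            score_orientation=self.score_orientation,
            top_n=self._top_n,
            validate=False,
        )

    def __len__(self):
        return len(self.df)

    def __repr__(self):
        return (f"<RankedPsmTable {self.n_spectra} spectra, {len(self.df)} records, "
                f"score={self.score_name!r} ({self.score_orientation})>")

    def write(self, path):
        write_psm_table(self, path)


# ---------------------------------------------------------------------------
# canonical TSV
# ---------------------------------------------------------------------------

def _fmt_opt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_psm_table(path, *, score_name: str = "score",
                   score_orientation: str = HIGHER_BETTER,
                   top_n: int | None = None) -> RankedPsmTable:
    """Read a canonical PSM TSV, validate it and orient its scores."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"spectrum_id": str, "peptide": str, "protein_ids": str},
        keep_default_na=False, na_values=["NA"],
    )
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path.name}: empty table")
    if df["is_decoy"].dtype == object:
        df["is_decoy"] = df["is_decoy"].map(
            {"true": True, "false": False, "True": True, "False": False})
        if df["is_decoy"].isna().any():
            raise FormatError(f"{path.name}: is_decoy must be true/false")
    return RankedPsmTable(df, score_name=score_name,
                          score_orientation=score_orientation, top_n=top_n)


def write_psm_table(table: RankedPsmTable, path) -> None:
    """Write the canonical TSV; inverse of :func:`read_psm_table`."""
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for row in table.df.itertuples(index=False):
        charge = row.charge
        if charge is not None and not (isinstance(charge, float) and math.isnan(charge)):
            charge = int(charge)
        else:
            charge = None
        prot = row.protein_ids
        if prot is None or (isinstance(prot, float) and math.isnan(prot)) or prot == "":
            prot = "NA"
        lines.append("\t".join([
            str(row.spectrum_id),
            str(int(row.rank)),
            str(row.peptide),
            _fmt_opt(charge),
            repr(float(row.score)),
            _fmt_opt(row.e_value),
            _fmt_opt(row.p_value),
            "true" if row.is_decoy else "false",
            str(prot),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA and digestion
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(protein_id, sequence), ...]`` preserving order.

    Sequences are uppercased and trailing/internal ``*`` stop codons removed.
    The protein id is the first whitespace-delimited token of the header.
    Residues outside the 20 amino acids plus B/J/O/U/X/Z trigger a warning but
    the record is kept.
    """
    path = Path(path)
    out = []
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            pid = description.split()[0] if description.split() else description
            seq = sequence.upper().replace("*", "")
            odd = set(seq) - VALID_RESIDUES
            if odd:
                warnings.warn(
                    f"{pid}: unexpected residue(s) {''.join(sorted(odd))}; record kept")
            out.append((pid, seq))
    if not out:
        raise FormatError(f"{path.name}: empty FASTA")
    return out


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


#: trypsin: cleave C-terminal to K or R except before P
TRYPSIN_RULE = r"[KR](?!P)"


def tryptic_digest(sequence: str, missed_cleavages: int = 0,
                   min_len: int = 7, max_len: int = 50) -> set[str]:
    """In-silico tryptic digestion of one protein sequence."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    if not sequence:
        return set()
    return set(_parser.cleave(sequence, TRYPSIN_RULE, missed_cleavages,
                              min_length=min_len, max_length=max_len))


def digest_fasta(records: Sequence[tuple[str, str]], missed_cleavages: int = 0,
                 min_len: int = 7, max_len: int = 50) -> SearchSpace:
    """Digest all proteins and pool the unique peptides into a search space."""
    peptides: set[str] = set()
    for _, seq in records:
        peptides |= tryptic_digest(seq, missed_cleavages, min_len, max_len)
    return SearchSpace(frozenset(peptides), source="fasta_digest")


# ---------------------------------------------------------------------------
# auxiliary lists and configuration
# ---------------------------------------------------------------------------

def read_id_list(path) -> set[str]:
    """One identifier (accession or peptide) per line; blank lines skipped."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = {ln.strip() for ln in lines if ln.strip()}
    if not out:
        raise FormatError(f"{Path(path).name}: empty identifier list")
    return out


def strip_modifications(peptide: str) -> str:
    """Bare-sequence peptide identity: drop anything that is not A-Z.

    Engines annotate modifications heterogeneously (``M[15.99]``,
    ``M+15.995``, lowercase); the default equality used for cross-search
    comparisons keeps only the uppercase residue letters (I/L stay distinct).
    """
    return "".join(ch for ch in peptide if "A" <= ch <= "Z")


def peptide_key(peptide: str, keep_modifications: bool = False) -> str:
    return peptide if keep_modifications else strip_modifications(peptide)


def read_config(path) -> dict:
    """Read the TOML run configuration (sections of ``key = value`` pairs)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path.name}: {exc}") from exc
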