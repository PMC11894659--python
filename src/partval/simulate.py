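"""Generative simulator of ranked search results with known ground truth.

The simulator emulates a database search: each spectrum is matched against a
search space Omega of unique peptides; every incorrect candidate draws an
i.i.d. Gumbel(mu0, beta) similarity score, so the best incorrect score among
n candidates is Gumbel(mu0 + beta*ln n, beta) — exactly the search-space-size
dependence that the subset score adjustment corrects for.  Identifiable
spectra (those whose generating peptide is inside Omega) additionally draw a
correct score from a configurable model and the correct peptide competes for
rank 1.  Unidentifiable spectra are "foreign": their true peptide lies
outside Omega (here guaranteed by using longer sequences), realising the
native/foreign split behind pi0.

Only the top-N order statistics of the incorrect scores are generated, via
the Renyi representation of exponential spacings — exact, and O(n_spectra *
top_n) regardless of |Omega|.  An optional decoy channel draws an independent
best-of-|Omega| Gumbel score per spectrum, exchangeable with the incorrect
target best by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .psm_io import RankedPsmTable, SearchSpace, write_fasta, write_psm_table

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated search.

    Defaults are the well-separated conditions used throughout the test
    suite: a 10,000-peptide space, 10-deep candidate lists, 85% identifiable
    spectra whose correct scores (Normal(16, 2)) sit clearly above the
    best-of-10^4 Gumbel(0, 1) null (location ~9.2).
    """

    n_spectra: int = 20_000
    frac_identifiable: float = 0.85
    space_size: int = 10_000
    top_n: int = 10
    correct_score_model: tuple = ("normal", 16.0, 2.0)  # (family, loc, scale)
    null_score_model: tuple = (0.0, 1.0)  # Gumbel (mu0, beta)
    decoy_channel: bool = True
    n_entrapment: int = 0  # trailing entrapment block of Omega
    seed: int = 0

    def __post_init__(self):
        if self.n_spectra < 1:
            raise ConfigError("n_spectra must be >= 1")
        if not 0 <= self.frac_identifiable <= 1:
            raise ConfigError("frac_identifiable must lie in [0, 1]")
        if self.space_size < self.top_n:
            raise ConfigError("space_size must be >= top_n")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        family, _, scale = self.correct_score_model
        if family not in ("normal", "gumbel"):
            raise ConfigError(f"unknown correct score family {family!r}")
        if scale <= 0 or self.null_score_model[1] <= 0:
            raise ConfigError("scale parameters must be > 0")
        if not 0 <= self.n_entrapment < self.space_size:
            raise ConfigError("n_entrapment must lie in [0, space_size)")


@dataclass
class SimResult:
    """Simulated search output: table, space, per-spectrum truth, decoys."""

    table: RankedPsmTable
    space: SearchSpace
    truth: pd.DataFrame  # spectrum_id, true_peptide, identifiable, channel
    decoys: RankedPsmTable | None
    config: SimConfig
    peptides: list = field(repr=False, default_factory=list)  # Omega, indexed


def random_peptides(rng, count: int, min_len: int = 8, max_len: int = 15,
                    forbidden=()) -> list[str]:
    """Unique random peptide strings over the 20-letter alphabet."""
    forbidden = set(forbidden)
    out: list[str] = []
    seen = set()
    while len(out) < count:
        need = count - len(out)
        lens = rng.integers(min_len, max_len + 1, size=need)
        chars = rng.integers(0, 20, size=(need, max_len))
        for i in range(need):
            pep = _AA[chars[i, :lens[i]]].tobytes().decode()
            if pep not in seen and pep not in forbidden:
                seen.add(pep)
                out.append(pep)
    return out


def _top_gumbel_order_stats(rng, counts: np.ndarray, top_n: int,
                            mu0: float, beta: float) -> np.ndarray:
    """Exact top-``top_n`` order statistics of ``counts[i]`` i.i.d. Gumbels.

    Uses X = mu0 - beta*ln(T) where T are the smallest order statistics of
    i.i.d. Exp(1), generated by Renyi's spacing representation.
    """
    n = len(counts)
    spacings = rng.exponential(size=(n, top_n))
    denom = counts[:, None] - np.arange(top_n)[None, :]
    T = np.cumsum(spacings / denom, axis=1)
    return mu0 - beta * np.log(T)


def _distinct_candidates(rng, n_spectra: int, space_size: int, top_n: int,
                         exclude: np.ndarray) -> np.ndarray:
    """(n_spectra, top_n) distinct candidate indices, avoiding exclude[i]."""
    cand = rng.integers(0, space_size, size=(n_spectra, top_n))
    while True:
        srt = np.sort(cand, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        bad |= (cand == exclude[:, None]).any(axis=1)
        idx = np.flatnonzero(bad)
        if idx.size == 0:
            return cand
        cand[idx] = rng.integers(0, space_size, size=(idx.size, top_n))


def simulate(config: SimConfig) -> SimResult:
    """Draw one complete simulated search with known per-spectrum truth."""
    rng = np.random.default_rng(config.seed)
    omega = random_peptides(rng, config.space_size)
    n = config.n_spectra
    identifiable = rng.random(n) < config.frac_identifiable
    n_sample = config.space_size - config.n_entrapment
    true_idx = np.where(identifiable, rng.integers(0, n_sample, size=n), -1)
    return _simulate_scores(config, omega, identifiable, true_idx, rng)


def _simulate_scores(config: SimConfig, omega: list[str],
                     identifiable: np.ndarray, true_idx: np.ndarray,
                     rng) -> SimResult:
    n, top_n = config.n_spectra, config.top_n
    mu0, beta = config.null_score_model

    n_incorrect = config.space_size - identifiable.astype(np.int64)
    inc_scores = _top_gumbel_order_stats(rng, n_incorrect, top_n, mu0, beta)
    cand = _distinct_candidates(rng, n, config.space_size, top_n,
                                exclude=true_idx)

    # correct channel competes for rank 1
    family, loc, scale = config.correct_score_model
    draw = rng.normal if family == "normal" else rng.gumbel
    corr_scores = np.where(identifiable, draw(loc, scale, size=n), -np.inf)
    all_scores = np.concatenate([corr_scores[:, None], inc_scores], axis=1)
    all_idx = np.concatenate([true_idx[:, None], cand], axis=1)
    order = np.argsort(-all_scores, axis=1, kind="stable")[:, :top_n]
    rows = np.arange(n)[:, None]
    top_scores = np.take_along_axis(all_scores, order, axis=1)
    top_idx = np.take_along_axis(all_idx, order, axis=1)

    sid = np.array([f"spec_{i:06d}" for i in range(n)])
    omega_arr = np.array(omega, dtype=object)
    prot = np.where(np.arange(config.space_size) <
                    config.space_size - config.n_entrapment,
                    "SAMPLE_", "ENTRAP_").astype(object)
    prot_arr = np.array([f"{p}{i:06d}" for i, p in enumerate(prot)], dtype=object)

    flat_idx = top_idx.ravel()
    df = pd.DataFrame({
        "spectrum_id": np.repeat(sid, top_n),
        "rank": np.tile(np.arange(1, top_n + 1), n),
        "peptide": omega_arr[flat_idx],
        "charge": 2,
        "score": top_scores.ravel(),
        # e-value of a score under the per-candidate Gumbel null
        "e_value": config.space_size * np.exp(-(top_scores.ravel() - mu0) / beta),
        "p_value": np.nan,
        "is_decoy": False,
        "protein_ids": prot_arr[flat_idx],
    })
    table = RankedPsmTable(df, score_name="sim_score", top_n=top_n,
                           validate=False)

    # foreign true peptides: longer than anything in Omega, hence outside it
    foreign = random_peptides(rng, int((~identifiable).sum()),
                              min_len=17, max_len=20)
    true_pep = np.empty(n, dtype=object)
    true_pep[identifiable] = omega_arr[true_idx[identifiable]]
    true_pep[~identifiable] = foreign
    truth = pd.DataFrame({
        "spectrum_id": sid,
        "true_peptide": true_pep,
        "identifiable": identifiable,
        "channel": np.where(identifiable, "native", "foreign"),
    })

    decoys = None
    if config.decoy_channel:
        dsc = rng.gumbel(mu0 + beta * np.log(config.space_size), beta, size=n)
        ddf = pd.DataFrame({
            "spectrum_id": sid,
            "rank": 1,
            "peptide": [f"XDECOY{i:06d}Z" for i in range(n)],
            "charge": 2,
            "score": dsc,
            "e_value": config.space_size * np.exp(-(dsc - mu0) / beta),
            "p_value": np.nan,
            "is_decoy": True,
            "protein_ids": "DECOY",
        })
        decoys = RankedPsmTable(ddf, score_name="sim_score", top_n=1,
                                validate=False)

    space = SearchSpace(frozenset(omega), source="explicit_list")
    return SimResult(table=table, space=space, truth=truth, decoys=decoys,
                     config=config, peptides=list(omega))


def simulate_with_truth(config: SimConfig, base: SimResult,
                        seed: int) -> SimResult:
    """Re-draw all scores and candidate lists while keeping the truth fixed.

    Emulates a second search engine (or a technical replicate) over the same
    spectra and search space: identities are shared, score noise is not.
    """
    if config.space_size != base.config.space_size:
        raise ConfigError("shared-truth simulation requires the same space")
    rng = np.random.default_rng(seed)
    identifiable = base.truth["identifiable"].to_numpy()
    omega_pos = {p: i for i, p in enumerate(base.peptides)}
    true_idx = np.array([
        omega_pos.get(p, -1) for p in base.truth["true_peptide"]], dtype=np.int64)
    out = _simulate_scores(config, base.peptides, identifiable, true_idx, rng)
    return replace(out, truth=base.truth.copy())


def true_fdp(table: RankedPsmTable, truth: pd.DataFrame, t: float) -> float:
    """Ground-truth FDP of rank-1 PSMs accepted at oriented score >= t."""
    top = table.rank1(include_decoys=False)
    merged = top.merge(truth, on="spectrum_id", how="left")
    acc = merged["oriented_score"].to_numpy() >= t
    n = int(acc.sum())
    if n == 0:
        return float("nan")
    wrong = merged["peptide"].to_numpy() != merged["true_peptide"].to_numpy()
    return float((wrong & acc).sum()) / n


def label_truth(labeled: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """True incorrect-indicator for labeled subset hits (peptide != truth)."""
    merged = labeled.merge(truth, on="spectrum_id", how="left")
    return merged["peptide"].to_numpy() != merged["true_peptide"].to_numpy()


# ---------------------------------------------------------------------------
# registered toy fixtures
# ---------------------------------------------------------------------------

FIXTURES: dict[str, SimConfig] = {
    # every spectrum unidentifiable: all labels incorrect, true FDP = 1
    "pure_null": SimConfig(n_spectra=10_000, frac_identifiable=0.0,
                           space_size=5_000, top_n=10,
                           correct_score_model=("normal", 16.0, 2.0)),
    # clear correct/incorrect separation: the convergence test substrate
    "separated": SimConfig(),
    # bipartite sample/entrapment space; identifiable truths in the sample half
    "entrapment": SimConfig(n_spectra=8_000, frac_identifiable=0.7,
                            space_size=8_000, n_entrapment=4_000),
    # three engines sharing truth plus a mass-shift surrogate (all-null)
    "triple_engine": SimConfig(n_spectra=3_000, frac_identifiable=0.7,
                               space_size=4_000),
}


def make_fixture(name: str, out_dir, seed: int | None = None) -> dict[str, Path]:
    """Write a registered toy scenario to disk in the canonical formats.

    Emits ``psms.tsv``, ``truth.tsv``, ``space.fasta`` (one entry per
    peptide), ``decoys.tsv`` when the decoy channel is on, plus
    fixture-specific extras (entrapment accession list; per-engine tables and
    a shifted-search surrogate for ``triple_engine``).
    """
    if name not in FIXTURES:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}")
    cfg = FIXTURES[name]
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = simulate(cfg)
    paths: dict[str, Path] = {}

    def _write_table(key, table):
        paths[key] = out / f"{key}.tsv"
        write_psm_table(table, paths[key])

    _write_table("psms", res.table)
    if res.decoys is not None:
        _write_table("decoys", res.decoys)
    paths["truth"] = out / "truth.tsv"
    res.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["space"] = out / "space.fasta"
    write_fasta([(f"PEP_{i:06d}", p) for i, p in enumerate(res.peptides)],
                paths["space"])

    if name == "entrapment":
        ids = sorted({pid for pid in res.table.df["protein_ids"]
                      if pid.startswith("ENTRAP_")})
        paths["entrapment_ids"] = out / "entrapment_ids.txt"
        paths["entrapment_ids"].write_text("\n".join(ids) + "\n")
    if name == "triple_engine":
        for engine, sub_seed in (("engine_b", cfg.seed + 101),
                                 ("engine_c", cfg.seed + 202)):
            other = simulate_with_truth(cfg, res, seed=sub_seed)
            _write_table(engine, other.table)
        # mass-shift surrogate: same spectra and space, every match incorrect
        shifted_cfg = replace(cfg, frac_identifiable=0.0, decoy_channel=False,
                              seed=cfg.seed + 303)
        shifted = _simulate_scores(
            shifted_cfg, res.peptides,
            identifiable=np.zeros(cfg.n_spectra, dtype=bool),
            true_idx=np.full(cfg.n_spectra, -1, dtype=np.int64),
            rng=np.random.default_rng(shifted_cfg.seed))
        _write_table("shifted", shifted.table)
    return paths
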