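import numpy as np
import pandas as pd
import pytest

import partval as pv


def make_table(rows, **kwargs):
    """Build a RankedPsmTable from (spectrum_id, rank, peptide, score[, decoy])."""
    recs = []
    for row in rows:
        sid, rank, pep, score = row[:4]
        decoy = row[4] if len(row) > 4 else False
        recs.append(pv.PsmRecord(spectrum_id=sid, rank=rank, peptide=pep,
                                 score=score, is_decoy=decoy))
    return pv.RankedPsmTable.from_records(recs, **kwargs)


@pytest.fixture
def toy_table():
    """Three spectra, three ranked candidates each."""
    return make_table([
        ("s1", 1, "AAA", 10.0), ("s1", 2, "BBB", 8.0), ("s1", 3, "CCC", 5.0),
        ("s2", 1, "BBB", 7.0), ("s2", 2, "DDD", 6.0), ("s2", 3, "EEE", 2.0),
        ("s3", 1, "CCC", 9.0), ("s3", 2, "AAA", 4.0), ("s3", 3, "FFF", 1.0),
    ])


@pytest.fixture(scope="session")
def sim_separated():
    """Moderate-size well-separated simulation shared across module tests."""
    return pv.simulate(pv.SimConfig(n_spectra=4000, space_size=5000, seed=42))


@pytest.fixture(scope="session")
def sim_labels(sim_separated):
    """Subset-search labels with TDC q-values for the shared simulation."""
    res = sim_separated
    union = pv.candidate_union(res.table, 10)
    part = pv.partition_space(union, k=2, seed=7)
    hits = pv.postsearch_scan(res.table, part.selected, 10)
    labeled = pv.label_hits(hits)
    adj = pv.adjust_score_for_subset(
        labeled["validation_score"].to_numpy(), 2, "gumbel", gumbel_scale=1.0)
    dmap = res.decoys.rank1().set_index("spectrum_id")["oriented_score"]
    ds = dmap.reindex(labeled["spectrum_id"]).to_numpy()
    win = adj >= ds
    q = np.ones(len(labeled))
    q[win] = pv.tdc_qvalues(adj[win], ds[~win])
    return labeled, q
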