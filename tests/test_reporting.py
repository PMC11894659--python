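"""Bootstrap bands, stability selection, reports, CLI and orchestration."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import partval as pv
from partval.cli import main as cli_main
from partval.errors import ConfigError
from partval.reporting import plot_band


def labels_frame(scores, statuses):
    return pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(len(scores))],
        "peptide": [f"P{i}" for i in range(len(scores))],
        "validation_score": scores,
        "status": statuses,
    })


class TestBootstrapBand:
    def test_degenerate_labels_zero_width(self):
        lab = labels_frame([1.0] * 50, ["correct"] * 50)
        band = pv.bootstrap_band(lab, [0.01] * 50, [0.05], B=200, seed=1)
        row = band.grid.iloc[0]
        assert row["band_low"] == row["band_high"] == row["pfdp"] == 0.0

    def test_reproducible_given_seed(self, sim_labels):
        lab, q = sim_labels
        a = pv.bootstrap_band(lab, q, [0.01, 0.05, 0.1], B=300, seed=7)
        b = pv.bootstrap_band(lab, q, [0.01, 0.05, 0.1], B=300, seed=7)
        pd.testing.assert_frame_equal(a.grid, b.grid)

    def test_band_brackets_point_estimate(self, sim_labels):
        lab, q = sim_labels
        band = pv.bootstrap_band(lab, q, [0.02, 0.05, 0.1, 0.2], B=300, seed=3)
        g = band.grid[~band.grid["masked"]]
        assert (g["band_low"] <= g["pfdp"] + 1e-12).all()
        assert (g["band_high"] >= g["pfdp"] - 1e-12).all()

    def test_unreachable_point_masked(self):
        lab = labels_frame([1.0, 2.0], ["correct", "correct"])
        band = pv.bootstrap_band(lab, [0.4, 0.5], [0.001, 0.5], B=100, seed=1)
        assert bool(band.grid.iloc[0]["masked"])
        assert not bool(band.grid.iloc[1]["masked"])

    def test_small_B_rejected(self, sim_labels):
        lab, q = sim_labels
        with pytest.raises(ConfigError):
            pv.bootstrap_band(lab, q, [0.05], B=10)


class TestSelectStableThreshold:
    def curves(self, widths, n=2000):
        """Synthetic curves whose bootstrap widths scale with `widths`."""
        rng = np.random.default_rng(0)
        out = []
        for i, w in enumerate(widths):
            m = max(30, int(1.0 / w))
            lab = labels_frame(
                rng.uniform(size=m).tolist(),
                ["incorrect" if v else "correct" for v in rng.random(m) < 0.3])
            q = np.full(m, 0.04)
            out.append(pv.ValidationCurve(
                qf_threshold=float(i),
                grid=pd.DataFrame({"fdr_threshold": [0.02, 0.05, 0.1]}),
                n_labeled=n, stable=True, labeled=lab, qvalues=q))
        return out

    def test_argmin_width(self):
        curves = self.curves([0.05, 0.002])  # second far narrower
        best = pv.select_stable_threshold(curves, min_psms=1, B=200, seed=5)
        assert best == 1.0

    def test_order_invariance(self):
        curves = self.curves([0.05, 0.002, 0.02])
        a = pv.select_stable_threshold(curves, min_psms=1, B=200, seed=5)
        b = pv.select_stable_threshold(curves[::-1], min_psms=1, B=200, seed=5)
        assert a == b

    def test_all_below_min_psms_errors(self):
        curves = self.curves([0.05, 0.02], n=10)
        with pytest.raises(ConfigError, match="widen"):
            pv.select_stable_threshold(curves, min_psms=1000)

    def test_tie_takes_larger_threshold(self):
        c = self.curves([0.02])[0]
        import copy
        c2 = copy.deepcopy(c)
        c2.qf_threshold = 5.0
        best = pv.select_stable_threshold([c, c2], min_psms=1, B=150, seed=1)
        assert best == 5.0


@pytest.fixture(scope="module")
def results(sim_separated):
    res = sim_separated
    model = pv.PartitionValidation(
        res.table, decoy_table=res.decoys, fdr_method="tdc",
        score_kind="gumbel", gumbel_scale=1.0, seed=4,
        qf_grid=pv.QfGrid((12.0, 14.0), min_retained_psms=500))
    return model.fit()


class TestReports:
    def test_contour_report_writes_figure_and_tsv_twin(self, results, tmp_path):
        paths = pv.contour_report(results, tmp_path)
        assert paths["tsv"].exists() and paths["png"].exists() \
            and paths["svg"].exists()
        twin = pd.read_csv(paths["tsv"], sep="\t")
        frame = results.curves_frame()
        assert np.allclose(twin["pfdp"], frame["pfdp"])

    def test_band_plot_runs(self, results):
        band = results.bootstrap_band(12.0, B=150, seed=2)
        ax = plot_band(band)
        assert ax.get_xlabel().startswith("FDR")

    def test_save_results_layout(self, results, tmp_path):
        paths = results.save(tmp_path / "out", B=150, seed=2)
        for key in ("curves", "band", "labels", "summary", "log", "tsv"):
            assert paths[key].exists()
        summary = json.loads(paths["summary"].read_text())
        assert summary["mode"] == "postsearch"
        assert summary["selected_qf_threshold"] in (12.0, 14.0)


def write_fixture_config(tmp_path, fixture_dir, seed=3, plots="none"):
    cfg = tmp_path / "run.toml"
    cfg.write_text(f"""
[input]
psm_table = "{fixture_dir/'psms.tsv'}"
decoy_table = "{fixture_dir/'decoys.tsv'}"

[run]
mode = "postsearch"
seed = {seed}
out_dir = "{tmp_path/'out'}"

[partition]
k = 2
top_n = 10

[qf]
thresholds = [12.0, 14.0]
min_retained = 200

[fdr]
method = "tdc"
score_kind = "gumbel"
gumbel_scale = 1.0

[report]
plots = "{plots}"
bootstrap = 150
""")
    return cfg


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fix")
    cfg = pv.SimConfig(n_spectra=1500, space_size=3000, seed=8)
    res = pv.simulate(cfg)
    res.table.write(d / "psms.tsv")
    res.decoys.write(d / "decoys.tsv")
    return d


class TestRunValidation:
    def test_writes_declared_artifacts(self, fixture_dir, tmp_path):
        cfg = write_fixture_config(tmp_path, fixture_dir)
        out = pv.run_validation(cfg)
        for name in ("curves.tsv", "labels.tsv", "banded_curve.tsv",
                     "summary.json", "run.log"):
            assert (out / name).exists()

    def test_invalid_mode_fails_before_computation(self, fixture_dir, tmp_path):
        cfg = write_fixture_config(tmp_path, fixture_dir)
        raw = cfg.read_text().replace('mode = "postsearch"', 'mode = "bogus"')
        cfg.write_text(raw)
        with pytest.raises(ConfigError):
            pv.run_validation(cfg)


class TestCli:
    def test_simulate_fixture(self, tmp_path):
        r = CliRunner().invoke(
            cli_main, ["simulate", "--fixture", "pure_null",
                       "--out", str(tmp_path), "--seed", "3"])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "psms.tsv").exists()

    def test_unknown_fixture_exits_2(self, tmp_path):
        r = CliRunner().invoke(
            cli_main, ["simulate", "--fixture", "zzz", "--out", str(tmp_path)])
        assert r.exit_code == 2

    def test_partition_fasta(self, tmp_path):
        fa = tmp_path / "db.fasta"
        pv.write_fasta([(f"p{i}", "PEPTIDEK" + "AR" * i) for i in range(6)], fa)
        r = CliRunner().invoke(
            cli_main, ["partition-fasta", "--fasta", str(fa), "--k", "2",
                       "--seed", "1", "--min-len", "2"])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "db.part0.fasta").exists()
        assert (tmp_path / "db.part1.fasta").exists()
        a = {p for _, p in pv.read_fasta(tmp_path / "db.part0.fasta")}
        b = {p for _, p in pv.read_fasta(tmp_path / "db.part1.fasta")}
        assert not a & b

    def test_validate_command(self, tmp_path):
        d = tmp_path / "fix"
        d.mkdir()
        res = pv.simulate(pv.SimConfig(n_spectra=1200, space_size=2500, seed=6))
        res.table.write(d / "psms.tsv")
        res.decoys.write(d / "decoys.tsv")
        cfg = write_fixture_config(tmp_path, d)
        r = CliRunner().invoke(cli_main, ["validate", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
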