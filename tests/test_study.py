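"""Study orchestration and CLI: manifests, fault isolation, comparisons."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from nlsbind.cli import main as cli_main
from nlsbind.study import (
    ManifestError,
    StudyManifest,
    compare_enantiomers,
    load_manifest,
    run_study,
)
from nlsbind.synth import gen_dosy, gen_itc, gen_sensorgram_set, gen_titration


@pytest.fixture
def fixture_dir(tmp_path):
    """Synthetic datasets for one peptide/species pair, written as CSVs."""
    curve = gen_titration(100.0, -40.0, 12.0)
    pd.DataFrame(
        {"ligand_total_uM": [p.ligand_total for p in curve.points],
         "intensity": [p.intensity_raw for p in curve.points],
         "blank": 0.0}
    ).to_csv(tmp_path / "fluor.csv", index=False)

    files = []
    for i, s in enumerate(gen_sensorgram_set(0.068, 0.069)):
        name = f"bli_{i}.csv"
        pd.DataFrame({"time_s": s.time, "response_RU": s.response}).to_csv(
            tmp_path / name, index=False)
        files.append({"path": name, "ligand_conc_uM": s.ligand_conc})

    iso = gen_itc(1.0, 2.7, -2.5)
    pd.DataFrame(
        {"volume_uL": iso.experiment.injection_volumes_ul, "heat_ucal": iso.heats}
    ).to_csv(tmp_path / "itc.csv", index=False)

    for name, d in (("dosy.csv", 1.78e-6), ("dioxane.csv", 1.05e-5)):
        series = gen_dosy(d)
        pd.DataFrame({"gradient_fraction": series.gradient_fraction,
                      "intensity": series.intensity}).to_csv(
            tmp_path / name, index=False)

    datasets = [
        {"peptide": "pepA", "species": "full", "technique": "fluorescence",
         "path": "fluor.csv", "receptor_total_uM": 3.0},
        {"peptide": "pepA", "species": "full", "technique": "bli", "files": files},
        {"peptide": "pepA", "species": "full", "technique": "itc", "path": "itc.csv"},
        {"peptide": "pepA", "species": "full", "technique": "dosy",
         "path": "dosy.csv", "reference_path": "dioxane.csv",
         "max_gradient": 40.0, "mw_da": 2511.78, "rh_coil_se_A": 3.0},
    ]
    manifest = {
        "peptides": [{"id": "pepA", "sequence": "YTNRPSPGGHERKLVTKLQNSE",
                      "chirality": "D"}],
        "datasets": datasets,
        "l_reference": [{"peptide": "pepA", "species": "full", "kd": 3.0}],
    }
    with open(tmp_path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return tmp_path


class TestRunStudy:
    def test_full_fixture_run_recovers_truth(self, fixture_dir):
        manifest = load_manifest(fixture_dir / "manifest.yaml")
        result = run_study(manifest, out_dir=fixture_dir / "out")
        assert result.failures == []
        assert len(result.table) == 1
        row = result.table.iloc[0]
        assert row["kd_fluor"] == pytest.approx(12.0, rel=1e-3)
        assert row["kd_bli"] == pytest.approx(0.069 / 0.068, rel=1e-3)
        assert row["kd_itc"] == pytest.approx(2.7, rel=1e-3)
        assert row["oligomeric_verdict"] == "monomeric_disordered"
        assert (fixture_dir / "out" / "results.csv").exists()
        assert (fixture_dir / "out" / "results.json").exists()

    def test_corrupted_file_is_isolated(self, fixture_dir):
        (fixture_dir / "fluor.csv").write_text("not,a,real\ncsv,file,,\n")
        manifest = load_manifest(fixture_dir / "manifest.yaml")
        result = run_study(manifest)
        assert len(result.failures) == 1
        assert result.failures[0]["technique"] == "fluorescence"
        row = result.table.iloc[0]
        assert row["kd_bli"] == pytest.approx(0.069 / 0.068, rel=1e-3)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ManifestError):
            StudyManifest(peptides={}, datasets=[]).validate()

    def test_missing_file_rejected(self, tmp_path):
        m = StudyManifest(
            peptides={}, base_dir=tmp_path,
            datasets=[{"technique": "itc", "path": "nope.csv"}],
        )
        with pytest.raises(ManifestError):
            m.validate()

    def test_duplicate_dataset_rejected(self, fixture_dir):
        manifest = load_manifest(fixture_dir / "manifest.yaml")
        manifest.datasets.append(dict(manifest.datasets[0]))
        with pytest.raises(ManifestError):
            manifest.validate()


class TestCompareEnantiomers:
    def test_fold_difference_and_concordance(self):
        d = pd.DataFrame([{"peptide": "pepA", "species": "full", "kd_bli": 1.0}])
        comp = compare_enantiomers(d, {("pepA", "full"): 3.0})
        row = comp.iloc[0]
        assert row["fold_difference"] == pytest.approx(1.0 / 3.0)
        assert bool(row["concordant"])

    def test_equal_kd_gives_fold_one(self):
        d = pd.DataFrame([{"peptide": "p", "species": "full", "kd_itc": 5.0}])
        comp = compare_enantiomers(d, {("p", "full"): 5.0})
        assert comp.iloc[0]["fold_difference"] == pytest.approx(1.0)

    def test_missing_l_reference_leaves_columns_empty(self):
        d = pd.DataFrame([{"peptide": "p", "species": "full", "kd_bli": 5.0}])
        comp = compare_enantiomers(d, {})
        assert comp.iloc[0]["fold_difference"] is None

    def test_discordant_fold(self):
        d = pd.DataFrame([{"peptide": "p", "species": "full", "kd_bli": 100.0}])
        comp = compare_enantiomers(d, {("p", "full"): 1.0})
        assert not comp.iloc[0]["concordant"]


class TestCLI:
    def test_fluor_fit(self, fixture_dir):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["fluor", "fit", str(fixture_dir / "fluor.csv"),
                                       "--receptor-total", "3.0"])
        assert res.exit_code == 0, res.output
        assert "Kd" in res.output

    def test_synth_make_then_dosy_fit(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"technique": "dosy", "D": 1.0e-6}))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["synth", "make", "--config", str(cfg),
                                       "--out-dir", str(tmp_path / "fx")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["dosy", "fit", str(tmp_path / "fx" / "dosy.csv"),
                                       "--max-gradient", "40"])
        assert res.exit_code == 0, res.output
        assert "1e-06" in res.output.replace("1.0e-06", "1e-06") or "D" in res.output

    def test_study_run(self, fixture_dir):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "study", "run", "--manifest", str(fixture_dir / "manifest.yaml"),
            "--out-dir", str(fixture_dir / "cli_out")])
        assert res.exit_code == 0, res.output
        assert (fixture_dir / "cli_out" / "results.csv").exists()
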