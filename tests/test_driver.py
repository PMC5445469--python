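import numpy as np
import pytest

from essdyn.driver import JobConfig, parse_config, parse_selection, run_batch, run_job, serialize_config
from essdyn.io import read_coordinate_matrix
from essdyn.synthetic import (
    PlantedModel,
    make_reference,
    random_orthonormal_modes,
    sample_trajectory,
    write_trajectory_pdbs,
)


@pytest.fixture
def fixture_inputs(tmp_path):
    """A small planted trajectory written as PDB frames plus a pair list."""
    ref = make_reference(8)
    gen = np.random.default_rng(77)
    v = random_orthonormal_modes(ref, 3, gen)
    model = PlantedModel(ref, v, np.array([4.0, 2.0, 1.0]), rigid_noise=True, seed=77)
    traj, _ = sample_trajectory(model, 60)
    paths = write_trajectory_pdbs(traj, tmp_path / "frames")
    pdb_list = tmp_path / "frames.txt"
    pdb_list.write_text("\n".join(str(p) for p in paths) + "\n")
    pair_list = tmp_path / "pairs.txt"
    pair_list.write_text("A 1 A 5\nA 2 A 8\nA 3 A 7\n")
    return pdb_list, pair_list


def write_config(tmp_path, pdb_list, pair_list=None, extra=""):
    cfg = tmp_path / "driver.txt"
    text = f"pdb_list = {pdb_list}\nout_dir = {tmp_path / 'out'}\n" + extra
    if pair_list is not None:
        text += f"pair_list = {pair_list}\n"
    cfg.write_text(text)
    return cfg


class TestParseConfig:
    def test_minimal_config_defaults(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        cfg = write_config(tmp_path, pdb_list)
        config = parse_config(cfg)
        assert config.modes_retained == 20
        assert config.zscore_cutoff == 0.0  # disabled
        assert config.matrices == ("Q", "R", "P")
        assert config.pca == "cpca"

    def test_dppca_without_pair_list_rejected(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        cfg = write_config(tmp_path, pdb_list, extra="pca = dppca\n")
        with pytest.raises(ValueError, match="pair_list"):
            parse_config(cfg)

    def test_missing_input_rejected(self, tmp_path):
        cfg = tmp_path / "driver.txt"
        cfg.write_text("pca = cpca\n")
        with pytest.raises(ValueError, match="pdb_list or coordinate_matrix"):
            parse_config(cfg)

    def test_unknown_key_warns_not_errors(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        cfg = write_config(tmp_path, pdb_list, extra="frobnicate = 7\n")
        with pytest.warns(UserWarning, match="frobnicate"):
            parse_config(cfg)

    def test_serialize_reparse_round_trip(self, tmp_path, fixture_inputs):
        pdb_list, pair_list = fixture_inputs
        cfg = write_config(
            tmp_path, pdb_list, pair_list,
            extra="pca = both\nmodes_retained = 5\nzscore_cutoff = 2.5\nfes_modes = 1,2\n",
        )
        config = parse_config(cfg)
        out = tmp_path / "reserialized.txt"
        serialize_config(config, out)
        assert parse_config(out) == config

    def test_selection_parsing(self):
        sel = parse_selection("A:1-3,B:12")
        assert sel.entries == (("A", 1), ("A", 2), ("A", 3), ("B", 12))
        assert parse_selection("all") == "all"


class TestRunJob:
    def test_cpca_output_manifest(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        config = parse_config(
            write_config(tmp_path, pdb_list, extra="modes_retained = 4\nzscore_cutoff = 3.0\n")
        )
        out = run_job(config)
        cdir = out / "cPCA"
        for mk in ("Q", "R", "P"):
            assert (cdir / f"{mk}_matrix.txt").exists()
            assert (cdir / f"{mk}_eigenvalues.txt").exists()
            assert (cdir / f"{mk}_top_eigenvectors.txt").exists()
            assert (cdir / f"{mk}_pcs.txt").exists()
            V = read_coordinate_matrix(cdir / f"{mk}_top_eigenvectors.txt", cartesian=False)
            assert V.shape == (24, 4)
        assert (cdir / "reduced_Q.txt").exists()
        assert (cdir / "Q_msf_weighted.txt").exists()
        assert (cdir / "rmsf_per_residue.txt").exists()
        assert (cdir / "mean_structure_rmsf_bfactors.pdb").exists()
        assert (cdir / "outlier_report.txt").exists()
        assert (out / "pdb_read.log").exists()
        log = (out / "run_log.txt").read_text()
        assert "job finished" in log and "condition_number" in log

    def test_both_kinds_with_fes(self, tmp_path, fixture_inputs):
        pdb_list, pair_list = fixture_inputs
        config = parse_config(
            write_config(
                tmp_path, pdb_list, pair_list,
                extra="pca = both\nmodes_retained = 3\nfes_modes = 1,2\n",
            )
        )
        out = run_job(config)
        assert (out / "cPCA" / "fes_pc1_pc2.txt").exists()
        assert (out / "dpPCA" / "Q_matrix.txt").exists()
        D = read_coordinate_matrix(out / "dpPCA" / "distance_matrix.txt", cartesian=False)
        assert D.shape == (3, 60)
        # dpPCA Q dimension equals the pair count
        Q = read_coordinate_matrix(out / "dpPCA" / "Q_matrix.txt", cartesian=False)
        assert Q.shape == (3, 3)

    def test_rerun_is_byte_identical(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        cfg = write_config(tmp_path, pdb_list, extra="modes_retained = 3\n")
        config = parse_config(cfg)
        out1 = run_job(config)
        snapshot = {
            p.name: p.read_bytes()
            for p in (out1 / "cPCA").iterdir()
            if p.suffix in (".txt", ".pdb")
        }
        out2 = run_job(config)
        for name, blob in snapshot.items():
            assert (out2 / "cPCA" / name).read_bytes() == blob

    def test_batch_runs_independent_trees(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        cfgs = []
        for i in range(3):
            cfg = tmp_path / f"driver_{i}.txt"
            cfg.write_text(
                f"pdb_list = {pdb_list}\nout_dir = {tmp_path / f'out_{i}'}\n"
                "modes_retained = 2\n"
            )
            cfgs.append(cfg)
        outs = run_batch(cfgs)
        assert len(outs) == 3
        assert len({str(o) for o in outs}) == 3
        for o in outs:
            assert (o / "cPCA" / "Q_eigenvalues.txt").exists()

    def test_outputs_parse_with_own_readers(self, tmp_path, fixture_inputs):
        pdb_list, _ = fixture_inputs
        config = parse_config(write_config(tmp_path, pdb_list, extra="modes_retained = 2\n"))
        out = run_job(config)
        aligned = read_coordinate_matrix(out / "cPCA" / "aligned_coordinates.txt")
        assert aligned.data.shape == (24, 60)
        from essdyn.io import read_pdb_frames

        pdb = read_pdb_frames([out / "cPCA" / "mean_structure_rmsf_bfactors.pdb"])
        assert pdb.n_residues == 8
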