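import filecmp

import numpy as np
import pytest

from egwaskit import io as eio
from egwaskit.synth import (
    CompendiumConfig,
    generate_compendium,
    split_total,
    write_compendium,
)


def test_default_config_matches_study_design():
    cfg = CompendiumConfig()
    assert cfg.n_experiments == 13
    assert sum(cfg.case_counts) == 251
    assert sum(cfg.control_counts) == 428
    swapped = CompendiumConfig(swap_case_control=True)
    assert sum(swapped.case_counts) == 428
    assert sum(swapped.control_counts) == 251


def test_split_total_even_and_exact():
    parts = split_total(251, 13)
    assert sum(parts) == 251 and max(parts) - min(parts) <= 1


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_genes": 0},
        {"activity_prob": 1.5},
        {"coverage_fraction": 0.0},
        {"n_true": 700, "n_genes": 600},
        {"cases_per_experiment": (5, 5)},  # wrong length for 3 experiments
    ],
)
def test_invalid_configs_rejected(overrides):
    base = dict(n_genes=600, n_experiments=3, cases_per_experiment=(5, 5, 5),
                controls_per_experiment=(5, 5, 5), seed=0)
    base.update(overrides)
    with pytest.raises(ValueError):
        CompendiumConfig(**base)


def test_generation_is_deterministic_and_files_bitwise_equal(tmp_path):
    cfg = CompendiumConfig.desk(seed=1, n_genes=200)
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    for out in (out_a, out_b):
        experiments, truth = generate_compendium(cfg)
        write_compendium(experiments, truth, out)
    for f in sorted(p.name for p in out_a.iterdir()):
        assert filecmp.cmp(out_a / f, out_b / f, shallow=False), f


def test_compendium_shape_and_truth(small_config, small_compendium):
    experiments, truth = small_compendium
    assert len(experiments) == small_config.n_experiments
    assert len(truth.table) == small_config.n_true
    universe = set(truth.universe)
    for exp, n1, n2 in zip(
        experiments, small_config.case_counts, small_config.control_counts
    ):
        assert exp.n_cases == n1 and exp.n_controls == n2
        assert set(exp.genes) <= universe
        assert not np.isnan(exp.matrix.to_numpy()).any()
    # sign is fixed per gene: one sign column, valued +-1
    assert set(truth.table["sign"].unique()) <= {-1, 1}


def test_coverage_close_to_nominal():
    cfg = CompendiumConfig(
        n_genes=2000, n_experiments=2, cases_per_experiment=(3, 3),
        controls_per_experiment=(3, 3), coverage_fraction=0.7, n_true=0, seed=3,
    )
    experiments, _ = generate_compendium(cfg)
    for exp in experiments:
        measured = len(exp.genes)
        assert abs(measured - 0.7 * 2000) <= 0.05 * 0.7 * 2000


def test_write_dimensions_and_round_trip(tmp_path):
    cfg = CompendiumConfig(
        n_genes=3, n_experiments=1, cases_per_experiment=(2,),
        controls_per_experiment=(2,), coverage_fraction=1.0, n_true=1, seed=5,
    )
    experiments, truth = generate_compendium(cfg)
    write_compendium(experiments, truth, tmp_path)
    lines = (tmp_path / "E01_matrix.tsv").read_text().splitlines()
    assert len(lines) == 4  # header + 3 gene rows
    assert all(len(line.split("\t")) == 5 for line in lines)  # id + 4 samples
    back = eio.read_experiment(tmp_path / "E01_matrix.tsv", tmp_path / "E01_labels.tsv")
    exp = experiments[0]
    assert back.experiment_id == exp.experiment_id
    assert back.genes == exp.genes
    assert (back.labels == exp.labels).all()
    np.testing.assert_allclose(
        back.matrix.to_numpy(), exp.matrix.to_numpy(), atol=1e-6
    )
    truth_back = eio.read_truth(tmp_path / "truth.tsv", truth.universe)
    assert len(truth_back.table) == cfg.n_true
    assert truth_back.true_genes == truth.true_genes


def test_reader_rejects_nan_and_missing_labels(tmp_path):
    cfg = CompendiumConfig.desk(seed=2, n_genes=20)
    experiments, truth = generate_compendium(cfg)
    write_compendium(experiments[:1], truth, tmp_path)
    mpath, lpath = tmp_path / "E01_matrix.tsv", tmp_path / "E01_labels.tsv"
    text = mpath.read_text().splitlines()
    cells = text[1].split("\t")
    cells[1] = "nan"
    text[1] = "\t".join(cells)
    mpath.write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="NaN"):
        eio.read_experiment(mpath, lpath)
    write_compendium(experiments[:1], truth, tmp_path)
    lab = lpath.read_text().splitlines()
    lpath.write_text("\n".join(lab[:-1]) + "\n")  # drop one sample's label
    with pytest.raises(ValueError, match="without labels"):
        eio.read_experiment(mpath, lpath)
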