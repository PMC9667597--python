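"""Training loop behaviour, prediction contracts, file round-trips, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ddiscl import (
    TrainConfig,
    TrainedModel,
    build_similarity_profiles,
    default_network_config,
    predict,
    train,
)
from ddiscl import io as ddio
from ddiscl.cli import main as cli_main
from ddiscl.training import pair_embeddings


def micro_train_cfg(**kw):
    base = dict(learning_rate=1e-3, batch_size=16, epochs=8, switch_epoch=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


def micro_net_cfg(profiles, n_classes, **kw):
    return default_network_config(
        profiles.fea_dim, n_classes, n_feature_types=len(profiles.feature_types),
        seed=0, **kw,
    )


@pytest.fixture(scope="module")
def trained(small_synth, small_profiles):
    cfg, _, dataset, _ = small_synth
    tcfg = micro_train_cfg()
    ncfg = micro_net_cfg(small_profiles, dataset.n_classes)
    model, history = train(small_profiles, dataset.records, tcfg, net_cfg=ncfg)
    return model, history, dataset


def test_history_records_loss_schedule(trained):
    _, history, _ = trained
    assert len(history) == 8
    active = [r.active_cla_loss for r in history.rows]
    assert active == ["cross_entropy"] * 2 + ["focal"] * 6
    assert all(np.isfinite(r.total) for r in history.rows)
    for r in history.rows:
        assert r.total == pytest.approx(r.l_mse + r.l_con + r.l_cla)


def test_training_reduces_losses(trained):
    _, history, _ = trained
    # compare within the focal phase (the loss switch rescales l_cla)
    assert history.rows[-1].l_cla < history.rows[2].l_cla
    assert history.rows[-1].l_mse < history.rows[0].l_mse


def test_scl_ablation_zeroes_contrastive_term(small_synth, small_profiles):
    _, _, dataset, _ = small_synth
    tcfg = micro_train_cfg(use_scl=False, epochs=2)
    ncfg = micro_net_cfg(small_profiles, dataset.n_classes)
    _, history = train(small_profiles, dataset.records, tcfg, net_cfg=ncfg)
    assert all(r.l_con == 0.0 for r in history.rows)


def test_training_reproducible_from_seed(small_synth, small_profiles):
    _, _, dataset, _ = small_synth
    tcfg = micro_train_cfg(epochs=3)
    ncfg = micro_net_cfg(small_profiles, dataset.n_classes)
    _, h1 = train(small_profiles, dataset.records, tcfg, net_cfg=ncfg)
    _, h2 = train(small_profiles, dataset.records, tcfg, net_cfg=ncfg)
    assert h1.rows[-1].total == pytest.approx(h2.rows[-1].total, abs=1e-5)


def test_empty_training_set_rejected(small_profiles):
    with pytest.raises(ValueError):
        train(small_profiles, [], micro_train_cfg())


def test_predict_contracts(trained, small_profiles):
    model, _, dataset = trained
    pairs = [(a, b) for a, b, _ in dataset.records[:10]]
    p1 = predict(model, small_profiles, pairs)
    assert p1.shape == (10, dataset.n_classes)
    assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-5)
    p2 = predict(model, small_profiles, pairs)
    assert np.array_equal(p1, p2)  # bitwise determinism


def test_predict_unknown_drug_lists_offenders(trained, small_profiles):
    model, _, _ = trained
    with pytest.raises(KeyError, match="ghost"):
        predict(model, small_profiles, [("ghost", small_profiles.drug_ids[0])])


def test_symmetrized_prediction_is_order_invariant(small_synth, small_profiles):
    _, _, dataset, _ = small_synth
    tcfg = micro_train_cfg(epochs=2)
    ncfg = micro_net_cfg(small_profiles, dataset.n_classes, symmetrize_pairs=True)
    model, _ = train(small_profiles, dataset.records, tcfg, net_cfg=ncfg)
    a, b, _ = dataset.records[0]
    pab = predict(model, small_profiles, [(a, b)])
    pba = predict(model, small_profiles, [(b, a)])
    assert np.allclose(pab, pba, atol=1e-12)


def test_checkpoint_roundtrip(tmp_path, trained, small_profiles):
    model, _, dataset = trained
    path = tmp_path / "model.npz"
    model.save(path)
    back = TrainedModel.load(path)
    pairs = [(a, b) for a, b, _ in dataset.records[:5]]
    assert np.array_equal(
        predict(model, small_profiles, pairs), predict(back, small_profiles, pairs)
    )
    assert back.feature_types == model.feature_types


def test_pair_embeddings_shape(trained, small_profiles):
    model, _, dataset = trained
    pairs = [(a, b) for a, b, _ in dataset.records[:8]]
    emb = pair_embeddings(model, small_profiles, pairs)
    assert emb.shape == (8, model.net_cfg.cfv_dim)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(switch_epoch=200, epochs=100)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")


# ------------------------------------------------------------------- io
def test_descriptor_csv_roundtrip(tmp_path, tiny_descriptors):
    paths = ddio.write_descriptor_csvs(tiny_descriptors, tmp_path)
    back = ddio.read_descriptor_csvs(paths)
    assert back.drug_ids == tiny_descriptors.drug_ids
    for k in tiny_descriptors.blocks:
        assert np.array_equal(back.blocks[k], tiny_descriptors.blocks[k])


def test_descriptor_nonbinary_cell_cited(tmp_path):
    p = tmp_path / "descriptors_t.csv"
    p.write_text("drug_id,f0,f1\na,0,1\nb,2,0\n")
    with pytest.raises(ddio.FormatError, match="f0"):
        ddio.read_descriptor_csvs({"t": p})


def test_descriptor_missing_type_filled_with_zeros(tmp_path):
    (tmp_path / "descriptors_a.csv").write_text("drug_id,f0\nx,1\ny,0\n")
    (tmp_path / "descriptors_b.csv").write_text("drug_id,g0\nx,1\nz,1\n")
    with pytest.warns(UserWarning):
        d = ddio.read_descriptor_csvs(
            {"a": tmp_path / "descriptors_a.csv", "b": tmp_path / "descriptors_b.csv"}
        )
    assert d.drug_ids == ["x", "y", "z"]
    assert d.blocks["b"][d.drug_ids.index("y")].sum() == 0


def test_long_format_descriptors(tmp_path):
    p = tmp_path / "long.csv"
    p.write_text(
        "drug_id,feature_type,descriptor_id\n"
        "a,sub,s1\na,sub,s2\nb,sub,s2\na,tgt,t1\nb,tgt,t2\n"
    )
    d = ddio.read_descriptors_long(p)
    assert d.drug_ids == ["a", "b"]
    assert d.blocks["sub"].tolist() == [[1, 1], [0, 1]]


def test_ddi_roundtrip_and_label_mapping(tmp_path, small_synth):
    _, _, dataset, _ = small_synth
    path = tmp_path / "ddis.csv"
    ddio.write_ddis(dataset, path)
    back, mapping = ddio.read_ddis(path, drug_universe=dataset.drug_universe)
    assert len(back) == len(dataset)
    assert sorted(mapping.values()) == list(range(len(mapping)))
    mpath = tmp_path / "labels.json"
    ddio.write_label_mapping(mapping, mpath)
    assert ddio.read_label_mapping(mpath) == mapping


def test_ddi_duplicate_conflict_and_self_pair(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("drugA,drugB,label\nd1,d2,t0\nd2,d1,t1\n")
    with pytest.raises(ddio.FormatError, match="conflicting"):
        ddio.read_ddis(p)
    p.write_text("drugA,drugB,label\nd1,d1,t0\n")
    with pytest.raises(ddio.FormatError, match="self-pair"):
        ddio.read_ddis(p)


def test_profile_roundtrip(tmp_path, tiny_descriptors):
    prof = build_similarity_profiles(tiny_descriptors)
    ddio.write_profile(prof, tmp_path / "prof.csv")
    back = ddio.read_profile(tmp_path / "prof.csv")
    assert back.drug_ids == prof.drug_ids
    assert back.feature_types == prof.feature_types
    assert np.allclose(back.matrix, prof.matrix)


def test_run_config_yaml(tmp_path):
    p = tmp_path / "run.yaml"
    p.write_text("training:\n  epochs: 3\n  batch_size: 8\nnetwork:\n  n_heads: 2\n")
    cfg = ddio.load_run_config(p)
    assert cfg["training"]["epochs"] == 3
    assert cfg["network"]["n_heads"] == 2


# ------------------------------------------------------------------- cli
def test_cli_generate_train_predict_roundtrip(tmp_path):
    runner = CliRunner()
    data_dir = tmp_path / "data"
    res = runner.invoke(
        cli_main,
        ["generate", "--preset", "dataset1", "--scale", "0.05",
         "--seed", "0", "--out", str(data_dir)],
    )
    assert res.exit_code == 0, res.output
    assert (data_dir / "ddis.csv").exists()
    assert (data_dir / "ground_truth.json").exists()

    run_yaml = tmp_path / "run.yaml"
    run_yaml.write_text(
        "training:\n  epochs: 2\n  batch_size: 32\n  learning_rate: 1e-3\n"
        "  switch_epoch: 1\n"
    )
    out_dir = tmp_path / "out"
    res = runner.invoke(
        cli_main,
        ["train", "--descriptors", str(data_dir), "--ddis", str(data_dir / "ddis.csv"),
         "--task", "1", "--fold", "0", "--config", str(run_yaml),
         "--seed", "0", "--out", str(out_dir)],
    )
    assert res.exit_code == 0, res.output
    assert (out_dir / "model_task1_fold0.npz").exists()
    hist = pd.read_csv(out_dir / "history_task1_fold0.csv")
    assert list(hist["active_cla_loss"]) == ["cross_entropy", "focal"]
    metrics = json.loads((out_dir / "metrics_task1_fold0.json").read_text())
    assert 0.0 <= metrics["acc"] <= 1.0

    pairs_csv = tmp_path / "pairs.csv"
    ddis = pd.read_csv(data_dir / "ddis.csv")
    ddis.head(5)[["drugA", "drugB"]].to_csv(pairs_csv, index=False)
    res = runner.invoke(
        cli_main,
        ["predict", "--model", str(out_dir / "model_task1_fold0.npz"),
         "--descriptors", str(data_dir), "--pairs", str(pairs_csv),
         "--out", str(tmp_path / "preds.csv")],
    )
    assert res.exit_code == 0, res.output
    preds = pd.read_csv(tmp_path / "preds.csv")
    assert len(preds) == 5
    prob_cols = [c for c in preds.columns if c.startswith("p_class")]
    assert np.allclose(preds[prob_cols].sum(axis=1), 1.0, atol=1e-5)


def test_cli_validation_exit_code(tmp_path):
    runner = CliRunner()
    bad = tmp_path / "ddis.csv"
    bad.write_text("drugA,drugB,label\nd1,d1,t0\n")
    ddir = tmp_path / "d"
    ddir.mkdir()
    (ddir / "descriptors_t.csv").write_text("drug_id,f0\nd1,1\nd2,0\n")
    res = runner.invoke(
        cli_main,
        ["train", "--descriptors", str(ddir), "--ddis", str(bad),
         "--out", str(tmp_path / "o")],
    )
    assert res.exit_code == 2
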