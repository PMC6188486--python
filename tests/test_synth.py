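"""Synthetic-data generator: determinism, calibration and planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cernet import synth
from cernet.cerna import hypergeom_pvalue
from cernet.interactions import load_interactions
from cernet.synth import (
    SynthConfig,
    SynthConfigError,
    SynthConsistencyError,
    generate_counts,
    generate_gene_sets,
    generate_interactions,
)


def test_identical_seed_gives_bit_identical_outputs(tmp_path):
    cfg = SynthConfig(seed=42)
    m1, t1 = generate_counts(cfg)
    m2, t2 = generate_counts(cfg)
    for cls in m1:
        pd.testing.assert_frame_equal(m1[cls].values, m2[cls].values)
    assert t1.de_features == t2.de_features
    assert t1.planted_pairs == t2.planted_pairs
    i1, i2 = generate_interactions(cfg, t1), generate_interactions(cfg, t2)
    pd.testing.assert_frame_equal(i1.records, i2.records)
    p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
    generate_gene_sets(cfg, t1).to_gmt(p1)
    generate_gene_sets(cfg, t2).to_gmt(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_matrix_dimensions_follow_the_config():
    cfg = dataclasses.replace(SynthConfig(), n_mrna=100, n_planted_pairs=0)
    matrices, _ = generate_counts(cfg)
    assert matrices["mRNA"].values.shape == (100, 6)
    assert matrices["miRNA"].values.shape == (30, 6)
    assert matrices["circRNA"].values.shape == (50, 6)
    assert sorted(set(matrices["mRNA"].groups.values())) == ["case", "control"]


def test_invalid_configurations_are_rejected():
    with pytest.raises(SynthConfigError):
        generate_counts(dataclasses.replace(SynthConfig(), n_mrna=0))
    with pytest.raises(SynthConfigError):
        SynthConfig(nb_dispersion=-1).validate()
    with pytest.raises(SynthConfigError):
        SynthConfig(frac_de=1.5).validate()
    with pytest.raises(SynthConfigError):
        SynthConfig(shared_mirnas_per_planted_pair=31).validate()


def test_planted_fold_change_calibration():
    """Across 10,000 planted features the mean empirical |log2 ratio| of group
    means converges to the configured effect of 2."""
    cfg = dataclasses.replace(
        SynthConfig(), n_mrna=20000, frac_de=0.5, n_planted_pairs=0, seed=8
    )
    matrices, truth = generate_counts(cfg)
    mat = matrices["mRNA"]
    case = mat.values[mat.samples("case")].mean(axis=1)
    ctrl = mat.values[mat.samples("control")].mean(axis=1)
    status = pd.Series(truth.de_features["mRNA"])
    assert len(status) == 10000
    ratio = np.log2(case[status.index] + 0.5) - np.log2(ctrl[status.index] + 0.5)
    assert abs(ratio[status == "UP"].mean() - 2.0) < 0.1
    assert abs(ratio[status == "DOWN"].mean() + 2.0) < 0.1


def test_de_direction_split_is_even():
    _, truth = generate_counts(SynthConfig(seed=0))
    for cls in ("mRNA", "miRNA", "circRNA"):
        statuses = list(truth.de_features[cls].values())
        assert abs(statuses.count("UP") - statuses.count("DOWN")) <= 1


def test_planted_pairs_share_exactly_the_configured_mirnas():
    cfg = SynthConfig(seed=13)
    _, truth = generate_counts(cfg)
    iset = generate_interactions(cfg, truth)
    df = iset.records
    partners = df.groupby("target_id")["mirna_id"].agg(set)
    for pair in truth.planted_pairs:
        shared = partners[pair.circ_id] & partners[pair.mrna_id]
        assert shared == set(pair.shared_mirnas)
        assert len(shared) == cfg.shared_mirnas_per_planted_pair


def test_zero_background_probability_isolates_planted_sharing():
    # with a single planted pair and no background, the only sharing in the
    # whole table is the planted one
    cfg = dataclasses.replace(
        SynthConfig(),
        background_share_prob=0.0,
        decoy_frac=0.0,
        n_planted_pairs=1,
        seed=2,
    )
    _, truth = generate_counts(cfg)
    df = generate_interactions(cfg, truth).records
    partners = df.groupby("target_id")["mirna_id"].agg(set)
    (pair,) = truth.planted_pairs
    assert set(partners.index) == {pair.circ_id, pair.mrna_id}
    assert partners[pair.circ_id] == partners[pair.mrna_id] == set(pair.shared_mirnas)
    # and with no pairs at all the table is empty
    cfg0 = dataclasses.replace(cfg, n_planted_pairs=0, seed=3)
    _, truth0 = generate_counts(cfg0)
    assert len(generate_interactions(cfg0, truth0)) == 0


def test_planted_pairs_score_better_than_random_pairs():
    cfg = SynthConfig(seed=21)
    _, truth = generate_counts(cfg)
    df = generate_interactions(cfg, truth).records
    partners = df.groupby("target_id")["mirna_id"].agg(set)
    m = df["mirna_id"].nunique()

    def pair_p(c, g):
        cn = partners.get(c, set())
        gn = partners.get(g, set())
        return hypergeom_pvalue(m, len(gn), len(cn), len(cn & gn))

    planted_p = [pair_p(p.circ_id, p.mrna_id) for p in truth.planted_pairs]
    rng = np.random.default_rng(0)
    planted_keys = {(p.circ_id, p.mrna_id) for p in truth.planted_pairs}
    random_p = []
    while len(random_p) < 100:
        c = f"CIRC-{int(rng.integers(1, cfg.n_circ + 1)):05d}"
        g = f"MRNA-{int(rng.integers(1, cfg.n_mrna + 1)):05d}"
        if (c, g) not in planted_keys:
            random_p.append(pair_p(c, g))
    assert np.median(planted_p) < np.median(random_p)


def test_energies_pass_filter_and_decoys_do_not(tmp_path):
    cfg = SynthConfig(seed=4)
    _, truth = generate_counts(cfg)
    iset = generate_interactions(cfg, truth)
    energies = iset.records["energy_kcal_mol"]
    n_decoys = int((energies > -20).sum())
    assert n_decoys > 0  # the filter has something to remove
    path = tmp_path / "inter.tsv"
    iset.to_tsv(path)
    filtered = load_interactions(path)
    assert len(filtered) == len(iset) - n_decoys
    assert (filtered.records["energy_kcal_mol"] <= -20).all()


def test_truth_and_config_must_match():
    cfg = SynthConfig(seed=5)
    _, truth = generate_counts(cfg)
    other = dataclasses.replace(cfg, seed=6)
    with pytest.raises(SynthConsistencyError):
        generate_interactions(other, truth)
    with pytest.raises(SynthConsistencyError):
        generate_gene_sets(other, truth)


def test_gene_sets_require_planted_de_mrnas():
    cfg = dataclasses.replace(SynthConfig(), frac_de=0.0, n_planted_pairs=0, seed=1)
    _, truth = generate_counts(cfg)
    with pytest.raises(SynthConsistencyError, match="planted term impossible"):
        generate_gene_sets(cfg, truth)


def test_truth_round_trips_through_json(tmp_path):
    cfg = SynthConfig(seed=9)
    _, truth = generate_counts(cfg)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    loaded = synth.GroundTruth.from_json(path)
    assert loaded.de_features == truth.de_features
    assert loaded.planted_pairs == truth.planted_pairs
    assert loaded.hub_circ == truth.hub_circ


def test_planted_pairs_reference_only_de_features():
    _, truth = generate_counts(SynthConfig(seed=17))
    de_c, de_g = truth.de_ids("circRNA"), truth.de_ids("mRNA")
    de_m = truth.de_ids("miRNA")
    for p in truth.planted_pairs:
        assert p.circ_id in de_c and p.mrna_id in de_g
        assert set(p.shared_mirnas) <= de_m
    assert truth.hub_circ == truth.planted_pairs[0].circ_id
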