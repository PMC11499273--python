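"""Structural features: distances, contacts, the 12-feature regression."""

import numpy as np
import pandas as pd
import pytest

from foldspace.simulate import synthetic_pair_features
from foldspace.structure import (
    FEATURE_COLUMNS,
    CouplingStrengthModel,
    build_pair_features,
    contact_map,
    coupling_distance_stats,
    evaluate_coupling_model,
    fit_coupling_strength_model,
    load_structure,
    min_sidechain_distance,
    read_annotations,
    read_contacts,
)


class TestMinSidechainDistance:
    def test_self_distance_is_zero(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        assert min_sidechain_distance(chain, 1, 1) == 0.0

    def test_three_four_five_triangle(self, toy_structure):
        # ALA CB at origin, SER CB at (3,4,0)
        path, _ = toy_structure
        chain = load_structure(path)
        assert min_sidechain_distance(chain, 1, 2) == pytest.approx(5.0)

    def test_symmetry(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        assert min_sidechain_distance(chain, 1, 2) == pytest.approx(
            min_sidechain_distance(chain, 2, 1))

    def test_brute_force_over_all_atom_pairs(self, toy_structure):
        """Exhaustive enumeration oracle from the fixture coordinates."""
        path, coords = toy_structure
        chain = load_structure(path)
        backbone = {"N", "CA", "C", "O", "OXT"}
        side = {r: [np.array(xyz) for name, _, xyz in atoms
                    if name not in backbone]
                for r, atoms in coords.items()}
        expected = min(np.linalg.norm(a - b)
                       for a in side[1] for b in side[2])
        assert min_sidechain_distance(chain, 1, 2) == pytest.approx(
            expected, abs=1e-9)

    def test_glycine_falls_back_to_ca(self, toy_structure):
        path, coords = toy_structure
        chain = load_structure(path)
        # GLY 3 has no side chain: distance measured from its CA (0,0,10)
        assert min_sidechain_distance(chain, 1, 3) == pytest.approx(10.0)

    def test_missing_residue_raises(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        with pytest.raises(KeyError):
            min_sidechain_distance(chain, 1, 99)

    def test_offset_map_translates_positions(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        d = min_sidechain_distance(chain, 101, 102,
                                   offset_map={101: 1, 102: 2})
        assert d == pytest.approx(5.0)


class TestContactMap:
    def test_toy_structure_contacts(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        contacts, long_range = contact_map(chain, [1, 2, 3], threshold=8.0)
        assert contacts[0, 1] and contacts[1, 0]       # 5.0 A < 8
        assert not contacts[0, 2]                      # 10.0 A
        assert not contacts.diagonal().any()
        assert (contacts == contacts.T).all()

    def test_distant_chain_is_empty(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        contacts, _ = contact_map(chain, [1, 3], threshold=8.0)
        assert not contacts.any()

    def test_long_range_mask_uses_backbone_cutoff(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        _, long_range = contact_map(chain, [1, 2, 3], long_range_cutoff=1)
        assert not long_range[0, 1]   # |1-2| = 1
        assert long_range[0, 2]       # |1-3| = 2 > 1


class TestContactsFile:
    def _write(self, tmp_path, lines):
        path = tmp_path / "contacts.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_counts_accumulate_per_listed_row(self, tmp_path):
        path = self._write(tmp_path, [
            "0\tsb\tA:LYS:10:NZ\tA:ASP:20:OD1",
            "0\tsb\tA:LYS:10:NZ\tA:ASP:20:OD2",
            "0\tvdw\tA:LYS:10:CB\tA:ASP:20:CB",
        ])
        df = read_contacts(path)
        row = df[(df.pos_i == 10) & (df.pos_j == 20)].iloc[0]
        assert row["salt_bridge"] == 2
        assert row["vdw"] == 1
        assert row["hbond_bb_bb"] == 0

    def test_unknown_labels_warn_and_are_ignored(self, tmp_path):
        path = self._write(tmp_path, [
            "0\twhatever\tA:LYS:10:NZ\tA:ASP:20:OD1",
            "0\thbss\tA:SER:11:OG\tA:THR:21:OG1",
        ])
        with pytest.warns(UserWarning, match="whatever"):
            df = read_contacts(path)
        assert len(df) == 1


class TestBuildPairFeatures:
    def _annotations(self):
        return pd.DataFrame({
            "position": [1, 2, 3],
            "rsasa": [0.6, 0.1, 0.4],
            "ss": ["loop", "strand", "strand"],
            "ligand_distance": [12.0, 3.0, 7.0],
        }).set_index("position", drop=False)

    def test_full_fixture_against_hand_assembly(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        couplings = pd.DataFrame({"pos_i": [1, 1], "pos_j": [2, 3],
                                  "strength": [0.4, 0.1]})
        contacts = pd.DataFrame([{"pos_i": 1, "pos_j": 2, "hbond_bb_bb": 0,
                                  "hbond_sb": 0, "hbond_ss": 1, "pi_cation": 0,
                                  "pi_stacking": 0, "salt_bridge": 0, "vdw": 3}])
        feats = build_pair_features(couplings, self._annotations(), chain=chain,
                                    contacts=contacts)
        assert list(feats.columns[2:-1]) == FEATURE_COLUMNS
        r12 = feats.iloc[0]
        assert r12["backbone_distance"] == 1
        assert r12["scha_distance"] == pytest.approx(5.0)
        assert r12["n_core"] == 1          # residue 2 has RSASA 0.1 < 0.25
        assert r12["n_interface"] == 1     # residue 2 at 3 A < 5
        assert r12["n_strand"] == 1
        assert r12["hbond_ss"] == 1 and r12["vdw"] == 3
        r13 = feats.iloc[1]
        assert r13["backbone_distance"] == 2
        assert (r13[list(FEATURE_COLUMNS[5:])] == 0).all()  # no contacts listed

    def test_pair_order_independent(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        a = build_pair_features(pd.DataFrame({"pos_i": [1], "pos_j": [2],
                                              "strength": [0.4]}),
                                self._annotations(), chain=chain)
        b = build_pair_features(pd.DataFrame({"pos_i": [2], "pos_j": [1],
                                              "strength": [0.4]}),
                                self._annotations(), chain=chain)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_annotation_raises(self, toy_structure):
        path, _ = toy_structure
        chain = load_structure(path)
        with pytest.raises(ValueError, match="annotation"):
            build_pair_features(pd.DataFrame({"pos_i": [1], "pos_j": [9],
                                              "strength": [0.1]}),
                                self._annotations(), chain=chain)


class TestAnnotationsIO:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "ann.tsv"
        pd.DataFrame({"position": [1], "rsasa": [0.5], "ss": ["loop"],
                      "ligand_distance": [4.0]}).to_csv(path, sep="\t", index=False)
        df = read_annotations(path)
        assert df.loc[1, "rsasa"] == 0.5

    def test_invalid_rsasa_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        pd.DataFrame({"position": [1], "rsasa": [1.5], "ss": ["loop"],
                      "ligand_distance": [4.0]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_annotations(path)


class TestCouplingStrengthModel:
    def test_sign_recovery_and_training_fit(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(0.0, 0.05, 12)
        train, _ = synthetic_pair_features(200, seed=1, beta=beta)
        model = fit_coupling_strength_model(train)
        big = np.abs(beta) > 0.02
        assert (np.sign(model.coef_.to_numpy()[big]) == np.sign(beta[big])).all()
        r = np.corrcoef(model.predict(train), train["strength"])[0, 1]
        assert r > 0.95

    def test_standardization_makes_fit_scale_invariant(self):
        beta = np.full(12, 0.03)
        train, _ = synthetic_pair_features(150, seed=2, beta=beta)
        rescaled = train.copy()
        rescaled["scha_distance"] = rescaled["scha_distance"] * 100.0  # m -> cm
        m1 = fit_coupling_strength_model(train)
        m2 = fit_coupling_strength_model(rescaled)
        np.testing.assert_allclose(m1.coef_.to_numpy(), m2.coef_.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(m1.predict(train), m2.predict(rescaled),
                                   atol=1e-8)

    def test_too_few_pairs_rejected(self):
        train, _ = synthetic_pair_features(10, seed=1)
        with pytest.raises(ValueError, match="20"):
            fit_coupling_strength_model(train)

    def test_collinear_features_reported(self):
        train, _ = synthetic_pair_features(100, seed=1)
        train["n_core"] = train["n_interface"]  # exact collinearity
        with pytest.raises(ValueError, match="n_core|n_interface"):
            fit_coupling_strength_model(train)

    def test_permuting_rows_leaves_fit_invariant(self):
        beta = np.full(12, 0.03)
        train, _ = synthetic_pair_features(100, seed=5, beta=beta)
        m1 = fit_coupling_strength_model(train)
        m2 = fit_coupling_strength_model(
            train.sample(frac=1.0, random_state=0).reset_index(drop=True))
        np.testing.assert_allclose(m1.coef_.to_numpy(), m2.coef_.to_numpy(),
                                   atol=1e-10)


class TestEvaluateCouplingModel:
    def test_overlapping_test_set_rejected(self):
        train, _ = synthetic_pair_features(50, seed=1)
        model = fit_coupling_strength_model(train)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_coupling_model(model, train)

    def test_perfect_model_scores_one(self):
        beta = np.full(12, 0.05)
        train, _ = synthetic_pair_features(200, seed=1, beta=beta, noise_sd=1e-9)
        test, _ = synthetic_pair_features(100, seed=2, beta=beta, noise_sd=1e-9)
        test["pos_i"] += 100_000  # force disjoint pair ids
        model = fit_coupling_strength_model(train)
        out = evaluate_coupling_model(model, test)
        assert out["pearson_r"] == pytest.approx(1.0, abs=1e-5)
        assert out["r2"] == pytest.approx(1.0, abs=1e-5)

    def test_r2_tracks_noise_fraction(self):
        beta = np.full(12, 0.05)
        signal_sd = np.sqrt((beta ** 2).sum())
        noise = 0.5 * signal_sd
        train, _ = synthetic_pair_features(400, seed=3, beta=beta, noise_sd=noise)
        test, _ = synthetic_pair_features(400, seed=4, beta=beta, noise_sd=noise)
        test["pos_i"] += 100_000
        model = fit_coupling_strength_model(train)
        out = evaluate_coupling_model(model, test)
        expected = 1.0 - noise ** 2 / (signal_sd ** 2 + noise ** 2)
        assert out["r2"] == pytest.approx(expected, abs=0.1)


class TestCouplingDistanceStats:
    def test_strictly_decreasing_gives_rho_minus_one(self):
        d = np.linspace(2, 20, 30)
        s = 1.0 / d
        out = coupling_distance_stats(s, d, np.arange(30) + 1.0)
        assert out["rho_scha_all"] == pytest.approx(-1.0)

    def test_independent_strengths_give_near_zero_rho(self):
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(200):
            d = rng.uniform(2, 20, 60)
            s = rng.uniform(0, 1, 60)
            rhos.append(coupling_distance_stats(s, d, rng.uniform(1, 50, 60))
                        ["rho_scha_all"])
        assert abs(np.mean(rhos)) < 0.03

    def test_restriction_masks_match_hand_filtering(self):
        from scipy.stats import spearmanr
        d3 = np.array([3.0, 4.0, 6.0, 10.0, 12.0, 2.5])
        bb = np.array([2.0, 7.0, 3.0, 9.0, 1.0, 30.0])
        s = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.6])
        out = coupling_distance_stats(s, d3, bb)
        mask = bb > 5
        assert out["rho_scha_backbone_distal"] == pytest.approx(
            spearmanr(s[mask], d3[mask]).statistic)
        mask2 = d3 >= 5.0
        assert out["rho_backbone_no_contacts"] == pytest.approx(
            spearmanr(s[mask2], bb[mask2]).statistic)

    def test_mc_replicates_give_percentile_bands(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(2, 20, 50)
        s = 1.0 / d
        mc = s[None, :] + rng.normal(0, 0.01, (10, 50))
        out = coupling_distance_stats(s, d, rng.uniform(1, 50, 50),
                                      mc_strengths=mc)
        assert {"ci95_lo", "ci95_hi"} <= set(out["binned"].columns)
        assert (out["binned"]["ci95_lo"] <= out["binned"]["ci95_hi"]).all()

    def test_too_few_pairs_after_restriction(self):
        with pytest.raises(ValueError):
            coupling_distance_stats(np.ones(2), np.ones(2), np.ones(2))
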