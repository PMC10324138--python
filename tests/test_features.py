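import itertools

import numpy as np
import pandas as pd
import pytest

from pcmlab.chem import BioactivityDataset, LigandDescriptorBlock
from pcmlab.features import (
    FeatureMatrix,
    build_pair_matrix,
    fit_center_scale,
    impute_features,
    pca_scores,
    remove_highly_correlated,
    remove_near_zero_variance,
    stratified_split,
)


def _matrix(df: pd.DataFrame, state="imputed") -> FeatureMatrix:
    index = pd.MultiIndex.from_tuples(
        [(f"c{i}", "t") for i in range(len(df))], names=["compound_id", "target_id"]
    )
    values = df.copy()
    values.index = index
    prov = pd.Series("ligand-physchem", index=values.columns)
    return FeatureMatrix(values=values, provenance=prov, preprocessing_state=state)


class TestBuildPairMatrix:
    def _blocks(self):
        lig = LigandDescriptorBlock(
            matrix=pd.DataFrame(
                {"fp_0": [1, 2], "logp": [0.5, 1.5]}, index=["c1", "c2"]
            ),
            provenance=pd.Series(
                ["fingerprint", "physchem"], index=["fp_0", "logp"]
            ),
        )
        prot = (
            pd.DataFrame({"Z1_Aa1": [0.24, 2.05]}, index=["tA", "tB"]),
            pd.Series("protein-zscale", index=["Z1_Aa1"]),
        )
        return lig, prot

    def test_one_compound_two_targets(self):
        lig, prot = self._blocks()
        ds = BioactivityDataset(
            pairs=pd.DataFrame(
                {
                    "compound_id": ["c1", "c1"],
                    "target_id": ["tA", "tB"],
                    "pic50": [6.0, 7.0],
                }
            )
        )
        fm = build_pair_matrix(ds, lig, prot)
        assert fm.n_rows == 2
        # rows differ only in the protein block
        assert (fm.values.iloc[0, :2] == fm.values.iloc[1, :2]).all()
        assert fm.values.iloc[0, 2] != fm.values.iloc[1, 2]

    def test_ligand_columns_precede_protein(self):
        lig, prot = self._blocks()
        ds = BioactivityDataset(
            pairs=pd.DataFrame(
                {"compound_id": ["c1"], "target_id": ["tA"], "pic50": [6.0]}
            )
        )
        fm = build_pair_matrix(ds, lig, prot)
        assert list(fm.values.columns) == ["fp_0", "logp", "Z1_Aa1"]
        assert list(fm.provenance) == [
            "ligand-fingerprint", "ligand-physchem", "protein-zscale",
        ]

    def test_missing_descriptors_listed(self):
        lig, prot = self._blocks()
        ds = BioactivityDataset(
            pairs=pd.DataFrame(
                {"compound_id": ["c9"], "target_id": ["tA"], "pic50": [6.0]}
            )
        )
        with pytest.raises(KeyError, match="c9"):
            build_pair_matrix(ds, lig, prot)

    def test_counts_compose_1241_plus_440(self, small_study):
        # 512 fingerprints + a 729-column provider + an 88-residue site block
        from pcmlab import chem
        from pcmlab.protein import zscale_block

        compounds = small_study["compounds"]
        fp = chem.morgan_fingerprint_block(compounds)

        def wide_provider(mol):
            return {f"pd_{i}": float(mol.GetNumAtoms() + i) for i in range(729)}

        pc, _ = chem.physchem_descriptors(compounds, provider=wide_provider)
        lig = chem.LigandDescriptorBlock.concat([fp, pc])
        assert len(lig.names) == 1241
        prot = zscale_block(list(small_study["sites"]))
        fm = build_pair_matrix(small_study["dataset"], lig, prot)
        assert fm.n_columns == 1241 + 440


class TestImpute:
    def test_mean_fill(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, np.nan, 3.0]}), state="raw")
        out, all_na = impute_features(fm)
        assert out.values["a"].tolist() == [1.0, 2.0, 3.0]
        assert all_na == []

    def test_identity_when_complete(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, 2.0]}), state="raw")
        out, _ = impute_features(fm)
        pd.testing.assert_frame_equal(out.values, fm.values)

    def test_inf_treated_as_missing(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, np.inf, 3.0]}), state="raw")
        out, _ = impute_features(fm)
        assert out.values["a"].tolist() == [1.0, 2.0, 3.0]

    def test_all_na_column_filled_zero_and_reported(self):
        fm = _matrix(pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]}), state="raw")
        out, all_na = impute_features(fm)
        assert all_na == ["a"]
        assert out.values["a"].tolist() == [0.0, 0.0]


class TestNearZeroVariance:
    def test_constant_column_removed(self):
        fm = _matrix(pd.DataFrame({"c": [1.0] * 5, "x": np.arange(5.0)}))
        out, removed = remove_near_zero_variance(fm)
        assert removed == ["c"]

    def test_ratio_boundary(self):
        col31 = [0.0] * 31 + [1.0]
        col30 = [0.0] * 30 + [1.0, np.pi]  # ratio 30/1, plus a third value
        n = len(col31)
        fm = _matrix(
            pd.DataFrame({"r31": col31, "r30": col30[:n], "x": np.arange(float(n))})
        )
        out, removed = remove_near_zero_variance(fm)
        assert "r31" in removed  # 31/1 > 30 -> removed
        assert "r30" not in removed  # 30/1 is not > 30 -> kept


class TestCorrelationFilter:
    @staticmethod
    def brute_force_rule(df: pd.DataFrame, cutoff: float) -> list[str]:
        """Independent exhaustive application of the stated removal rule."""
        cols = list(df.columns)
        removed = []
        while True:
            corr = df[cols].corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            pairs = [
                (corr.loc[a, b], a, b)
                for a, b in itertools.combinations(cols, 2)
            ]
            worst = max(pairs, key=lambda t: t[0], default=None)
            if worst is None or worst[0] < cutoff:
                return removed
            _, a, b = worst
            mean_a = corr.loc[a, cols].sum() / (len(cols) - 1)
            mean_b = corr.loc[b, cols].sum() / (len(cols) - 1)
            drop = a if mean_a >= mean_b else b
            cols.remove(drop)
            removed.append(drop)

    def test_duplicated_column_one_removed(self):
        x = np.arange(10.0)
        fm = _matrix(pd.DataFrame({"a": x, "b": x, "c": np.cos(x)}))
        out, removed = remove_highly_correlated(fm)
        assert len(removed) == 1 and removed[0] in {"a", "b"}
        assert "c" in out.values.columns

    def test_independent_columns_untouched(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 8)), columns=list("abcdefgh"))
        fm = _matrix(df)
        out, removed = remove_highly_correlated(fm)
        assert removed == []

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(60)
        df = pd.DataFrame(
            {
                "A": x,
                "B": x + 0.05 * rng.standard_normal(60),  # r ~ 0.999 with A
                "C": rng.standard_normal(60),
                "D": x + 0.2 * rng.standard_normal(60),
                "E": rng.standard_normal(60),
            }
        )
        out, removed = remove_highly_correlated(_matrix(df), cutoff=0.95)
        assert removed == self.brute_force_rule(df, 0.95)
        # no remaining pair at or above the cutoff
        corr = out.values.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        assert (corr.values < 0.95).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((40, 3))
        df = pd.DataFrame(
            np.column_stack([base, base[:, 0] + 0.1 * rng.standard_normal(40),
                             base[:, 1] * 0.98 + 0.05 * rng.standard_normal(40)]),
            columns=list("vwxyz"),
        )
        _, removed = remove_highly_correlated(_matrix(df), cutoff=0.9)
        assert removed == self.brute_force_rule(df, 0.9)


class TestCenterScale:
    def test_training_column_minus1_0_1(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), state="filtered")
        scaler = fit_center_scale(fm, list(fm.values.index))
        out = scaler.transform(fm)
        np.testing.assert_allclose(out.values["a"], [-1.0, 0.0, 1.0])

    def test_test_value_at_training_mean_maps_to_zero(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, 2.0, 3.0, 2.0]}), state="filtered")
        train = list(fm.values.index[:3])
        scaler = fit_center_scale(fm, train)
        out = scaler.transform(fm)
        assert out.values["a"].iloc[3] == pytest.approx(0.0, abs=1e-12)

    def test_train_rows_standardized(self, rng):
        fm = _matrix(
            pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd")),
            state="filtered",
        )
        train = list(fm.values.index)
        out = fit_center_scale(fm, train).transform(fm)
        assert (out.values.mean().abs() < 1e-9).all()
        assert ((out.values.std(ddof=1) - 1).abs() < 1e-9).all()

    def test_zero_sd_column_raises(self):
        fm = _matrix(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), state="filtered")
        with pytest.raises(ValueError, match="zero-SD"):
            fit_center_scale(fm, list(fm.values.index))


class TestStratifiedSplit:
    def test_312_yields_218_94(self, rng):
        y = pd.Series(rng.normal(7, 1, size=312))
        split = stratified_split(y, ratio=0.7, seed=1)
        assert len(split.train_keys) == 218
        assert len(split.test_keys) == 94

    def test_small_n_rounding(self, rng):
        y = pd.Series(rng.normal(size=10))
        split = stratified_split(y, ratio=0.7, seed=2)
        assert len(split.train_keys) == 7

    def test_per_bin_fraction_within_one_row(self, rng):
        y = pd.Series(rng.normal(size=80))
        split = stratified_split(y, ratio=0.7, n_bins=4, seed=3)
        edges = split.bins
        bin_ids = np.clip(
            np.searchsorted(edges[1:-1], y.to_numpy(), side="right"), 0, 3
        )
        for b in np.unique(bin_ids):
            members = y.index[bin_ids == b]
            n_train = sum(split.labels[m] == "train" for m in members)
            assert abs(n_train - 0.7 * len(members)) <= 1.0

    def test_reproducible(self, rng):
        y = pd.Series(rng.normal(size=50))
        a = stratified_split(y, seed=9)
        b = stratified_split(y, seed=9)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestPCA:
    def test_variance_fractions_sum_to_one_over_all_components(self, rng):
        df = pd.DataFrame(rng.standard_normal((30, 4)))
        _, evr = pca_scores(_matrix(df, state="scaled"), n_components=4)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(evr) <= 1e-12).all()

    def test_rank_one_data(self):
        v = np.arange(6.0)
        df = pd.DataFrame({"a": v, "b": 2 * v, "c": -v})
        scores, evr = pca_scores(_matrix(df, state="scaled"), n_components=1)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="rank"):
            pca_scores(_matrix(df, state="scaled"), n_components=2)

    def test_separated_clusters_split_on_pc1(self, rng):
        a = rng.normal(0, 0.1, size=(20, 3))
        b = rng.normal(10, 0.1, size=(20, 3))
        df = pd.DataFrame(np.vstack([a, b]))
        scores, _ = pca_scores(_matrix(df, state="scaled"), n_components=2)
        signs = np.sign(scores["PC1"].to_numpy())
        assert len(set(signs[:20])) == 1
        assert len(set(signs[20:])) == 1
        assert signs[0] != signs[-1]
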