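"""Clade framework, bijective-map enumeration, distance averaging, testing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pitcherchem import phylo_concordance as pc
from pitcherchem import synthetic_data as sd
from pitcherchem.peak_tables import QUALITATIVE, QUANTITATIVE

from conftest import make_table


def write_framework(tmp_path, newick, clade_rows, map_rows):
    tree = tmp_path / "tree.nwk"
    tree.write_text(newick + "\n")
    clades = tmp_path / "clades.tsv"
    clades.write_text(
        "tip_id\tclade_name\n" + "".join(f"{t}\t{c}\n" for t, c in clade_rows)
    )
    mapping = tmp_path / "map.tsv"
    mapping.write_text(
        "sample_id\ttip_id\n" + "".join(f"{s}\t{t}\n" for s, t in map_rows)
    )
    return tree, clades, mapping


@pytest.fixture
def four_tip_fw(tmp_path):
    files = write_framework(
        tmp_path,
        "((T1:1,T2:1):1,(T3:1,T4:1):1);",
        [("T1", "X"), ("T2", "X"), ("T3", "Y"), ("T4", "Y")],
        [("S1", "T1"), ("S2", "T2"), ("S3", "T3"), ("S4", "T4")],
    )
    return pc.read_clade_framework(*files)


class TestReadCladeFramework:
    def test_one_to_one_framework(self, four_tip_fw):
        assert four_tip_fw.tip_order == ["T1", "T2", "T3", "T4"]
        assert len(pc.enumerate_bijective_maps(four_tip_fw)) == 1

    def test_clade_file_with_unknown_tip(self, tmp_path):
        files = write_framework(
            tmp_path,
            "(T1:1,T2:1);",
            [("T1", "X"), ("T9", "X")],
            [("S1", "T1")],
        )
        with pytest.raises(ValueError, match="T9"):
            pc.read_clade_framework(*files)

    def test_tip_missing_from_clade_table(self, tmp_path):
        files = write_framework(
            tmp_path, "(T1:1,T2:1);", [("T1", "X")], [("S1", "T1")]
        )
        with pytest.raises(ValueError, match="T2"):
            pc.read_clade_framework(*files)

    def test_many_to_many_accepted(self, tmp_path):
        # candidate groups of sizes 3, 3, 2 over three tips plus
        # one-to-one rows for the rest
        newick = "(" + ",".join(f"T{i}:1" for i in range(1, 6)) + ");"
        clade_rows = [(f"T{i}", "X") for i in range(1, 6)]
        map_rows = (
            [(f"G1S{k}", "T1") for k in range(3)]
            + [(f"G2S{k}", "T2") for k in range(3)]
            + [(f"G3S{k}", "T3") for k in range(2)]
            + [("S4", "T4"), ("S5", "T5")]
        )
        fw = pc.read_clade_framework(*write_framework(tmp_path, newick,
                                                      clade_rows, map_rows))
        assert len(pc.enumerate_bijective_maps(fw)) == 3 * 3 * 2


def permanent(matrix):
    """Brute-force permanent of a 0/1 candidate matrix (oracle)."""
    n = matrix.shape[0]
    total = 0
    for perm in itertools.permutations(range(matrix.shape[1]), n):
        total += int(all(matrix[i, perm[i]] for i in range(n)))
    return total


class TestEnumerateBijectiveMaps:
    def test_disjoint_groups_product_rule(self, tmp_path):
        fw, _ = sd.simulate_clade_framework(seed=0)
        maps = pc.enumerate_bijective_maps(fw)
        assert len(maps) == 18  # groups {3, 3, 2}

    def test_shared_candidates_injective_only(self, tmp_path):
        files = write_framework(
            tmp_path,
            "(T1:1,T2:1);",
            [("T1", "X"), ("T2", "X")],
            [("S1", "T1"), ("S2", "T1"), ("S1", "T2"), ("S2", "T2")],
        )
        fw = pc.read_clade_framework(*files)
        maps = pc.enumerate_bijective_maps(fw)
        assert len(maps) == 2  # not 4: assignments must be injective
        assert all(len(set(m.values())) == 2 for m in maps)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_equals_permanent(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n_tips, n_samples = 5, 7
        cand = (rng.random((n_tips, n_samples)) < 0.45).astype(int)
        cand[np.arange(n_tips), rng.integers(0, n_samples, n_tips)] = 1
        newick = "(" + ",".join(f"T{i}:1" for i in range(n_tips)) + ");"
        clade_rows = [(f"T{i}", "X") for i in range(n_tips)]
        map_rows = [
            (f"S{j}", f"T{i}")
            for i in range(n_tips)
            for j in range(n_samples)
            if cand[i, j]
        ]
        fw = pc.read_clade_framework(*write_framework(tmp_path, newick,
                                                      clade_rows, map_rows))
        try:
            count = len(pc.enumerate_bijective_maps(fw))
        except ValueError:
            count = 0
        assert count == permanent(cand)

    def test_zero_candidate_tip_errors(self, tmp_path):
        files = write_framework(
            tmp_path, "(T1:1,T2:1);",
            [("T1", "X"), ("T2", "X")], [("S1", "T1")],
        )
        fw = pc.read_clade_framework(*files)
        fw.sample_map["T2"] = []
        with pytest.raises(ValueError, match="no candidate"):
            pc.enumerate_bijective_maps(fw)

    def test_cap_enforced(self):
        fw, _ = sd.simulate_clade_framework(seed=0)
        with pytest.raises(ValueError, match="reduce the mapping"):
            pc.enumerate_bijective_maps(fw, cap=5)


class TestSpeciesLevelDistances:
    def test_binary_hamming_counts(self):
        table = make_table([[1, 0, 1], [1, 1, 0], [0, 0, 0]], QUALITATIVE)
        sld = pc.species_level_distances(table, ["C1", "C2", "C3"], "hamming")
        assert sld.to_numpy().tolist() == [[0, 2, 2], [2, 0, 2], [2, 2, 0]]

    def test_single_feature_restriction(self):
        table = make_table([[1, 0], [1, 1], [0, 1]], QUALITATIVE)
        sld = pc.species_level_distances(table, ["C1"], "hamming")
        assert sld.loc["S1", "S2"] == 0 and sld.loc["S1", "S3"] == 1

    def test_euclidean_345(self):
        table = make_table([[30.0, 40.0, 30.0], [0.0, 0.0, 0.0]], QUANTITATIVE)
        sld = pc.species_level_distances(table, ["C1", "C2"], "euclidean")
        assert sld.loc["S1", "S2"] == pytest.approx(50.0)

    def test_unknown_feature_errors(self, binary_table):
        with pytest.raises(ValueError, match="unknown feature"):
            pc.species_level_distances(binary_table, ["nope"], "hamming")


class TestCladeDistances:
    def _sld(self, mat, labels):
        return pd.DataFrame(np.array(mat, dtype=float), index=labels,
                            columns=labels)

    def test_wcd_pair_and_triple(self):
        sld = self._sld([[0, 7], [7, 0]], ["a", "b"])
        assert pc.within_clade_distance(sld, ["a", "b"]) == 7
        sld3 = self._sld([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ["a", "b", "c"])
        assert pc.within_clade_distance(sld3, ["a", "b", "c"]) == 2

    def test_singleton_wcd_undefined(self):
        sld = self._sld([[0, 1], [1, 0]], ["a", "b"])
        assert np.isnan(pc.within_clade_distance(sld, ["a"]))
        with pytest.raises(ValueError):
            pc.within_clade_distance(sld, [])

    def test_bcd_examples(self):
        sld = self._sld([[0, 5], [5, 0]], ["a", "b"])
        assert pc.between_clade_distance(sld, ["a"], ["b"]) == 5
        sld4 = self._sld(
            [[0, 0, 1, 2], [0, 0, 3, 4], [1, 3, 0, 0], [2, 4, 0, 0]],
            ["a", "b", "c", "d"],
        )
        assert pc.between_clade_distance(sld4, ["a", "b"], ["c", "d"]) == 2.5

    def test_bcd_duplicated_profiles_zero(self):
        sld = self._sld([[0, 0], [0, 0]], ["a", "b"])
        assert pc.between_clade_distance(sld, ["a"], ["b"]) == 0

    def test_bcd_overlap_errors(self):
        sld = self._sld([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            pc.between_clade_distance(sld, ["a"], ["a", "b"])


def enumeration_pvalue(x, y):
    """Exact one-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:nx].sum()
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if ranks[list(idx)].sum() <= w_obs:
            count += 1
    return count / total


class TestWilcoxonLess:
    def test_exact_small_example(self):
        assert pc.wilcoxon_less([1, 2], [3, 4]) == pytest.approx(1 / 6)

    def test_single_pair(self):
        assert pc.wilcoxon_less([1], [2]) == pytest.approx(0.5)

    def test_identical_samples_not_significant(self):
        assert pc.wilcoxon_less([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_nan_removed(self):
        assert pc.wilcoxon_less([1, np.nan, 2], [3, 4]) == pytest.approx(1 / 6)

    def test_all_nan_errors(self):
        with pytest.raises(ValueError):
            pc.wilcoxon_less([np.nan], [1.0])

    @pytest.mark.parametrize("nx,ny", [(1, 3), (2, 2), (3, 4), (2, 5)])
    def test_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        vals = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
        x, y = vals[:nx], vals[nx:]
        assert pc.wilcoxon_less(x, y) == pytest.approx(enumeration_pvalue(x, y))


@pytest.fixture(scope="module")
def small_study():
    fw, clade_of = sd.simulate_clade_framework(
        clade_sizes=(3, 3, 2), candidate_group_sizes=(2,), n_unmapped=0, seed=3
    )
    table, _ = sd.simulate_compound_matrix(
        clade_of, n_features=40, n_informative=4, target_sparsity=0.6, seed=4
    )
    return fw, table


class TestAverageOverMaps:
    def test_single_map_identity(self, four_tip_fw):
        table = make_table(
            [[1, 0, 1], [1, 1, 0], [0, 0, 1], [1, 1, 1]], QUALITATIVE
        )
        summary = pc.average_over_maps(
            four_tip_fw, table, ["C1", "C2", "C3"], "hamming"
        )
        assert len(summary.maps) == 1
        pd.testing.assert_frame_equal(summary.asld, summary.sld_per_map[0])
        assert summary.awcd.equals(summary.wcd_per_map.iloc[0])

    def test_awcd_matches_recomputation_oracle(self, small_study):
        fw, table = small_study
        features = table.compound_ids[:20]
        summary = pc.average_over_maps(fw, table, features, "hamming")
        clade_members = {
            name: [t for t in tips if t in fw.sample_map]
            for name, tips in fw.clades.items()
        }
        sample_d = pc.species_level_distances(table, features, "hamming")
        for name, members in clade_members.items():
            if len(members) < 2:
                continue
            per_map = []
            for m in summary.maps:
                vals = [
                    sample_d.loc[m[a], m[b]]
                    for a, b in itertools.combinations(members, 2)
                ]
                per_map.append(np.mean(vals))
            assert summary.awcd[name] == pytest.approx(np.mean(per_map))

    def test_asld_row_is_mean_over_maps(self, small_study):
        fw, table = small_study
        features = table.compound_ids
        summary = pc.average_over_maps(fw, table, features, "hamming")
        stacked = np.stack([s.to_numpy() for s in summary.sld_per_map])
        assert np.allclose(summary.asld.to_numpy(), stacked.mean(axis=0))

    def test_conservation_identity_every_map(self, small_study):
        # pair-count-weighted combination of WCDs and BCDs must equal the
        # mean off-diagonal SLD entry, for every enumerated map
        fw, table = small_study
        summary = pc.average_over_maps(fw, table, table.compound_ids, "hamming")
        clades = {
            name: [t for t in tips if t in fw.sample_map]
            for name, tips in fw.clades.items()
        }
        n = len(sorted(fw.sample_map))
        total_pairs = n * (n - 1) / 2
        for k, sld in enumerate(summary.sld_per_map):
            acc = 0.0
            for name, members in clades.items():
                npairs = len(members) * (len(members) - 1) / 2
                if npairs:
                    acc += npairs * summary.wcd_per_map.iloc[k][name]
            for (a, b) in itertools.combinations(summary.clade_names, 2):
                npairs = len(clades[a]) * len(clades[b])
                acc += npairs * summary.bcd_per_map.iloc[k][f"{a}|{b}"]
            iu = np.triu_indices(n, 1)
            mean_offdiag = sld.to_numpy()[iu].mean()
            assert acc / total_pairs == pytest.approx(mean_offdiag, abs=1e-9)


class TestBestMap:
    def test_single_map_selected(self, four_tip_fw):
        table = make_table(
            [[1, 0, 1], [1, 1, 0], [0, 0, 1], [1, 1, 1]], QUALITATIVE
        )
        summary = pc.average_over_maps(four_tip_fw, table,
                                       ["C1", "C2", "C3"], "hamming")
        assert pc.best_bijective_map(summary) == summary.maps[0]

    def test_outlier_kept_out_of_clade(self, tmp_path):
        # T1's candidates: S1 (identical to clade partner) or S9 (outlier);
        # the map avoiding the outlier within the clade must win
        files = write_framework(
            tmp_path,
            "((T1:1,T2:1):1,(T3:1,T4:1):1);",
            [("T1", "X"), ("T2", "X"), ("T3", "Y"), ("T4", "Y")],
            [("S1", "T1"), ("S9", "T1"), ("S2", "T2"),
             ("S9", "T3"), ("S3", "T3"), ("S4", "T4")],
        )
        fw = pc.read_clade_framework(*files)
        table = make_table(
            [
                [1, 1, 0, 0],  # S1 ~ clade X profile
                [1, 1, 0, 0],  # S2 ~ clade X profile
                [0, 0, 1, 1],  # S3 ~ clade Y profile
                [0, 0, 1, 1],  # S4 ~ clade Y profile
                [1, 0, 1, 0],  # S9 outlier
            ],
            QUALITATIVE,
            samples=["S1", "S2", "S3", "S4", "S9"],
        )
        summary = pc.average_over_maps(fw, table, table.compound_ids, "hamming")
        best = pc.best_bijective_map(summary)
        # direct evaluation over all maps confirms the argmax
        scores = summary.bcd_per_map.mean(axis=1) - summary.wcd_per_map.mean(axis=1)
        assert best == summary.maps[int(np.argmax(scores.to_numpy()))]
        assert best["T1"] == "S1" and best["T3"] == "S3"

    def test_tie_broken_by_enumeration_order(self, tmp_path):
        files = write_framework(
            tmp_path,
            "((T1:1,T2:1):1,T3:1);",
            [("T1", "X"), ("T2", "X"), ("T3", "Y")],
            [("S1", "T1"), ("S2", "T1"), ("S1", "T2"), ("S2", "T2"),
             ("S3", "T3")],
        )
        fw = pc.read_clade_framework(*files)
        table = make_table([[1, 0], [0, 1], [1, 1]], QUALITATIVE,
                           samples=["S1", "S2", "S3"])
        summary = pc.average_over_maps(fw, table, ["C1", "C2"], "hamming")
        # swapping S1/S2 leaves every clade distance unchanged: a pure tie
        scores = summary.bcd_per_map.mean(axis=1) - summary.wcd_per_map.mean(axis=1)
        assert scores.nunique() == 1 and len(summary.maps) == 2
        assert summary.best_map_index == 0


class TestReportAndExport:
    def test_report_counts(self, small_study):
        fw, table = small_study
        summary = pc.average_over_maps(fw, table, table.compound_ids, "hamming")
        report = pc.concordance_report(summary)
        defined = summary.awcd.dropna().to_numpy()
        assert report["n_awcd_defined"] == defined.size
        assert report["awcd_below_abcd_mean"] == int(
            (defined < summary.abcd.mean()).sum()
        )
        asld_vals = summary.asld.to_numpy()[
            np.triu_indices(summary.asld.shape[0], 1)
        ]
        assert report["asld_median"] == pytest.approx(np.median(asld_vals))
        assert 0 < report["wilcoxon_p"] <= 1

    def test_export_preserves_tip_order_and_unmapped(self, small_study):
        fw, table = small_study
        features = table.compound_ids[:5]
        summary = pc.average_over_maps(fw, table, features, "hamming")
        matrix, unmapped = pc.export_tree_ordered_matrix(
            fw, summary.best_map, table, features
        )
        assert list(matrix.index) == [t for t in fw.tip_order
                                      if t in summary.best_map]
        assert list(matrix.columns[1:]) == features
        assigned = set(summary.best_map.values())
        assert set(unmapped) == set(table.sample_ids) - assigned
        assert not (set(matrix["sample_id"]) & set(unmapped))
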