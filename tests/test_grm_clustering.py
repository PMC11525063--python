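import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from grmkit import grm_clustering as gc
from grmkit.synthetic_data import PlantedModule, simulate_binding_matrix

from _oracles import submatrix_density


# ---------------------------------------------------------------------------
# Row scaling
# ---------------------------------------------------------------------------

def test_row_zscore_population_sd():
    matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
    scaled = gc.row_zscore(matrix)
    assert np.allclose(scaled.loc["g"], [-1.2247, 0.0, 1.2247], atol=1e-4)


def test_row_zscore_constant_row_is_zero():
    matrix = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
    assert (gc.row_zscore(matrix).loc["g"] == 0).all()


def test_row_zscore_fixed_point(rng):
    row = rng.normal(0, 1, 10)
    row = (row - row.mean()) / row.std()
    matrix = pd.DataFrame([row], index=["g"])
    assert np.allclose(gc.row_zscore(matrix).loc["g"], row)


# ---------------------------------------------------------------------------
# Cluster-number selection
# ---------------------------------------------------------------------------

def test_choose_k_recovers_three_separated_blobs(rng):
    blocks = []
    for center in ([10, 0, 0], [0, 10, 0], [0, 0, 10]):
        blocks.append(rng.normal(center, 0.5, size=(20, 3)))
    matrix = pd.DataFrame(np.vstack(blocks))
    selection = gc.choose_k(matrix, "rows", range(2, 7), seed=0)
    assert selection.k == 3
    assert not selection.weak_structure


def test_choose_k_flags_single_blob_as_weak(rng):
    matrix = pd.DataFrame(rng.normal(0, 1, size=(60, 4)))
    selection = gc.choose_k(matrix, "rows", range(2, 7), seed=0)
    assert selection.weak_structure
    assert max(selection.silhouette.values()) <= 0.3


def test_choose_k_two_identical_blocks(rng):
    block = rng.normal(0, 0.05, size=(15, 4))
    matrix = pd.DataFrame(np.vstack([block + 5, block - 5]))
    selection = gc.choose_k(matrix, "rows", range(2, 6), seed=0)
    assert selection.k == 2
    assert selection.silhouette[2] > 0.9


def test_choose_k_tiny_axis_errors():
    with pytest.raises(ValueError):
        gc.choose_k(pd.DataFrame(np.eye(2)), "rows")


# ---------------------------------------------------------------------------
# Double k-means
# ---------------------------------------------------------------------------

def _planted_block_matrix(rng, noise=0.05):
    # 2x2 block design with +-1 blocks; the two row patterns stay distinct
    # after row scaling
    m = rng.normal(0, noise, size=(40, 20))
    m[:20, :10] += 1.0
    m[:20, 10:] -= 1.0
    m[20:, :10] -= 1.0
    m[20:, 10:] += 1.0
    return pd.DataFrame(m, index=[f"g{i:02d}" for i in range(40)],
                        columns=[f"T{i:02d}" for i in range(20)])


def test_double_kmeans_recovers_planted_blocks(rng):
    matrix = _planted_block_matrix(rng)
    result = gc.double_kmeans(gc.row_zscore(matrix), 2, 2, seed=0)
    row_truth = [0] * 20 + [1] * 20
    col_truth = [0] * 10 + [1] * 10
    assert adjusted_rand_score(row_truth, result.row_labels.values) == 1.0
    assert adjusted_rand_score(col_truth, result.col_labels.values) == 1.0


def test_double_kmeans_deterministic(rng):
    matrix = _planted_block_matrix(rng, noise=0.5)
    a = gc.double_kmeans(matrix, 3, 3, seed=7)
    b = gc.double_kmeans(matrix, 3, 3, seed=7)
    assert (a.row_labels == b.row_labels).all()
    assert (a.col_labels == b.col_labels).all()


def test_double_kmeans_row_permutation_equivariance(rng):
    matrix = _planted_block_matrix(rng, noise=0.3)
    perm = rng.permutation(matrix.index)
    a = gc.double_kmeans(matrix, 2, 2, seed=3)
    b = gc.double_kmeans(matrix.loc[perm], 2, 2, seed=3)
    # same partition up to label renumbering
    assert adjusted_rand_score(a.row_labels.loc[perm].values, b.row_labels.values) == 1.0


def test_double_kmeans_invalid_k_errors(rng):
    with pytest.raises(ValueError):
        gc.double_kmeans(_planted_block_matrix(rng), 1, 2, seed=0)


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def test_density_arithmetic():
    matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["T1", "T2"])
    assert gc.module_density(matrix, ["g1", "g2"], ["T1", "T2"]) == pytest.approx(2.5)
    zeros = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("xyz"))
    assert gc.module_density(zeros, list("abc"), list("xyz")) == 0.0


def test_density_matches_loop_oracle(rng):
    matrix = pd.DataFrame(
        rng.normal(0, 1, (20, 20)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"T{i}" for i in range(20)],
    )
    genes = [f"g{i}" for i in rng.choice(20, 7, replace=False)]
    tfs = [f"T{i}" for i in rng.choice(20, 5, replace=False)]
    assert gc.module_density(matrix, genes, tfs) == pytest.approx(
        submatrix_density(matrix, genes, tfs)
    )


def test_density_empty_cluster_errors():
    matrix = pd.DataFrame([[1.0]], index=["g"], columns=["T"])
    with pytest.raises(ValueError):
        gc.module_density(matrix, [], ["T"])


def test_full_matrix_density_is_grand_mean(rng):
    matrix = pd.DataFrame(rng.normal(0, 1, (10, 6)))
    assert gc.module_density(matrix, matrix.index, matrix.columns) == pytest.approx(
        matrix.to_numpy().mean()
    )


def test_density_conserved_over_partition(rng):
    matrix = pd.DataFrame(
        rng.normal(0, 1, (30, 12)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"T{i}" for i in range(12)],
    )
    clustering = gc.double_kmeans(gc.row_zscore(matrix), 3, 2, seed=0)
    total = 0.0
    for gcl in clustering.row_labels.unique():
        genes = clustering.row_labels.index[clustering.row_labels == gcl]
        for tcl in clustering.col_labels.unique():
            tfs = clustering.col_labels.index[clustering.col_labels == tcl]
            total += gc.module_density(matrix, genes, tfs) * len(genes) * len(tfs)
    assert total == pytest.approx(matrix.to_numpy().sum())


def test_row_scaling_never_feeds_density(rng):
    # densities are computed on the raw matrix, so ranking is scale-independent
    matrix = pd.DataFrame(
        rng.normal(0, 1, (30, 12)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"T{i}" for i in range(12)],
    )
    clustering = gc.double_kmeans(gc.row_zscore(matrix), 2, 2, seed=1)
    modules_raw = gc.select_modules(clustering, matrix, "up", top_n=4, exclude_singletons=False)
    shifted = matrix * 3.0
    modules_shifted = gc.select_modules(clustering, shifted, "up", top_n=4, exclude_singletons=False)
    assert [(m.gene_cluster, m.tf_cluster) for m in modules_raw] == [
        (m.gene_cluster, m.tf_cluster) for m in modules_shifted
    ]


# ---------------------------------------------------------------------------
# Module selection
# ---------------------------------------------------------------------------

def _manual_clustering(row_labels: dict, col_labels: dict) -> gc.ClusteringResult:
    rows = pd.Series(row_labels)
    cols = pd.Series(col_labels)
    return gc.ClusteringResult(rows, cols, rows.nunique(), cols.nunique(), 0, 0.0, 0.0)


def test_selection_ranks_by_absolute_density():
    matrix = pd.DataFrame(
        [[3.0, -2.0], [0.1, 0.1]], index=["g1", "g2"], columns=["T1", "T2"]
    )
    clustering = _manual_clustering({"g1": 0, "g2": 1}, {"T1": 0, "T2": 1})
    modules = gc.select_modules(clustering, matrix, "up", top_n=2, exclude_singletons=False)
    assert [round(m.density, 1) for m in modules] == [3.0, -2.0]


def test_singleton_tf_cluster_excluded():
    matrix = pd.DataFrame(
        [[10.0, 1.0, 1.0]], index=["g1"], columns=["T1", "T2", "T3"]
    )
    clustering = _manual_clustering({"g1": 0}, {"T1": 0, "T2": 1, "T3": 1})
    modules = gc.select_modules(clustering, matrix, "up", top_n=5)
    assert all(len(m.tf_cluster) >= 2 for m in modules)
    assert all("T1" not in m.tf_cluster for m in modules)
    included = gc.select_modules(clustering, matrix, "up", top_n=5, exclude_singletons=False)
    assert any(m.tf_cluster == frozenset({"T1"}) for m in included)


def test_planted_modules_selected_end_to_end():
    modules = (
        PlantedModule(tuple(range(0, 8)), tuple(range(0, 50)), "up", 1.0),
        PlantedModule(tuple(range(8, 16)), tuple(range(50, 100)), "down", 1.0),
    )
    matrix, row_truth, col_truth = simulate_binding_matrix(200, 40, modules, 0.2, seed=5)
    clustering = gc.double_kmeans(gc.row_zscore(matrix), 3, 3, seed=5)
    selected = gc.select_modules(clustering, matrix, "up", top_n=2, tfbs=None)
    planted_pairs = [
        (frozenset(row_truth.index[row_truth == i]), frozenset(col_truth.index[col_truth == i]))
        for i in (1, 2)
    ]
    got_pairs = [(m.gene_cluster, m.tf_cluster) for m in selected]
    for planted_genes, planted_tfs in planted_pairs:
        assert any(
            len(g & planted_genes) / len(g | planted_genes) >= 0.9
            and len(t & planted_tfs) / len(t | planted_tfs) >= 0.9
            for g, t in got_pairs
        )
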