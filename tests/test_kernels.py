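import numpy as np
import pandas as pd
import pytest

from soilnorm.kernels import (
    MODEL_TERMS,
    Kernel,
    KernelError,
    KernelSet,
    expand_to_records,
    genomic_relationship,
    hadamard,
    model_kernels,
)
from soilnorm.trial_data import MarkerMatrix, incidence

from conftest import make_table


def test_genomic_relationship_hand_example(toy_markers):
    # centered, unscaled: X_c = [[-1,1],[1,-1],[0,0]], G = X_c X_c'/2
    G = genomic_relationship(toy_markers, center=True, scale=False)
    np.testing.assert_allclose(
        G.values, [[1, -1, 0], [-1, 1, 0], [0, 0, 0]], atol=1e-12
    )
    assert G.labels == ["g1", "g2", "g3"]


def test_identical_genotypes_fully_correlated():
    m = MarkerMatrix(
        pd.DataFrame(
            [[0, 1, 2], [0, 1, 2], [2, 1, 0]], index=["a", "b", "c"], columns=list("xyz")
        )
    )
    G = genomic_relationship(m).values
    assert G[0, 0] == pytest.approx(G[1, 1])
    assert G[0, 1] == pytest.approx(G[0, 0])


def test_random_relationship_symmetric_psd():
    rng = np.random.default_rng(4)
    m = MarkerMatrix(
        pd.DataFrame(
            rng.integers(0, 3, size=(10, 50)).astype(float),
            index=[f"g{i}" for i in range(10)],
            columns=[f"m{j}" for j in range(50)],
        )
    )
    G = genomic_relationship(m)
    assert np.abs(G.values - G.values.T).max() <= 1e-10
    assert G.is_psd()
    # with centered+scaled markers the mean diagonal is ~1
    assert np.mean(np.diag(G.values)) == pytest.approx(1.0, rel=0.2)


def test_missing_codes_imputed_with_marker_mean():
    m = MarkerMatrix(
        pd.DataFrame(
            [[0.0, 2.0], [2.0, np.nan], [1.0, 1.0]],
            index=["a", "b", "c"],
            columns=["m1", "m2"],
        )
    )
    G = genomic_relationship(m, center=True, scale=False)
    # imputing m2 for b with mean(2,1)=1.5 reproduces explicit computation
    X = np.array([[0, 2], [2, 1.5], [1, 1]])
    Xc = X - X.mean(axis=0)
    np.testing.assert_allclose(G.values, Xc @ Xc.T / 2, atol=1e-12)


def test_all_monomorphic_is_degenerate():
    m = MarkerMatrix(
        pd.DataFrame([[2.0, 0.0], [2.0, 0.0]], index=["a", "b"], columns=["m1", "m2"])
    )
    with pytest.raises(KernelError, match="monomorphic"):
        genomic_relationship(m)


def test_expand_identity_reproduces_ZZt(toy_table):
    Z = incidence(toy_table, "environment")
    K = Kernel(np.eye(2), list(Z.levels))
    expanded = expand_to_records(K, Z)
    np.testing.assert_array_equal(expanded.values, Z.values @ Z.values.T)


def test_expand_hand_product():
    table = make_table(
        [
            ("g1", "e1", 2020, "f", "clay", 1.0),
            ("g2", "e1", 2020, "f", "clay", 1.0),
            ("g1", "e2", 2020, "f", "silt", 1.0),
            ("g2", "e2", 2020, "f", "silt", 1.0),
        ]
    )
    Z = incidence(table, "line")
    K = Kernel(np.array([[1.0, 0.5], [0.5, 1.0]]), ["g1", "g2"])
    expanded = expand_to_records(K, Z).values
    expected = np.array(
        [
            [1.0, 0.5, 1.0, 0.5],
            [0.5, 1.0, 0.5, 1.0],
            [1.0, 0.5, 1.0, 0.5],
            [0.5, 1.0, 0.5, 1.0],
        ]
    )
    np.testing.assert_allclose(expanded, expected)
    # duplicated entity -> identical rows/columns
    np.testing.assert_allclose(expanded[0], expanded[2])


def test_expand_label_mismatch(toy_table):
    Z = incidence(toy_table, "environment")
    K = Kernel(np.eye(2), ["x1", "x2"])
    with pytest.raises(KernelError, match="labels"):
        expand_to_records(K, Z)


def test_hadamard_identities_and_arithmetic():
    A = Kernel(np.array([[1.0, 2.0], [2.0, 4.0]]))
    ones = Kernel(np.ones((2, 2)))
    np.testing.assert_array_equal(hadamard(A, ones).values, A.values)
    eye = Kernel(np.eye(2))
    np.testing.assert_array_equal(hadamard(A, eye).values, np.diag(np.diag(A.values)))
    B = Kernel(np.array([[5.0, 6.0], [6.0, 8.0]]))
    np.testing.assert_array_equal(
        hadamard(A, B).values, [[5.0, 12.0], [12.0, 32.0]]
    )
    with pytest.raises(KernelError, match="dimensions"):
        hadamard(A, Kernel(np.eye(3)))


@pytest.mark.parametrize("model_id", ["M1", "M2", "M3", "M4"])
def test_model_kernel_term_sets(model_id, small_sim):
    table, markers, _ = small_sim
    G = genomic_relationship(markers)
    ks = model_kernels(model_id, table, G)
    assert set(ks.kernels) == set(MODEL_TERMS[model_id])
    for term in ks.terms:
        k = ks[term]
        assert np.abs(k.values - k.values.T).max() <= 1e-10
        assert k.is_psd()


def test_gxe_is_definitional_composition(small_sim):
    table, markers, _ = small_sim
    G = genomic_relationship(markers)
    ks = model_kernels("M3", table, G)
    np.testing.assert_allclose(
        ks["GxE"].values, ks["G"].values * ks["E"].values, atol=1e-12
    )
    np.testing.assert_allclose(
        ks["GxS"].values, ks["G"].values * ks["S"].values, atol=1e-12
    )


def test_gxs_matches_g_within_soil_zero_across(toy_markers):
    table = make_table(
        [
            ("g1", "e1", 2020, "f", "clay", 1.0),
            ("g2", "e1", 2020, "f", "clay", 1.0),
            ("g1", "e2", 2020, "f", "sand", 1.0),
        ]
    )
    G = genomic_relationship(toy_markers, center=True, scale=False)
    ks = model_kernels("M3", table, G)
    gxs, g = ks["GxS"].values, ks["G"].values
    assert gxs[0, 1] == pytest.approx(g[0, 1])  # same soil
    assert gxs[0, 2] == 0.0  # different soils
    assert gxs[1, 2] == 0.0


def test_single_environment_gxe_degenerates_to_g(toy_markers):
    table = make_table(
        [
            ("g1", "e1", 2020, "f", "clay", 1.0),
            ("g2", "e1", 2020, "f", "clay", 1.0),
        ]
    )
    G = genomic_relationship(toy_markers, center=True, scale=False)
    ks = model_kernels("M2", table, G)
    np.testing.assert_allclose(ks["GxE"].values, ks["G"].values)


def test_kernel_csv_roundtrip(tmp_path, toy_markers):
    G = genomic_relationship(toy_markers)
    path = tmp_path / "G.csv"
    G.to_csv(path)
    back = Kernel.from_csv(path)
    np.testing.assert_allclose(back.values, G.values)
    assert back.labels == G.labels


def test_kernelset_rejects_wrong_terms(small_sim):
    table, markers, _ = small_sim
    G = genomic_relationship(markers)
    ks = model_kernels("M1", table, G)
    with pytest.raises(KernelError, match="requires terms"):
        KernelSet("M2", dict(ks.kernels))
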