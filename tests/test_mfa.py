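import numpy as np
import pandas as pd
import pytest

from seafusion.design import generate_design, subset
from seafusion.mfa import (MFAError, block_weight, encode_qualitative,
                           mfa_fit, pca)
from seafusion.preprocess import preprocess_blocks
from seafusion.simulate import SyntheticSpec, generate_multiomics


def test_pca_rank_one_line():
    x = np.array([[1.0, 1.0], [2.0, 2.0], [-3.0, -3.0], [0.0, 0.0]])
    eigvals, _, loadings = pca(x)
    np.testing.assert_allclose(np.abs(loadings[:, 0]),
                               [1 / np.sqrt(2)] * 2, atol=1e-12)
    assert eigvals[1] < 1e-12


def test_pca_trace_identity(rng):
    x = rng.normal(size=(12, 30))
    x -= x.mean(axis=0)
    eigvals, _, _ = pca(x)
    np.testing.assert_allclose(eigvals.sum(), x.var(axis=0, ddof=1).sum(),
                               atol=1e-10)


def test_pca_matches_eigendecomposition_oracle(rng):
    """Scores agree (up to column sign) with an independent
    covariance-eigendecomposition route on 20 random matrices."""
    for _ in range(20):
        x = rng.normal(size=(8, 5))
        x -= x.mean(axis=0)
        eigvals, scores, loadings = pca(x)
        # independent oracle: eigh of the covariance matrix
        cov = x.T @ x / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(eigvals, w, atol=1e-8)
        oracle_scores = x @ v
        for k in range(len(w)):
            assert min(np.abs(scores[:, k] - oracle_scores[:, k]).max(),
                       np.abs(scores[:, k] + oracle_scores[:, k]).max()
                       ) < 1e-8
        np.testing.assert_allclose(scores @ loadings.T, x, atol=1e-10)


def test_block_weight_inverts_first_eigenvalue(rng):
    x = rng.normal(size=(12, 6))
    x -= x.mean(axis=0)
    lam1 = pca(x)[0][0]
    w = block_weight(x)
    assert w == pytest.approx(1.0 / lam1)
    assert block_weight(pd.DataFrame(x)) == pytest.approx(w)  # duplicate
    # post-weighting first eigenvalue is 1, on 20 random blocks
    for _ in range(20):
        b = rng.normal(size=(10, 4))
        b -= b.mean(axis=0)
        assert pca(b * np.sqrt(block_weight(b)))[0][0] == pytest.approx(
            1.0, abs=1e-8)


def test_block_weight_degenerate_block():
    with pytest.raises(MFAError):
        block_weight(np.zeros((6, 3)))


def test_encode_qualitative_balanced_four_levels():
    labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6 + ["d"] * 6
    enc = encode_qualitative(labels)
    assert enc.shape == (24, 4)
    # each column scaled by sqrt(4)=2 before centering: values in
    # {2 - 0.5, -0.5}
    assert set(np.round(enc.to_numpy().ravel(), 12)) == {1.5, -0.5}
    np.testing.assert_allclose(enc.sum(axis=0), 0.0, atol=1e-12)


def test_encode_qualitative_two_levels_rank_one():
    enc = encode_qualitative(["a", "b"])
    assert np.linalg.matrix_rank(enc.to_numpy()) == 1
    with pytest.raises(MFAError):
        encode_qualitative(["a", "a"])


def _site_mfa(seed, block_sizes, effect=3.0, classes=True, **spec_kw):
    design = subset(generate_design(6), site="muscle")
    spec = SyntheticSpec(seed=seed, block_sizes=block_sizes,
                         effect_size=effect, **spec_kw)
    blocks, truth = generate_multiomics(design, spec)
    scaled, _ = preprocess_blocks(blocks, design)
    meta = design.set_index("sample_id")
    labels = (meta["time"] + "_" + meta["group"]).loc[
        next(iter(scaled.values())).index]
    return scaled, (list(labels) if classes else None), truth, labels


def test_single_block_mfa_equals_pca():
    scaled, _, _, _ = _site_mfa(0, {"metabolomics": 40}, classes=False)
    res = mfa_fit(scaled, classes=None, n_dims=4)
    x = scaled["metabolomics"].to_numpy()
    xw = x * np.sqrt(block_weight(x))
    _, ref_scores, _ = pca(xw)
    for k in range(4):
        r = np.corrcoef(res.scores.iloc[:, k], ref_scores[:, k])[0, 1]
        assert abs(r) > 1 - 1e-8


def test_identical_blocks_share_contributions_equally(rng):
    x = rng.normal(size=(12, 8))
    x = pd.DataFrame(x - x.mean(axis=0))
    a = x.copy()
    a.columns = [f"a{j}" for j in range(8)]
    b = x.copy()
    b.columns = [f"b{j}" for j in range(8)]
    res = mfa_fit({"a": a, "b": b}, n_dims=3)
    np.testing.assert_allclose(res.block_contributions.loc["a"],
                               res.block_contributions.loc["b"], atol=1e-8)
    np.testing.assert_allclose(res.block_contributions.loc["a"], 50.0,
                               atol=1e-8)


def test_contributions_sum_to_100_and_scores_orthogonal():
    scaled, classes, _, _ = _site_mfa(
        1, {"lipidomics": 60, "metabolomics": 50, "proteomics": 40})
    res = mfa_fit(scaled, classes=classes, n_dims=5)
    np.testing.assert_allclose(res.block_contributions.sum(axis=0), 100.0,
                               atol=1e-8)
    np.testing.assert_allclose(res.variable_contributions.sum(axis=0),
                               100.0, atol=1e-8)
    s = res.scores.to_numpy()
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.diag(gram).max()
    assert (np.diff(res.eigenvalues.to_numpy()) <= 1e-12).all()


def test_permuting_samples_permutes_scores():
    scaled, classes, _, _ = _site_mfa(2, {"metabolomics": 30})
    res = mfa_fit(scaled, classes=classes, n_dims=3)
    perm = np.random.default_rng(0).permutation(len(classes))
    scaled_p = {k: v.iloc[perm] for k, v in scaled.items()}
    res_p = mfa_fit(scaled_p, classes=[classes[i] for i in perm], n_dims=3)
    pd.testing.assert_frame_equal(res.scores.iloc[perm], res_p.scores)


def test_truncation_warns_beyond_rank(rng):
    x = pd.DataFrame(rng.normal(size=(4, 10)))
    x -= x.mean(axis=0)
    with pytest.warns(UserWarning, match="rank"):
        mfa_fit({"a": x}, n_dims=9)


def test_planted_block_dominates_discriminating_dimension():
    """When the treatment signal lives in one block, that block's
    contribution exceeds the others' on the class-correlated dimension."""
    wins = 0
    for seed in range(20):
        design = subset(generate_design(6), site="muscle")
        spec = SyntheticSpec(
            seed=seed, effect_size=4.0, n_planted=15,
            block_sizes={"lipidomics": 60, "metabolomics": 50,
                         "proteomics": 40})
        blocks, _ = generate_multiomics(design, spec)
        # strip the planted effect from all but lipidomics by regenerating
        null = SyntheticSpec(seed=seed, effect_size=0.0, n_planted=15,
                             block_sizes=spec.block_sizes)
        null_blocks, _ = generate_multiomics(design, null)
        blocks["metabolomics"] = null_blocks["metabolomics"]
        blocks["proteomics"] = null_blocks["proteomics"]
        scaled, _ = preprocess_blocks(blocks, design)
        meta = design.set_index("sample_id")
        labels = (meta["time"] + "_" + meta["group"]).loc[
            next(iter(scaled.values())).index]
        res = mfa_fit(scaled, classes=list(labels), n_dims=3)
        # dimension most correlated with the treatment contrast
        y = (meta["group"] == "treated").astype(float).loc[
            res.scores.index].to_numpy()
        disc = np.argmax([abs(np.corrcoef(res.scores.iloc[:, k], y)[0, 1])
                          for k in range(3)])
        ctr = res.block_contributions.iloc[:, disc].drop(
            index="classes", errors="ignore")
        wins += ctr.idxmax() == "lipidomics"
    assert wins >= 19


def test_four_classes_separate_in_score_space():
    """Distinct 3 h and 24 h planted effects give four separated class
    centroids on the first two dimensions (positive silhouette)."""
    from sklearn.metrics import silhouette_score

    wins = 0
    for seed in range(20):
        scaled, classes, _, labels = _site_mfa(
            seed, {"lipidomics": 60, "metabolomics": 50, "proteomics": 40},
            effect=3.0, n_planted=15, distinct_time_effects=True)
        res = mfa_fit(scaled, classes=classes, n_dims=2)
        sil = silhouette_score(res.scores.to_numpy(), np.asarray(classes))
        wins += sil > 0
    assert wins >= 19
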