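import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance

from seafusion.design import generate_design, subset
from seafusion.microbiome import (MicrobiomeError, bray_curtis, chao1_bc,
                                  daa_wald, diversity_report, fold_change,
                                  kruskal_wallis, pcoa, permanova, rarefy,
                                  run_comparisons, shannon, simpson,
                                  tmm_factors)
from seafusion.simulate import OTUTable, generate_otu_counts


def _skin_3h():
    return subset(generate_design(6, sites=("skin",)), time="t3h",
                  site="skin")


# ----------------------------------------------------------------- alpha

def test_chao1_bias_corrected_hand_example():
    # S_obs=4, f1=2, f2=0 -> 4 + 2*1/(2*1) = 5
    assert chao1_bc([5, 3, 1, 1]) == 5.0
    assert chao1_bc([5, 3, 2, 2]) == 4.0  # no singletons -> S_obs
    with pytest.raises(MicrobiomeError):
        chao1_bc([0, 0])


def test_shannon_and_simpson_closed_forms(rng):
    assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
    assert simpson([1, 1, 1, 1]) == pytest.approx(0.75)
    assert shannon([7]) == 0.0
    assert simpson([7]) == 0.0
    assert simpson([1, 1, 1, 1], gini=False) == pytest.approx(0.25)
    for _ in range(10):
        c = rng.integers(1, 50, size=12)
        assert shannon(c) <= np.log((c > 0).sum()) + 1e-12
        # order invariance
        assert shannon(c[::-1]) == pytest.approx(shannon(c))
        assert chao1_bc(c[::-1]) == chao1_bc(c)


# ------------------------------------------------------------------ beta

def test_bray_curtis_formula_and_bounds():
    d = bray_curtis(np.array([[2.0, 2.0], [1.0, 1.0]]))
    assert d[0, 1] == pytest.approx(1.0 / 3.0)
    same = bray_curtis(np.array([[3.0, 1.0], [3.0, 1.0]]))
    assert same[0, 1] == 0.0
    disjoint = bray_curtis(np.array([[5.0, 0.0], [0.0, 4.0]]))
    assert disjoint[0, 1] == 1.0
    # joint scaling invariance
    a = np.array([[4.0, 1.0, 0.0], [2.0, 2.0, 3.0]])
    np.testing.assert_allclose(bray_curtis(a).data,
                               bray_curtis(10 * a).data)


def test_pcoa_reproduces_euclidean_configuration(rng):
    pts = rng.normal(size=(5, 2))
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(pts))
    from skbio.stats.distance import DistanceMatrix
    coords, eig = pcoa(DistanceMatrix(dist, ids=list("abcde")))
    rec = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(coords.to_numpy()))
    np.testing.assert_allclose(rec, dist, atol=1e-8)
    assert (np.diff(eig.to_numpy()) <= 1e-12).all()


def test_pcoa_identical_points_coincide():
    from skbio.stats.distance import DistanceMatrix
    d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    coords, _ = pcoa(DistanceMatrix(d, ids=list("abc")))
    np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-10)


def test_permanova_detects_separated_clusters(rng):
    x = np.r_[rng.normal(0, 0.1, size=(6, 3)),
              rng.normal(5, 0.1, size=(6, 3))]
    dist = bray_curtis(np.abs(x))
    groups = ["a"] * 6 + ["b"] * 6
    _, p = permanova(dist, groups, n_perm=199, seed=0)
    assert p == pytest.approx(1.0 / 200.0)


def test_kruskal_wallis_hand_example():
    h, p = kruskal_wallis([1, 2, 3, 4, 5, 6],
                          ["a", "a", "a", "b", "b", "b"])
    assert h == pytest.approx(3.857, abs=5e-4)
    h0, p0 = kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
    assert h0 == 0.0 and p0 == 1.0


# ------------------------------------------------------------------- TMM

def test_tmm_reference_and_composition_invariance():
    otu, _ = generate_otu_counts(_skin_3h(), n_taxa=50, dispersion=0.1,
                                 seed=0)
    f = tmm_factors(otu)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0)
    # doubling every count of a sample is a pure library-size change:
    # its factor stays within 5% of the undoubled sample's
    c = otu.counts.copy()
    c.iloc[:, 0] = c.iloc[:, 1] * 2
    f2 = tmm_factors(OTUTable(counts=c, taxonomy=otu.taxonomy))
    assert f2.iloc[0] / f2.iloc[1] == pytest.approx(1.0, abs=0.05)
    # reference against itself: identical columns share one factor
    assert f2.iloc[0] == pytest.approx(f2.iloc[1], abs=0.05)


def test_tmm_matches_edger_oracle(tmp_path):
    """Independent oracle: edgeR's calcNormFactors on the same table."""
    otu, _ = generate_otu_counts(_skin_3h(), n_taxa=60, dispersion=0.2,
                                 seed=42)
    mine = tmm_factors(otu)
    counts_path = tmp_path / "counts.tsv"
    otu.counts.to_csv(counts_path, sep="\t")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{counts_path}", row.names=1));'
        'cat(paste(calcNormFactors(x, method="TMM"), collapse=","))')
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    theirs = np.array([float(v) for v in out.stdout.strip().split(",")])
    np.testing.assert_allclose(mine.to_numpy(), theirs, atol=1e-10)


def test_tmm_trimming_robust_to_planted_upregulation():
    """Upregulating 5% of the taxa (at above-average abundance) in one
    group barely moves the factors: the trimming excludes the shifted
    M-values, and only the small residual composition change remains."""
    design = _skin_3h()
    otu, _ = generate_otu_counts(design, n_taxa=40,
                                 mean_abundances=np.ones(40),
                                 dispersion=0.0,  # Poisson: isolate the
                                 # composition effect from overdispersion
                                 planted_log2fc={0: 1.0, 1: 1.0}, seed=3,
                                 libsize_meanlog=np.log(1e5))
    f = tmm_factors(otu)
    # doubling 2 of 40 taxa inflates treated libraries by ~5%, which the
    # factors split ~+-2.5% around 1; anything beyond that is leakage of
    # the planted taxa past the trimming
    assert np.abs(f - 1.0).max() < 0.05


def test_tmm_rejects_empty_sample():
    otu, _ = generate_otu_counts(_skin_3h(), n_taxa=10, seed=1)
    c = otu.counts.copy()
    c.iloc[:, 2] = 0
    with pytest.raises(MicrobiomeError):
        tmm_factors(OTUTable(counts=c, taxonomy=otu.taxonomy))


# ------------------------------------------------------------------- DAA

def test_fold_change_matches_reported_table():
    """Printed log2 fold changes and fold changes are mutually consistent
    at two significant figures."""
    rows = [(6.26, 77), (6.05, 66), (5.19, 37), (9.20, 5.9e2),
            (3.96, 16), (10.43, 1.4e3), (6.53, 92), (3.22, 9.3)]
    for log2fc, fc in rows:
        assert fold_change(log2fc) == pytest.approx(fc)
    assert fold_change(0.0) == 1.0


def test_daa_wald_internal_consistency():
    design = _skin_3h()
    otu, _ = generate_otu_counts(design, n_taxa=25, dispersion=0.1,
                                 planted_log2fc={0: 2.0, 1: -1.5}, seed=8)
    res = daa_wald(otu, design, ("control", "treated"))
    t = res.table
    for taxon, row in t.dropna().iterrows():
        assert row["fold_change"] == pytest.approx(
            fold_change(row["log2_fold_change"]))
        assert row["fdr_p"] >= row["wald_p"] - 1e-12
    # BH monotone in p-value ranks
    s = t.dropna().sort_values("wald_p")
    assert s["fdr_p"].is_monotonic_increasing


def test_daa_excludes_all_zero_taxa():
    design = _skin_3h()
    otu, _ = generate_otu_counts(design, n_taxa=10, seed=4)
    c = otu.counts.copy()
    c.iloc[3] = 0
    res = daa_wald(OTUTable(counts=c, taxonomy=otu.taxonomy), design,
                   ("control", "treated"))
    assert res.excluded == ["Family004"]
    assert "Family004" not in res.table.index


def test_run_comparisons_layout():
    """Six contrast families; per-site families run once per microbiome
    site; pooled contrasts use three times the per-site sample count."""
    design = generate_design(6, sites=("skin", "gills", "eye"))
    otu, _ = generate_otu_counts(design, n_taxa=20, seed=6)
    results = run_comparisons(otu, design)
    families = {name for name, _ in results}
    assert len(families) == 6
    assert len(results) == 4 * 3 + 2
    per_site = results[("control_vs_treated_3h", "skin")]
    pooled = results[("all_sites_control_vs_treated_3h", None)]
    assert pooled.table.shape[0] == per_site.table.shape[0]
    # pooled contrast covers 3 sites x 12 samples
    n_pooled = design[(design["time"] == "t3h")].shape[0]
    assert n_pooled == 36


def test_targeted_contrast_is_detected_and_others_stay_quiet():
    """A fold change planted in treated samples at 24 h shows up in the
    treated 3h-vs-24h contrast but not in contrasts that exclude those
    samples."""
    planted_ids = [f"Family{i + 1:03d}" for i in range(4)]
    hits_target, hits_quiet = 0, 0
    n_seeds = 10
    for seed in range(n_seeds):
        design = generate_design(6, sites=("skin",))
        otu, _ = generate_otu_counts(
            design, n_taxa=30, mean_abundances=np.ones(30), dispersion=0.05,
            planted_log2fc={i: 3.0 for i in range(4)},
            seed=seed, target_group="treated", target_time="t24h")
        results = run_comparisons(otu, design, sites=("skin",))
        target = results[("treated_3h_vs_24h", "skin")].table
        quiet_a = results[("control_3h_vs_24h", "skin")].table
        quiet_b = results[("control_vs_treated_3h", "skin")].table
        hits_target += int((target.loc[planted_ids, "fdr_p"] < 0.05).sum())
        hits_quiet += int((quiet_a.loc[planted_ids, "fdr_p"] < 0.05).sum()
                          + (quiet_b.loc[planted_ids, "fdr_p"] < 0.05).sum())
    # near-complete power where the effect lives, ~none where it does not
    assert hits_target >= 0.9 * 4 * n_seeds
    assert hits_quiet <= 4


# ------------------------------------------------------- rarefaction etc.

def test_rarefaction_depth_and_dropping():
    design = _skin_3h()
    otu, _ = generate_otu_counts(design, n_taxa=30, seed=11)
    depth = int(otu.library_size.median())
    rare = rarefy(otu, depth=depth, seed=0)
    assert (rare.counts.sum(axis=0) == depth).all()
    assert rare.counts.shape[1] <= otu.counts.shape[1]
    # deterministic under the seed
    rare2 = rarefy(otu, depth=depth, seed=0)
    pd.testing.assert_frame_equal(rare.counts, rare2.counts)
    with pytest.raises(MicrobiomeError):
        rarefy(otu, depth=10**9)


def test_diversity_report_structure():
    design = generate_design(3, sites=("skin",))
    otu, _ = generate_otu_counts(design, n_taxa=25, seed=12)
    rep = diversity_report(otu, design, depth=int(otu.library_size.min()),
                           n_perm=99, seed=1)
    assert set(rep["alpha"].columns) == {"chao1_bc", "shannon", "simpson"}
    assert rep["kruskal_wallis"].shape == (3, 2)
    assert 0.0 < rep["permanova"]["p"] <= 1.0
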