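import numpy as np
import pandas as pd
import pytest

from csfnet.exceptions import ParameterError
from csfnet.matrix import AbundanceMatrix
from csfnet.preprocess import (OutlierParams, RegressionSpec, detect_outliers,
                               encode_covariates, filter_missingness,
                               knn_impute, mds_coordinates, median_polish,
                               regress_covariates, tampor_correct,
                               variance_fractions)
from csfnet.simulate import plant_outliers


def _matrix_from_frame(df, batches=None):
    roles = pd.Series("sample", index=df.columns)
    if batches is None:
        batches = pd.Series("1", index=df.columns)
    return AbundanceMatrix(data=df, roles=roles, batches=batches)


# ---------------------------------------------------------------------------
# quantification filter
# ---------------------------------------------------------------------------

def test_filter_boundary_inclusive():
    # 10 sample columns; proteins quantified in 100 / 60 / 50 / 40 percent
    cols = [f"s{i}" for i in range(10)]
    rows = {}
    for name, n_obs in [("p100", 10), ("p60", 6), ("p50", 5), ("p40", 4)]:
        vals = [1.0] * n_obs + [np.nan] * (10 - n_obs)
        rows[name] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    m = _matrix_from_frame(df)
    kept = filter_missingness(m, 0.5)
    assert list(kept.data.index) == ["p100", "p60", "p50"]


def test_filter_ignores_gis_columns():
    df = pd.DataFrame([[1.0, np.nan, 5.0]], index=["p"],
                      columns=["s1", "s2", "g1"])
    roles = pd.Series({"s1": "sample", "s2": "sample", "g1": "gis"})
    batches = pd.Series("1", index=df.columns)
    m = AbundanceMatrix(data=df, roles=roles, batches=batches)
    # quantified in 1/2 samples = 50% exactly -> kept; GIS column not counted
    assert filter_missingness(m, 0.5).data.shape[0] == 1
    assert filter_missingness(m, 0.6).data.shape[0] == 0


def test_filter_bad_fraction():
    df = pd.DataFrame([[1.0]], index=["p"], columns=["s1"])
    m = _matrix_from_frame(df)
    with pytest.raises(ParameterError):
        filter_missingness(m, 0.0)
    with pytest.raises(ParameterError):
        filter_missingness(m, 1.5)


# ---------------------------------------------------------------------------
# median polish / batch correction
# ---------------------------------------------------------------------------

def test_median_polish_removes_additive_structure():
    rng = np.random.default_rng(0)
    r = rng.normal(size=9)
    c = rng.normal(size=7)
    df = pd.DataFrame(np.add.outer(r, c))
    out = median_polish(df)
    assert np.abs(out.to_numpy()).max() < 1e-7


def test_median_polish_preserves_nan():
    df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
    out = median_polish(df)
    assert np.isnan(out.iloc[0, 1])
    assert out.notna().sum().sum() == 3


def test_tampor_cancels_planted_batch_offsets_exactly():
    # two batches, each 2 samples + 1 GIS; the batch offset hits every
    # channel including the GIS, so the ratio cancels it exactly
    rng = np.random.default_rng(1)
    true = rng.normal(10.0, 1.0, size=(30, 4))
    offsets = {"1": 0.0, "2": 1.7}
    cols = ["b1.s1", "b1.s2", "b1.gis", "b2.s1", "b2.s2", "b2.gis"]
    batches = pd.Series([c[1] for c in cols], index=cols)
    roles = pd.Series(["sample", "sample", "gis"] * 2, index=cols)
    gis_level = true.mean(axis=1)
    data = pd.DataFrame(
        np.column_stack([
            true[:, 0] + offsets["1"], true[:, 1] + offsets["1"],
            gis_level + offsets["1"],
            true[:, 2] + offsets["2"], true[:, 3] + offsets["2"],
            gis_level + offsets["2"],
        ]), index=[f"p{i}" for i in range(30)], columns=cols)
    m = AbundanceMatrix(data=data, roles=roles, batches=batches)
    corrected = tampor_correct(m)
    # batch medians of the corrected values agree across batches
    meds = corrected.data.T.groupby(batches[corrected.data.columns]).median().T
    assert np.abs(meds["1"] - meds["2"]).median() < np.abs(
        data[["b1.s1", "b1.s2"]].median(axis=1)
        - data[["b2.s1", "b2.s2"]].median(axis=1)).median()
    # a protein constant across samples comes out constant across batches
    assert corrected.data.shape[1] == 4        # GIS columns dropped


def _batch_variance_fraction(mat):
    sample_cols = [c for c in mat.data.columns if mat.roles[c] == "sample"]
    df = mat.data[sample_cols]
    batches = mat.batches[sample_cols]
    grand = df.mean(axis=1)
    means = df.T.groupby(batches).mean().T
    counts = df.notna().T.groupby(batches).sum().T
    ss_between = ((means.sub(grand, axis=0)) ** 2 * counts).sum(axis=1)
    ss_total = (df.sub(grand, axis=0) ** 2).sum(axis=1)
    frac = (ss_between / ss_total).replace([np.inf, -np.inf], np.nan)
    return float(frac.median())


def test_tampor_on_simulated_batches(cohort):
    from csfnet.simulate import BatchDesign, ModulePlantSpec, generate_tmt
    plant = ModulePlantSpec()
    shifted, _ = generate_tmt(cohort, plant,
                              BatchDesign(batchwise_missing_prob=0.0), seed=5)
    clean, _ = generate_tmt(cohort, plant,
                            BatchDesign(batch_shift_sd=0.0,
                                        batchwise_missing_prob=0.0), seed=5)
    # planted shifts are visible in the raw batch variance
    assert (_batch_variance_fraction(shifted)
            > _batch_variance_fraction(clean) + 0.05)
    # the shift hits every channel including the GIS, so the GIS ratio
    # cancels it exactly: corrected shifted and corrected clean data differ
    # only by a per-protein constant (the grand-median add-back)
    diff = (tampor_correct(shifted).data - tampor_correct(clean).data)
    assert float(diff.std(axis=1).max()) < 1e-8


def test_tampor_requires_gis():
    df = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["s1", "s2"])
    m = _matrix_from_frame(df)
    with pytest.raises(ParameterError, match="no GIS"):
        tampor_correct(m)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

def test_mds_separates_planted_sample_clusters():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 12))
    X[:, :6] += 3.0
    df = pd.DataFrame(X, index=[f"p{i}" for i in range(60)],
                      columns=[f"s{i}" for i in range(12)])
    coords = mds_coordinates(_matrix_from_frame(df))
    a = coords["dim1"].iloc[:6].to_numpy()
    b = coords["dim1"].iloc[6:].to_numpy()
    # linearly separated on dim1 (sign of the axis is arbitrary)
    assert max(a.min() - b.max(), b.min() - a.max()) > 0


def test_mds_matches_eigendecomposition_on_complete_data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 8))
    df = pd.DataFrame(X, columns=[f"s{i}" for i in range(8)])
    coords = mds_coordinates(_matrix_from_frame(df), n_dims=7).to_numpy()
    # with all n-1 dimensions, classical MDS reproduces the pairwise
    # distances of the standardised data exactly
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    D = np.sqrt(((Z[:, :, None] - Z[:, None, :]) ** 2).sum(axis=0))
    recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    assert np.allclose(D, recon, atol=1e-6)


def test_mds_too_few_samples():
    df = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["s1", "s2"])
    with pytest.raises(ParameterError):
        mds_coordinates(_matrix_from_frame(df), n_dims=2)


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------

def test_outlier_params_validation():
    with pytest.raises(ParameterError):
        OutlierParams(n_components=0).validate()
    with pytest.raises(ParameterError):
        OutlierParams(crit=0.4).validate()
    with pytest.raises(ParameterError):
        OutlierParams(crit=1.0).validate()


def test_detect_outliers_recovers_planted(tmt):
    mat, _ = tmt
    mat = tampor_correct(filter_missingness(mat))
    n = len(mat.sample_columns)
    clean = detect_outliers(mat)
    assert len(clean.outliers) <= 0.05 * n

    targets = list(mat.sample_of_column)[:3]
    planted = plant_outliers(mat, targets, shift_mads=8.0, seed=1)
    res = detect_outliers(planted)
    cols = {planted.column_of_sample(s) for s in targets}
    assert cols <= set(res.outliers)
    assert len(res.outliers) <= len(cols) + 0.05 * n


def test_detect_outliers_dimension_guard():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(20, 4)),
                      columns=[f"s{i}" for i in range(4)])
    with pytest.raises(ParameterError):
        detect_outliers(_matrix_from_frame(df), OutlierParams(n_components=7))


# ---------------------------------------------------------------------------
# covariate regression
# ---------------------------------------------------------------------------

def _toy_traits(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "diagnosis": np.where(np.arange(n) % 2 == 0, "CT", "AD"),
        "race": np.where(np.arange(n) % 4 < 2, "Cau", "AA"),
        "sex": rng.choice(["F", "M"], size=n),
        "age": rng.uniform(55, 85, size=n),
    }, index=[f"S{i:03d}" for i in range(n)])


def test_regression_removes_age_keeps_group():
    n = 80
    traits = _toy_traits(n, seed=5)
    rng = np.random.default_rng(6)
    age_c = traits["age"] - traits["age"].mean()
    dx = (traits["diagnosis"] == "AD").astype(float).to_numpy()
    Y = (0.05 * age_c.to_numpy() + 0.8 * dx
         + 0.1 * rng.normal(size=n))
    df = pd.DataFrame([Y, Y + 1.0], index=["p1", "p2"], columns=traits.index)
    spec = RegressionSpec(remove_covariates=("age",), n_bootstrap=200, seed=0)
    out = regress_covariates(df, traits, spec)
    before = np.corrcoef(df.loc["p1"], traits["age"])[0, 1]
    after = np.corrcoef(out.loc["p1"], traits["age"])[0, 1]
    assert abs(before) > 0.5
    assert abs(after) < 0.15
    gap = out.loc["p1", dx == 1].mean() - out.loc["p1", dx == 0].mean()
    assert gap == pytest.approx(0.8, abs=0.1)   # group effect survives


def test_regression_null_is_near_identity():
    traits = _toy_traits(60, seed=7)
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(size=(5, 60)),
                      index=[f"p{i}" for i in range(5)], columns=traits.index)
    spec = RegressionSpec(remove_covariates=("age",), n_bootstrap=200, seed=0)
    out = regress_covariates(df, traits, spec)
    assert np.abs(out.to_numpy() - df.to_numpy()).max() < 0.5
    assert np.corrcoef(out.to_numpy().ravel(), df.to_numpy().ravel())[0, 1] > 0.95


def test_regression_constant_covariate_warns():
    traits = _toy_traits(30, seed=9)
    traits["sex"] = "F"
    df = pd.DataFrame(np.random.default_rng(10).normal(size=(2, 30)),
                      index=["p1", "p2"], columns=traits.index)
    spec = RegressionSpec(remove_covariates=("age", "sex"), n_bootstrap=50)
    with pytest.warns(UserWarning, match="constant covariates"):
        regress_covariates(df, traits, spec)


def test_regression_spec_validation():
    with pytest.raises(ParameterError):
        RegressionSpec(remove_covariates=("age", "diagnosis")).validate()
    with pytest.raises(ParameterError):
        RegressionSpec(n_bootstrap=0).validate()


def test_regression_unknown_sample_errors():
    traits = _toy_traits(10)
    df = pd.DataFrame(np.zeros((1, 2)), index=["p"],
                      columns=["S000", "missing"])
    with pytest.raises(ParameterError, match="without traits"):
        regress_covariates(df, traits, RegressionSpec(n_bootstrap=10))


def test_encode_covariates_coding():
    traits = _toy_traits(8)
    enc = encode_covariates(traits, ["diagnosis", "race", "sex", "age"])
    assert set(enc["diagnosis"].unique()) <= {0.0, 1.0}
    assert (enc.loc[traits["diagnosis"] == "AD", "diagnosis"] == 1.0).all()
    assert (enc.loc[traits["race"] == "AA", "race"] == 1.0).all()
    assert (enc["age"] == traits["age"]).all()


# ---------------------------------------------------------------------------
# kNN imputation and variance partition
# ---------------------------------------------------------------------------

def test_knn_impute_recovers_from_identical_donors():
    base = np.tile(np.arange(10.0), (5, 1))
    df = pd.DataFrame(base.copy())
    df.iloc[0, 3] = np.nan
    out = knn_impute(df, k=3)
    assert out.iloc[0, 3] == pytest.approx(3.0)
    assert out.notna().all().all()


def test_knn_impute_no_missing_is_identity():
    df = pd.DataFrame(np.random.default_rng(11).normal(size=(4, 6)))
    pd.testing.assert_frame_equal(knn_impute(df), df)


def test_variance_fractions_planted_factor_dominates():
    traits = _toy_traits(100, seed=12)
    rng = np.random.default_rng(13)
    dx = (traits["diagnosis"] == "AD").astype(float).to_numpy()
    Y = np.vstack([2.0 * dx + 0.3 * rng.normal(size=100),
                   rng.normal(size=100)])
    df = pd.DataFrame(Y, index=["driven", "noise"], columns=traits.index)
    vf = variance_fractions(df, traits)
    assert vf.loc["driven", "diagnosis"] > 0.7
    assert vf.loc["driven", "diagnosis"] == vf.loc["driven"].drop("residual").max()
    assert vf.loc["noise", "residual"] > 0.8
    sums = vf.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-8)
    assert (vf.to_numpy() >= -1e-8).all()
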