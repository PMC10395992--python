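import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mcdt
from mcdt.pooled_index import (
    SelectionConfig,
    candidate_signs,
    fit_normalization,
)


def random_candidates(rng, n_sub=15, n_cand=6, corr_blocks=()):
    """Candidate matrix with optional planted correlated blocks."""
    X = rng.normal(size=(n_sub, n_cand))
    for block in corr_blocks:
        lead = block[0]
        for j in block[1:]:
            X[:, j] = X[:, lead] + 0.1 * rng.normal(size=n_sub)
    cols = [f"c{j:02d}" for j in range(n_cand)]
    return pd.DataFrame(X, index=[f"S{i:02d}" for i in range(n_sub)], columns=cols)


def rand_labels(rng, n):
    lab = np.array(["CNA", "SCI", "MCI"])[rng.integers(0, 3, size=n)]
    # guarantee >= 2 per class
    lab[:6] = ["CNA", "CNA", "SCI", "SCI", "MCI", "MCI"]
    return pd.Series(lab, index=[f"S{i:02d}" for i in range(n)])


# -- spearman ------------------------------------------------------------


def test_spearman_rank_invariance_and_antisymmetry():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    df = pd.DataFrame({"x": x, "mono": np.exp(2 * x), "neg": -x})
    rho = mcdt.spearman_matrix(df)
    assert rho.loc["x", "mono"] == pytest.approx(1.0)
    assert rho.loc["x", "neg"] == pytest.approx(-1.0)
    assert np.allclose(rho, rho.T)
    assert np.allclose(np.diag(rho), 1.0)


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.integers(0, 6, size=(5, 3)).astype(float), columns=list("abc"))
    rho = mcdt.spearman_matrix(df)
    ranks = df.rank()  # average-rank tie handling
    oracle = np.corrcoef(ranks.to_numpy().T)
    assert np.allclose(rho.to_numpy(), oracle, atol=1e-12)


def test_spearman_constant_column_reported():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [4.0, 3, 1, 2]})
    with pytest.warns(UserWarning, match="constant"):
        rho = mcdt.spearman_matrix(df)
    assert np.isnan(rho.loc["a", "b"])
    counts = mcdt.count_exceedances(rho, 0.4)
    assert counts["b"] == 2  # undefined correlations treated as exceeding


# -- exceedance counting --------------------------------------------------


def test_count_exceedances_forced_cases():
    eye = pd.DataFrame(np.eye(4) * 1.0, index=list("abcd"), columns=list("abcd"))
    assert (mcdt.count_exceedances(eye, 0.4) == 0).all()
    m = eye.copy()
    m.loc["a", "b"] = m.loc["b", "a"] = 0.95
    counts = mcdt.count_exceedances(m, 0.4)
    assert counts["a"] == 1 and counts["b"] == 1 and counts["c"] == 0


def test_count_exceedances_brute_force_oracle():
    rng = np.random.default_rng(9)
    a = rng.uniform(-1, 1, size=(6, 6))
    rho = pd.DataFrame((a + a.T) / 2, index=list("abcdef"), columns=list("abcdef"))
    np.fill_diagonal(rho.values, 1.0)
    counts = mcdt.count_exceedances(rho, 0.4)
    for i, ci in enumerate(rho.index):
        expected = sum(
            1 for j, cj in enumerate(rho.columns) if j != i and abs(rho.iloc[i, j]) >= 0.4
        )
        assert counts[ci] == expected
    # boundary counts as exceeding
    b = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["x", "y"], columns=["x", "y"])
    assert (mcdt.count_exceedances(b, 0.4) == 1).all()


# -- Cohen's d ------------------------------------------------------------


def test_cohens_d_cases():
    assert mcdt.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
    # group means 1 and 2, both SD exactly 1, equal n -> |d| = 1
    assert mcdt.cohens_d([0, 1, 2], [1, 2, 3]) == pytest.approx(-1.0)
    # unequal-n fixture, frozen from the pooled-SD hand computation
    assert mcdt.cohens_d([1, 2, 3], [2, 4, 6, 8]) == pytest.approx(-1.4301938838683883)
    with pytest.warns(UserWarning, match="zero pooled SD"):
        assert mcdt.cohens_d([2, 2], [2, 2]) == 0.0
    with pytest.raises(ValueError):
        mcdt.cohens_d([1], [1, 2])


# -- selection ------------------------------------------------------------


def flowchart_oracle(candidates, labels, threshold=0.4, max_components=6, manual=()):
    """Independent re-implementation of the elimination flowchart using
    scipy.stats for both the correlation matrix and the effect sizes."""
    current = list(candidates.columns)
    while len(current) > 1:
        X = candidates[current].to_numpy()
        k = len(current)
        rho = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                r = stats.spearmanr(X[:, i], X[:, j]).statistic
                rho[i, j] = rho[j, i] = r
        counts = [
            sum(
                1
                for j in range(k)
                if j != i and (np.isnan(rho[i, j]) or abs(rho[i, j]) >= threshold - 1e-9)
            )
            for i in range(k)
        ]
        if len(current) <= max_components and max(counts) == 0:
            break
        top = max(counts)
        tied = [current[i] for i in range(k) if counts[i] == top]
        if len(tied) == 1:
            victim = tied[0]
        else:
            es = {}
            for c in tied:
                v = candidates[c]
                ds = []
                for ca, cb in (("CNA", "SCI"), ("CNA", "MCI"), ("SCI", "MCI")):
                    ga = v[labels == ca].to_numpy()
                    gb = v[labels == cb].to_numpy()
                    na, nb = len(ga), len(gb)
                    sp = np.sqrt(
                        ((na - 1) * np.var(ga, ddof=1) + (nb - 1) * np.var(gb, ddof=1))
                        / (na + nb - 2)
                    )
                    ds.append(abs((ga.mean() - gb.mean()) / sp) if sp > 0 else 0.0)
                es[c] = max(ds)
            weakest = min(es.values())
            tied2 = sorted(c for c in tied if es[c] == weakest)
            if len(tied2) == 1:
                victim = tied2[0]
            else:
                pick = [c for c in manual if c in tied2]
                victim = pick[0] if pick else tied2[0]
        current.remove(victim)
    return sorted(current)


def test_selection_stop_condition():
    rng = np.random.default_rng(21)
    # orthogonalized candidates: all pairwise |rho| < 0.4 stays untouched
    cand = random_candidates(rng, n_sub=60, n_cand=4)
    labels = rand_labels(rng, 60)
    model = mcdt.select_components(cand, labels)
    assert sorted(model.components) == sorted(cand.columns)
    assert model.audit_trail[-1]["action"] == "stop"


def test_selection_duplicate_removed_first():
    rng = np.random.default_rng(22)
    cand = random_candidates(rng, n_sub=80, n_cand=8, corr_blocks=[(0, 7)])
    labels = rand_labels(rng, 80)
    model = mcdt.select_components(cand, labels)
    deletions = [e for e in model.audit_trail if e["action"] == "delete"]
    assert deletions[0]["candidate"] in ("c00", "c07")
    assert not {"c00", "c07"} <= set(model.components)


@pytest.mark.parametrize("seed", range(25))
def test_selection_matches_flowchart_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    blocks = [(0, 1, 2), (3, 4)] if seed % 2 else [(0, 1), (2, 3), (4, 5)]
    cand = random_candidates(rng, n_sub=18, n_cand=10, corr_blocks=blocks)
    labels = rand_labels(rng, 18)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mcdt.select_components(cand, labels)
        expected = flowchart_oracle(cand, labels)
    assert sorted(model.components) == expected


def test_selection_invariant_to_monotone_transform():
    rng = np.random.default_rng(77)
    cand = random_candidates(rng, n_sub=30, n_cand=8, corr_blocks=[(0, 1)])
    labels = rand_labels(rng, 30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = mcdt.select_components(cand, labels)
        # strictly monotone transform of every candidate; rank screen is
        # unchanged, only effect-size tie-breaks could in principle move
        transformed = np.exp(cand / cand.abs().max())
        other = mcdt.select_components(transformed, labels)
    assert set(base.components) == set(other.components)


def test_selection_needs_two_per_class():
    rng = np.random.default_rng(5)
    cand = random_candidates(rng, n_sub=6, n_cand=4, corr_blocks=[(0, 1), (2, 3)])
    labels = pd.Series(
        ["CNA", "CNA", "CNA", "CNA", "CNA", "MCI"], index=cand.index
    )
    with pytest.raises(ValueError, match="two classes"):
        mcdt.select_components(cand, labels)


# -- scoring --------------------------------------------------------------


def test_score_pi_single_component_and_bounds():
    rng = np.random.default_rng(8)
    cand = random_candidates(rng, n_sub=12, n_cand=3)
    labels = rand_labels(rng, 12)
    model = mcdt.select_components(cand[["c00"]].assign(c01=cand["c01"]), labels)
    single = mcdt.PooledIndexModel(
        name="one", components=["c00"], signs={"c00": 1}, norm_params={}, normalization="minmax"
    )
    fit_normalization(single, cand)
    scores = mcdt.score_pi(single, cand).scores["one"]
    v = cand["c00"]
    expected = (v - v.min()) / (v.max() - v.min())
    assert np.allclose(scores, expected)
    assert scores.min() == pytest.approx(0.0) and scores.max() == pytest.approx(1.0)


def test_score_pi_hand_fixture():
    cand = pd.DataFrame(
        {"a": [0.0, 5.0, 10.0], "b": [2.0, 2.0, 6.0], "c": [-4.0, 0.0, 4.0]},
        index=["s1", "s2", "s3"],
    )
    model = mcdt.PooledIndexModel(
        name="PI", components=["a", "b", "c"], signs={"a": 1, "b": 1, "c": -1},
        norm_params={}, normalization="minmax",
    )
    fit_normalization(model, cand)
    s = mcdt.score_pi(model, cand).scores["PI"]
    # a: 0, .5, 1 ; b: 0, 0, 1 ; c oriented -> 4,0,-4: 1, .5, 0
    assert s["s1"] == pytest.approx((0 + 0 + 1) / 3)
    assert s["s2"] == pytest.approx((0.5 + 0 + 0.5) / 3)
    assert s["s3"] == pytest.approx((1 + 1 + 0) / 3)


def test_score_pi_orientation_polarity_invariance():
    """Flipping a candidate's raw polarity and its orientation sign leaves
    the PI unchanged under min-max normalization."""
    rng = np.random.default_rng(17)
    cand = random_candidates(rng, n_sub=10, n_cand=2)
    m1 = mcdt.PooledIndexModel("PI", ["c00", "c01"], {"c00": 1, "c01": 1}, {}, "minmax")
    fit_normalization(m1, cand)
    s1 = mcdt.score_pi(m1, cand).scores["PI"]
    flipped = cand.assign(c01=-cand["c01"])
    m2 = mcdt.PooledIndexModel("PI", ["c00", "c01"], {"c00": 1, "c01": -1}, {}, "minmax")
    fit_normalization(m2, flipped)
    s2 = mcdt.score_pi(m2, flipped).scores["PI"]
    assert np.allclose(s1, s2)


def test_score_pi_missing_component_value():
    cand = pd.DataFrame({"a": [1.0, np.nan, 3.0]}, index=["s1", "s2", "s3"])
    model = mcdt.PooledIndexModel("PI", ["a"], {"a": 1}, {}, "minmax")
    fit_normalization(model, cand)
    with pytest.warns(UserWarning, match="missing"):
        s = mcdt.score_pi(model, cand).scores["PI"]
    assert np.isnan(s["s2"]) and not np.isnan(s["s1"])


# -- assembly and the five indices ----------------------------------------


def test_assemble_candidate_counts(dtc_table):
    cfg = SelectionConfig()
    tthp = mcdt.assemble_candidates(dtc_table, ["TTHP"], cfg)
    assert tthp.shape[1] == 8 * 3  # 8 features x 3 loads
    total_avg = mcdt.assemble_candidates(
        dtc_table, ["FTAP", "TTHP", "GAIT"], SelectionConfig(candidate_mode="load_averaged")
    )
    assert total_avg.shape[1] == 32
    with pytest.raises(ValueError, match="unknown exercises"):
        mcdt.assemble_candidates(dtc_table, ["SWIM"], cfg)


def test_build_all_pis_structure(pis, dtc_table):
    models, scores = pis
    assert set(models) == {"FTAP", "TTHP", "GAIT", "TAPPING", "TOTAL"}
    for name, model in models.items():
        assert 1 <= len(model.components) <= 6
        exercises = {c.split("_")[0] for c in model.components}
        assert exercises <= set(mcdt.PI_NAMES[name])
    assert list(scores.scores.columns) == list(mcdt.PI_NAMES)
    assert scores.scores.to_numpy().min() >= 0 and scores.scores.to_numpy().max() <= 1
    # TAPPING candidate pool spans the union of the two tapping exercises
    cfg = SelectionConfig()
    tap = set(mcdt.assemble_candidates(dtc_table, mcdt.PI_NAMES["TAPPING"], cfg).columns)
    ftap = set(mcdt.assemble_candidates(dtc_table, ["FTAP"], cfg).columns)
    tthp = set(mcdt.assemble_candidates(dtc_table, ["TTHP"], cfg).columns)
    assert tap == ftap | tthp


def test_retained_set_is_mutually_weakly_correlated(pis, dtc_table):
    models, _ = pis
    cfg = SelectionConfig()
    for name, model in models.items():
        if len(model.components) < 2:
            continue
        cand = mcdt.assemble_candidates(dtc_table, mcdt.PI_NAMES[name], cfg)
        rho = mcdt.spearman_matrix(cand[model.components])
        off = rho.to_numpy()[~np.eye(len(rho), dtype=bool)]
        assert np.nanmax(np.abs(off)) < cfg.rho_threshold
        assert model.audit_trail[-1]["action"] == "stop"


def test_model_json_roundtrip(pis):
    models, _ = pis
    m = models["TTHP"]
    back = mcdt.PooledIndexModel.from_json(m.to_json())
    assert back.components == m.components
    assert back.signs == m.signs
    assert back.norm_params == m.norm_params


def test_candidate_signs_follow_feature_orientation():
    orientation = {"FTAP_f01": True, "FTAP_f02": False}
    signs = candidate_signs(["FTAP_f01_CL1", "FTAP_f02_CL3"], orientation)
    assert signs == {"FTAP_f01_CL1": 1, "FTAP_f02_CL3": -1}
    with pytest.raises(ValueError, match="orientation"):
        candidate_signs(["GAIT_f01_CL1"], orientation)
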