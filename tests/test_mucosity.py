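import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mucoswab import (
    AbundanceTable,
    CohortDesign,
    SampleMetadata,
    cross_experiment_predict,
    diet_effect_prda,
    eating_correlation,
    fit_mucosity_space,
    predict_mucosity,
    simulate_cohort,
    to_relative,
)
from mucoswab.ordination import design_matrix, rda

from conftest import cohort_mucosity


def study_swabs(meta, pairs, study):
    df = meta.frame.set_index("sample_id")
    return [p.swab_id for p in pairs.paired if df.loc[p.swab_id, "study"] == study]


# ----------------------------------------------------------- fitting


def test_fit_requires_enough_swabs_and_values(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    swab_ids = study_swabs(meta, pairs, "exp1")
    with pytest.raises(ValueError, match="at least 8"):
        fit_mucosity_space(rel.select_samples(swab_ids[:5]), measured)
    gappy = measured.drop(swab_ids[0])
    with pytest.raises(ValueError, match="missing mucosity"):
        fit_mucosity_space(rel.select_samples(swab_ids), gappy)


def test_fit_rejects_constant_mucosity(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    swab_ids = study_swabs(meta, pairs, "exp1")
    const = pd.Series(0.3, index=measured.index)
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_mucosity_space(rel.select_samples(swab_ids), const)


def test_fitted_space_is_significant_and_tracks_mucosity():
    """Axis-1 CaseR scores of the training swabs rank with measured mucosity."""
    rhos = []
    for seed in range(10):
        table, meta, _ = simulate_cohort(CohortDesign(seed=seed))
        rel, pairs, measured = cohort_mucosity(table, meta)
        swab_ids = study_swabs(meta, pairs, "exp1")
        model = fit_mucosity_space(
            rel.select_samples(swab_ids), measured, n_perm=999, seed=seed
        )
        assert model.explained_variation > 0
        assert model.permutation_p < 0.05
        assessment = predict_mucosity(model, rel.select_samples(swab_ids), measured)
        rhos.append(assessment.validation_rho)
    assert np.mean(rhos) >= 0.9


# ----------------------------------------------------------- predict


def test_predict_training_flagged_and_self_consistent(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    swab_ids = study_swabs(meta, pairs, "exp1")
    model = fit_mucosity_space(rel.select_samples(swab_ids), measured)
    assessment = predict_mucosity(model, rel.select_samples(swab_ids), measured)
    assert (assessment.frame["source"] == "trained").all()
    np.testing.assert_allclose(
        assessment.frame["predicted"].to_numpy(), model.case_r_scores[:, 0], atol=1e-10
    )


def test_predict_invariant_to_order_and_count_scaling(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    swab_ids = study_swabs(meta, pairs, "exp1")
    model = fit_mucosity_space(rel.select_samples(swab_ids), measured)
    counts = table.select_samples(swab_ids)
    base = predict_mucosity(model, counts).frame.set_index("sample_id")["predicted"]
    # reversed sample order
    rev = predict_mucosity(model, table.select_samples(swab_ids[::-1]))
    rev_s = rev.frame.set_index("sample_id")["predicted"]
    np.testing.assert_allclose(rev_s.loc[base.index], base, atol=1e-12)
    # one sample's counts multiplied by a positive constant
    scaled_counts = counts.counts.copy()
    scaled_counts[0] *= 7
    scaled = AbundanceTable(counts.sample_ids, counts.taxon_ids, scaled_counts)
    scaled_s = predict_mucosity(model, scaled).frame.set_index("sample_id")["predicted"]
    np.testing.assert_allclose(scaled_s, base, atol=1e-12)


def test_heldout_recovery_and_colon_projection():
    """Held-out swabs recover their true mixing coefficient; colon samples
    projected as supplementary land below the swabs on axis 1."""
    held_rhos = []
    colon_low = 0
    for seed in range(10):
        design = CohortDesign(seed=seed)
        table, meta, truth = simulate_cohort(design)
        rel, pairs, measured = cohort_mucosity(table, meta)
        swab_animal = {p.swab_id: p.animal_id for p in pairs.paired}
        s1 = study_swabs(meta, pairs, "exp1")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(s1))
        train = [s1[i] for i in perm[:14]]
        held = [s1[i] for i in perm[14:]]
        model = fit_mucosity_space(rel.select_samples(train), measured)
        held_pred = predict_mucosity(model, rel.select_samples(held)).frame
        truth_m = [truth.mixing[swab_animal[s]] for s in held_pred["sample_id"]]
        held_rhos.append(spearmanr(truth_m, held_pred["predicted"]).statistic)
        # colon samples as pseudo-swabs
        df = meta.frame.set_index("sample_id")
        colon1 = [p.colon_id for p in pairs.paired if df.loc[p.swab_id, "study"] == "exp1"]
        colon_pred = predict_mucosity(model, rel.select_samples(colon1)).frame["predicted"]
        swab_pred = predict_mucosity(model, rel.select_samples(s1)).frame["predicted"]
        colon_low += np.median(colon_pred) < np.quantile(swab_pred, 0.25)
    assert np.mean(held_rhos) >= 0.85
    assert colon_low == 10


def test_recovery_degrades_with_more_overdispersion():
    """Parameter recovery worsens monotonically as the Dirichlet
    concentration drops (noisier compositions)."""
    means = []
    for conc in (200.0, 50.0, 12.5):
        rhos = []
        for seed in range(5):
            design = CohortDesign(
                studies=("exp1",), n_animals_per_arm=(14,), overdispersion=conc, seed=seed + 90
            )
            table, meta, truth = simulate_cohort(design)
            rel, pairs, measured = cohort_mucosity(table, meta)
            swab_animal = {p.swab_id: p.animal_id for p in pairs.paired}
            s1 = [p.swab_id for p in pairs.paired]
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(s1))
            train = [s1[i] for i in perm[:14]]
            held = [s1[i] for i in perm[14:]]
            model = fit_mucosity_space(rel.select_samples(train), measured)
            pred = predict_mucosity(model, rel.select_samples(held)).frame
            truth_m = [truth.mixing[swab_animal[s]] for s in pred["sample_id"]]
            rhos.append(spearmanr(truth_m, pred["predicted"]).statistic)
        means.append(np.mean(rhos))
    assert means[0] > means[1] > means[2]


# ------------------------------------------------- cross experiment


def test_cross_experiment_consistency_with_and_without_batch_effect():
    for batch_sigma, floor in ((0.0, 0.95), (0.25, 0.7)):
        rhos = []
        for seed in range(10):
            design = CohortDesign(batch_sigma=batch_sigma, seed=seed + 50)
            table, meta, _ = simulate_cohort(design)
            rel, pairs, measured = cohort_mucosity(table, meta)
            s1 = study_swabs(meta, pairs, "exp1")
            s2 = study_swabs(meta, pairs, "exp2")
            model1 = fit_mucosity_space(rel.select_samples(s1), measured)
            model2 = fit_mucosity_space(rel.select_samples(s2), measured)
            within = predict_mucosity(model2, rel.select_samples(s2)).frame
            within_s = within.set_index("sample_id")["predicted"]
            _, rho = cross_experiment_predict(
                model1, rel.select_samples(s2), measured, within_predictions=within_s
            )
            rhos.append(rho)
        assert np.mean(rhos) >= floor


def test_cross_experiment_self_projection_matches_predict(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    s1 = study_swabs(meta, pairs, "exp1")
    model = fit_mucosity_space(rel.select_samples(s1), measured)
    direct = predict_mucosity(model, rel.select_samples(s1), measured)
    crossed, _ = cross_experiment_predict(model, rel.select_samples(s1), measured)
    np.testing.assert_allclose(
        crossed.frame["predicted"].to_numpy(), direct.frame["predicted"].to_numpy(), atol=1e-12
    )


def test_cross_experiment_overlap_floor(default_cohort):
    _, table, meta, _ = default_cohort
    rel, pairs, measured = cohort_mucosity(table, meta)
    s1 = study_swabs(meta, pairs, "exp1")
    model = fit_mucosity_space(rel.select_samples(s1), measured)
    few = rel.select_samples(s1)
    # keep only a quarter of the genera
    keep = list(few.taxon_ids[: len(few.taxon_ids) // 4])
    vals = few.to_dataframe()[keep]
    vals = vals.div(vals.sum(axis=1), axis=0)
    from mucoswab.tablesio import RelativeAbundanceTable

    small = RelativeAbundanceTable(few.sample_ids, tuple(keep), vals.to_numpy())
    with pytest.raises(ValueError, match="overlap"):
        cross_experiment_predict(model, small, measured)


# ------------------------------------------------------- diet pRDA


def test_diet_effect_detected_and_directional():
    design = CohortDesign(seed=4, ef_suppression=0.3)
    table, meta, _ = simulate_cohort(design)
    rel, pairs, measured = cohort_mucosity(table, meta)
    swabs = table.select_samples([p.swab_id for p in pairs.paired])
    model, contrasts = diet_effect_prda(swabs, meta, measured, n_perm=199, seed=1)
    assert model.permutation_p < 0.05
    dom = model.taxon_ids.index(design.dominant_taxon)
    assert model.response_scores[dom, 0] < 0  # suppressed in EF -> CON side
    row = contrasts.set_index("taxon_id").loc[design.dominant_taxon]
    assert row["median_a"] < row["median_b"]  # EF median below CON median


def test_diet_effect_shuffled_labels_destroy_effect():
    design = CohortDesign(seed=4, ef_suppression=0.3)
    table, meta, _ = simulate_cohort(design)
    rel, pairs, measured = cohort_mucosity(table, meta)
    swab_ids = [p.swab_id for p in pairs.paired]
    swabs = table.select_samples(swab_ids)
    rng = np.random.default_rng(99)
    null_ps = []
    for rep in range(20):
        df = meta.frame.copy()
        swab_mask = df["sample_id"].isin(swab_ids)
        labels = df.loc[swab_mask, "treatment"].to_numpy()
        df.loc[swab_mask, "treatment"] = rng.permutation(labels)
        shuffled = SampleMetadata(df)
        model, _ = diet_effect_prda(swabs, shuffled, measured, n_perm=199, seed=rep)
        null_ps.append(model.permutation_p)
    assert np.mean(np.array(null_ps) > 0.05) >= 0.9


def test_diet_effect_single_study_warns():
    design = CohortDesign(studies=("exp1",), n_animals_per_arm=(14,), seed=8)
    table, meta, _ = simulate_cohort(design)
    rel, pairs, measured = cohort_mucosity(table, meta)
    swabs = table.select_samples([p.swab_id for p in pairs.paired])
    with pytest.warns(UserWarning, match="single-study"):
        model, _ = diet_effect_prda(swabs, meta, measured, n_perm=199, seed=0)
    assert model.covariate_names == ("mucosity",)


# ------------------------------------------------- eating correlation


def _eating_fixture(scores, abundances):
    n = len(scores)
    ids = [f"a{i}_S" for i in range(n)]
    counts = np.column_stack(
        [np.round(abundances * 1000).astype(int) + 1, np.full(n, 1000, dtype=int)]
    )
    table = AbundanceTable(tuple(ids), ("target", "other"), counts)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ids,
                "animal_id": [f"a{i}" for i in range(n)],
                "sample_type": ["swab"] * n,
                "treatment": ["EF"] * n,
                "study": ["exp1"] * n,
                "eating_score": scores,
            }
        )
    )
    return table, meta


def test_eating_correlation_perfect_monotone_is_minus_one():
    rng = np.random.default_rng(17)
    abundances = rng.uniform(0.05, 0.5, size=10)
    # score exactly proportional to -(realised relative abundance)
    counts = np.round(abundances * 1000).astype(int) + 1
    realised = counts / (counts + 1000)
    scores = 100 - 100 * realised
    table, meta = _eating_fixture(scores, abundances)
    method, coef, p, label = eating_correlation(meta, table, "target")
    assert coef == pytest.approx(-1.0, abs=1e-9)
    assert label == "significant"


def test_eating_correlation_heavy_tails_use_spearman():
    rng = np.random.default_rng(18)
    scores = np.exp(rng.normal(0, 2.0, size=14))  # strongly log-normal
    abundances = rng.uniform(0.05, 0.5, size=14)
    table, meta = _eating_fixture(scores, abundances)
    method, *_ = eating_correlation(meta, table, "target")
    assert method == "spearman"


def test_eating_correlation_null_calibration():
    rng = np.random.default_rng(19)
    coefs, rejections = [], 0
    for _ in range(200):
        scores = rng.uniform(10, 60, size=14)
        abundances = rng.uniform(0.05, 0.5, size=14)
        table, meta = _eating_fixture(scores, abundances)
        _, coef, p, _ = eating_correlation(meta, table, "target")
        coefs.append(abs(coef))
        rejections += p < 0.05
    assert np.median(coefs) < 0.3
    assert rejections / 200 <= 0.10


def test_eating_correlation_needs_observations(default_cohort):
    _, table, meta, _ = default_cohort
    df = meta.frame.copy()
    df["eating_score"] = np.nan
    with pytest.raises(ValueError, match="at least 5"):
        eating_correlation(SampleMetadata(df), table, "Escherichia-Shigella")


def test_eating_correlation_negative_on_synthetic_cohort(default_cohort):
    """More feed foraging, less of the dominant adhered genus."""
    coefs = []
    for seed in range(5):
        table, meta, _ = simulate_cohort(CohortDesign(seed=seed, ef_suppression=0.3))
        _, coef, _, _ = eating_correlation(meta, table, "Escherichia-Shigella")
        coefs.append(coef)
    assert np.mean(coefs) < -0.3
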