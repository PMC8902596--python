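"""Measure, model and predict the mucosity factor of rectal swabs.

Pipeline: (1) measure each paired swab's mucosity factor — its (squared)
Bray-Curtis distance to the colon sample of the same animal; (2) fit an RDA
of swab composition constrained by that single continuous variable, giving a
one-axis "mucosity space"; (3) place any further swab (same study or a
replicate study) into that space as a supplementary sample and read off its
axis-1 CaseR score as the *predicted* mucosity factor; (4) validate by rank
correlation against measured values where both exist. A partial RDA
corrected for mucosity and study then isolates the diet (EF vs CON) effect
on swab composition from the nuisance variation in how much adhered
material each swab happened to collect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, shapiro, spearmanr

from . import statsreport
from .divdist import mucosity_measured
from .ordination import (
    OrdinationModel,
    design_matrix,
    discriminant_taxa,
    prda,
    project_supplementary,
    rda,
)
from .tablesio import PairMap, SampleMetadata, to_relative

MIN_VALIDATION_N = 5


@dataclass(frozen=True)
class MucosityAssessment:
    """Measured and predicted mucosity per swab, with validation."""

    frame: pd.DataFrame  # sample_id, measured, predicted, source
    validation_rho: float | None
    validation_p: float | None
    model: OrdinationModel

    def __post_init__(self) -> None:
        required = {"sample_id", "measured", "predicted", "source"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"assessment frame must contain {sorted(required)}")
        if self.frame["predicted"].isna().any():
            raise ValueError("every swab must receive a predicted mucosity")

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def _validate(frame: pd.DataFrame) -> tuple[float | None, float | None]:
    both = frame.dropna(subset=["measured", "predicted"])
    if len(both) < MIN_VALIDATION_N:
        return None, None
    rho, p = spearmanr(both["measured"], both["predicted"])
    return float(rho), float(p)


def fit_mucosity_space(
    swab_table,
    mucosity: pd.Series,
    n_perm: int | None = None,
    seed: int | None = None,
) -> OrdinationModel:
    """RDA of paired-swab composition on the measured mucosity factor.

    ``swab_table`` must contain paired swabs only and ``mucosity`` a value
    for each of them. The single constrained axis is oriented so higher
    scores mean higher mucosity.
    """
    ids = list(swab_table.sample_ids)
    if len(ids) < 8:
        raise ValueError("need at least 8 paired swabs to build a mucosity space")
    missing = [s for s in ids if s not in mucosity.index or pd.isna(mucosity.get(s))]
    if missing:
        raise ValueError(f"missing mucosity value for swabs: {missing[:5]}")
    x = mucosity.loc[ids].astype(float).rename("mucosity")
    return rda(swab_table, x, n_perm=n_perm, seed=seed)


def predict_mucosity(
    model: OrdinationModel,
    swab_table,
    measured: pd.Series | None = None,
    source: str = "supplementary",
) -> MucosityAssessment:
    """Predicted mucosity factor (axis-1 CaseR score) for any swab samples.

    Samples that were part of the training set are flagged ``trained``; the
    validation Spearman correlation is computed over samples that also carry
    a measured value (when at least five do).
    """
    scores = project_supplementary(model, swab_table)
    trained = set(model.sample_ids)
    frame = pd.DataFrame(
        {
            "sample_id": scores.index,
            "measured": [
                float(measured[s]) if measured is not None and s in measured.index and pd.notna(measured[s]) else np.nan
                for s in scores.index
            ],
            "predicted": scores.iloc[:, 0].to_numpy(),
            "source": [("trained" if s in trained else source) for s in scores.index],
        }
    ).reset_index(drop=True)
    rho, p = _validate(frame)
    return MucosityAssessment(frame, rho, p, model)


def cross_experiment_predict(
    model: OrdinationModel,
    swab_table,
    measured: pd.Series | None = None,
    within_predictions: pd.Series | None = None,
    min_overlap: float = 0.5,
) -> tuple[MucosityAssessment, float | None]:
    """Project another experiment's swabs into an existing mucosity space.

    Taxa are harmonised by genus-label intersection; a warning is raised if
    more than 25% of the training taxa are absent and an error if the
    overlap falls below ``min_overlap``. When ``within_predictions`` (the
    swabs' predicted mucosity from their own study's space) is supplied, the
    Spearman correlation between within- and cross-study predictions is
    returned alongside the assessment.
    """
    new_taxa = set(swab_table.taxon_ids)
    overlap = [t for t in model.taxon_ids if t in new_taxa]
    frac = len(overlap) / len(model.taxon_ids)
    if frac < min_overlap:
        raise ValueError(
            f"taxon overlap {frac:.0%} below the {min_overlap:.0%} floor; "
            "refusing cross-experiment projection"
        )
    if frac < 0.75:
        warnings.warn(
            f"cross-experiment projection loses {1 - frac:.0%} of training taxa",
            stacklevel=2,
        )
    assessment = predict_mucosity(model, swab_table, measured, source="cross_experiment")
    rho = None
    if within_predictions is not None:
        merged = assessment.frame.set_index("sample_id")["predicted"]
        common = merged.index.intersection(within_predictions.index)
        if len(common) >= MIN_VALIDATION_N:
            rho = float(spearmanr(merged.loc[common], within_predictions.loc[common]).statistic)
    return assessment, rho


def diet_effect_prda(
    table,
    meta: SampleMetadata,
    mucosity: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    response_threshold: float = 0.60,
) -> tuple[OrdinationModel, pd.DataFrame]:
    """Diet (EF vs CON) effect on swab composition, corrected for mucosity
    and study.

    Fits pRDA with the treatment indicator as the constraint and the
    measured mucosity factor (plus study indicators, when more than one
    study is present) as covariates. Returns the fitted model and a
    per-taxon EF-vs-CON Mann-Whitney contrast table.
    """
    df = meta.frame.set_index("sample_id")
    swab_ids = [s for s in table.sample_ids if df.loc[s, "sample_type"] == "swab"]
    if not swab_ids:
        raise ValueError("no swab samples in input")
    swabs = table.select_samples(swab_ids)
    missing = [s for s in swab_ids if s not in mucosity.index or pd.isna(mucosity.get(s))]
    if missing:
        raise ValueError(f"swabs without measured mucosity: {missing[:5]}")
    sub = df.loc[swab_ids]
    if sub["treatment"].nunique() < 2:
        raise ValueError("both treatment levels must be present")
    X = design_matrix(sub["treatment"], "treatment")
    W = pd.DataFrame({"mucosity": mucosity.loc[swab_ids].astype(float).to_numpy()}, index=sub.index)
    single_study = sub["study"].nunique() < 2
    if single_study:
        warnings.warn("single-study input: correcting for mucosity only", stacklevel=2)
    else:
        W = pd.concat([W, design_matrix(sub["study"], "study")], axis=1)
    model = prda(swabs, X, W, n_perm=n_perm, seed=seed)
    rel = to_relative(swabs) if hasattr(swabs, "counts") else swabs
    contrasts = statsreport.taxon_contrasts(
        rel, sub["treatment"], group_a="EF", group_b="CON"
    )
    disc = dict(discriminant_taxa(model, threshold=response_threshold))
    contrasts["response_score"] = [
        model.response_scores[model.taxon_ids.index(t), 0] for t in contrasts["taxon_id"]
    ]
    contrasts["discriminant"] = contrasts["taxon_id"].isin(disc)
    return model, contrasts


def eating_correlation(
    meta: SampleMetadata, table, taxon: str
) -> tuple[str, float, float, str]:
    """Correlation between EF animals' eating scores and a genus's relative
    abundance in their swabs.

    Uses Pearson when both variables pass a Shapiro-Wilk normality test at
    alpha = 0.05 and Spearman otherwise. Returns (method, coefficient, p,
    significance label).
    """
    rel = to_relative(table) if hasattr(table, "counts") else table
    if taxon not in rel.taxon_ids:
        raise KeyError(f"taxon {taxon!r} not in table")
    j = rel.taxon_ids.index(taxon)
    df = meta.frame.set_index("sample_id")
    ids = [
        s
        for s in rel.sample_ids
        if df.loc[s, "sample_type"] == "swab"
        and df.loc[s, "treatment"] == "EF"
        and pd.notna(df.loc[s, "eating_score"])
    ]
    if len(ids) < 5:
        raise ValueError("need at least 5 EF swabs with eating scores")
    rows = [rel.sample_ids.index(s) for s in ids]
    abund = rel.values[rows, j]
    scores = df.loc[ids, "eating_score"].astype(float).to_numpy()
    normal = (
        shapiro(scores).pvalue > 0.05
        and shapiro(abund).pvalue > 0.05
        and np.ptp(abund) > 0
        and np.ptp(scores) > 0
    )
    if normal:
        res = pearsonr(scores, abund)
        method = "pearson"
    else:
        res = spearmanr(scores, abund)
        method = "spearman"
    coef = float(res.statistic if hasattr(res, "statistic") else res[0])
    p = float(res.pvalue if hasattr(res, "pvalue") else res[1])
    return method, coef, p, statsreport.significance_label(p)


def measure_and_fit(
    table,
    meta: SampleMetadata,
    pairs: PairMap | None = None,
    squared: bool = True,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[pd.Series, OrdinationModel, MucosityAssessment]:
    """Convenience wrapper: measure mucosity, fit the space on paired swabs,
    and predict for every swab in the table."""
    from .tablesio import pair_samples

    rel = to_relative(table) if hasattr(table, "counts") else table
    if pairs is None:
        pairs = pair_samples(meta)
    measured = mucosity_measured(rel, pairs, squared=squared)
    paired_ids = [p.swab_id for p in pairs.paired]
    model = fit_mucosity_space(rel.select_samples(paired_ids), measured, n_perm=n_perm, seed=seed)
    df = meta.frame
    swab_ids = [s for s in rel.sample_ids if df.set_index("sample_id").loc[s, "sample_type"] == "swab"]
    assessment = predict_mucosity(model, rel.select_samples(swab_ids), measured)
    return measured, model, assessment
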