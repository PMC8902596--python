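"""Univariate statistics, significance labelling, clustering, reporting.

Conventions: P < 0.05 is *significant*, 0.1 > P >= 0.05 is a *trend*, and
everything else is *ns*. Per-taxon contrasts use the Mann-Whitney U test on
relative abundances with no multiple-testing correction; a
Benjamini-Hochberg q-value is appended as an extra column for readers who
want one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import false_discovery_control, mannwhitneyu, spearmanr

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # combined group size up to which the exact null is enumerated


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    The exact null distribution is enumerated when the combined sample size
    is at most 12 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= EXACT_MAX_N and no_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def significance_label(p: float) -> str:
    """Map a p-value to 'significant' (<0.05), 'trend' ([0.05, 0.1)), 'ns'."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "ns"


@dataclass(frozen=True)
class HclustOrder:
    """Leaf orders and merge heights of a UPGMA clustering."""

    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    row_heights: tuple[float, ...]
    col_heights: tuple[float, ...]


def _upgma(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if matrix.shape[0] < 2:
        return np.array([0], dtype=int), np.array([])
    Z = linkage(pdist(matrix, metric="euclidean"), method="average")
    return leaves_list(Z), Z[:, 2]


def hclust_order(matrix) -> HclustOrder:
    """Agglomerative clustering (Euclidean distance, average linkage/UPGMA)
    of rows and columns; returns leaf orders and merge heights for heat-map
    layout. Ties break deterministically by smallest index (scipy's
    convention on equal distances)."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(M).any():
        raise ValueError("matrix contains NaN")
    row_order, row_h = _upgma(M)
    col_order, col_h = _upgma(M.T)
    return HclustOrder(
        tuple(int(i) for i in row_order),
        tuple(int(i) for i in col_order),
        tuple(float(h) for h in row_h),
        tuple(float(h) for h in col_h),
    )


def taxon_contrasts(rel_table, groups: pd.Series, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-taxon Mann-Whitney contrast of relative abundances between two
    groups, with medians, significance labels and (extra, not part of the
    original analysis convention) BH q-values."""
    ids = list(rel_table.sample_ids)
    g = groups.loc[ids].astype(str)
    mask_a = (g == group_a).to_numpy()
    mask_b = (g == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    values = rel_table.values
    records = []
    for j, taxon in enumerate(rel_table.taxon_ids):
        a = values[mask_a, j]
        b = values[mask_b, j]
        if np.ptp(np.concatenate([a, b])) == 0:  # constant taxon: no contrast
            u, p = a.size * b.size / 2, 1.0
        else:
            u, p = mann_whitney(a, b)
        records.append(
            {
                "taxon_id": taxon,
                "group_a": group_a,
                "group_b": group_b,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "U": u,
                "p_value": p,
                "label": significance_label(p),
            }
        )
    out = pd.DataFrame.from_records(records)
    out["q_value_bh"] = false_discovery_control(out["p_value"], method="bh")
    return out


def swab_colon_contrast(
    table,
    meta,
    mucosity: pd.Series | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
    response_threshold: float = 0.60,
):
    """Sample-type (swab vs colon) RDA plus per-taxon contrasts.

    Fits RDA of the pooled composition on the sample-type indicator, lists
    discriminant taxa (|response score| > threshold, swab side positive),
    tests each taxon swab-vs-colon by Mann-Whitney, and — when measured
    mucosity values are given — reports each taxon's Spearman correlation
    between its swab relative abundance and the swab's mucosity factor.

    Returns (OrdinationModel, contrast DataFrame).
    """
    from .ordination import design_matrix, discriminant_taxa, rda
    from .tablesio import to_relative

    rel = to_relative(table) if hasattr(table, "counts") else table
    df = meta.frame.set_index("sample_id")
    stype = df.loc[list(rel.sample_ids), "sample_type"]
    if stype.nunique() < 2:
        raise ValueError("both sample types must be present")
    X = design_matrix(stype, "sample_type")  # indicator is 1 for swab
    model = rda(rel, X, n_perm=n_perm, seed=seed)
    contrasts = taxon_contrasts(rel, stype, group_a="swab", group_b="colon")
    disc = dict(discriminant_taxa(model, threshold=response_threshold))
    contrasts["response_score"] = [
        model.response_scores[model.taxon_ids.index(t), 0] for t in contrasts["taxon_id"]
    ]
    contrasts["discriminant"] = contrasts["taxon_id"].isin(disc)
    if mucosity is not None:
        swab_ids = [s for s in rel.sample_ids if stype.loc[s] == "swab" and s in mucosity.index and pd.notna(mucosity[s])]
        rows = [rel.sample_ids.index(s) for s in swab_ids]
        m = mucosity.loc[swab_ids].to_numpy(dtype=float)
        rhos, ps = [], []
        for j in range(len(rel.taxon_ids)):
            col = rel.values[rows, j]
            if np.ptp(col) == 0 or np.ptp(m) == 0:
                rhos.append(np.nan)
                ps.append(np.nan)
            else:
                r = spearmanr(col, m)
                rhos.append(float(r.statistic))
                ps.append(float(r.pvalue))
        contrasts["mucosity_spearman_rho"] = rhos
        contrasts["mucosity_spearman_p"] = ps
    return model, contrasts


@dataclass(frozen=True)
class ReportConfig:
    """Inputs and knobs for the end-to-end report."""

    abundance_path: str
    metadata_path: str
    out_dir: str
    squared: bool = True
    n_perm: int = 999
    seed: int = 0
    response_threshold: float = 0.60
    heatmap_top_n: int = 20


def run_report(config: ReportConfig) -> dict:
    """End-to-end pipeline: pairing, mucosity, spaces, diet analysis,
    contrasts, heat-map ordering. Writes every table as TSV under
    ``config.out_dir`` plus a log and a human-readable summary; returns a
    dict of the headline numbers. Any stage failure aborts with the stage
    name in the error."""
    from . import mucosity as muc
    from .divdist import mucosity_measured, write_mucosity
    from .tablesio import pair_samples, read_abundance, read_metadata, to_relative

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "report.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mucoswab")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "n_perm": config.n_perm, "squared": config.squared}

    def stage(name):
        logger.info("stage: %s", name)
        summary["last_stage"] = name

    try:
        stage("read")
        for path in (config.abundance_path, config.metadata_path):
            if not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
        table = read_abundance(config.abundance_path)
        meta = read_metadata(config.metadata_path)
        meta.require_covers(table)
        rel = to_relative(table)

        stage("pair")
        pairs = pair_samples(meta)
        summary["n_paired"] = len(pairs.paired)
        summary["n_unpaired_swabs"] = len(pairs.unpaired)

        stage("mucosity")
        measured = mucosity_measured(rel, pairs, squared=config.squared)
        write_mucosity(measured, out / "mucosity_measured.tsv")

        stage("sample_type_rda")
        st_model, st_contrasts = swab_colon_contrast(
            rel, meta, mucosity=measured, n_perm=config.n_perm, seed=config.seed,
            response_threshold=config.response_threshold,
        )
        st_model.save(out / "sample_type_rda")
        st_contrasts.to_csv(out / "swab_colon_contrasts.tsv", sep="\t", index=False,
                            na_rep="NA", float_format="%.10g")
        summary["sample_type_adjusted_variation"] = st_model.adjusted_variation
        summary["sample_type_permutation_p"] = st_model.permutation_p

        stage("mucosity_space")
        paired_ids = [p.swab_id for p in pairs.paired]
        model = muc.fit_mucosity_space(
            rel.select_samples(paired_ids), measured,
            n_perm=config.n_perm, seed=config.seed,
        )
        model.save(out / "mucosity_rda")
        df = meta.frame.set_index("sample_id")
        swab_ids = [s for s in rel.sample_ids if df.loc[s, "sample_type"] == "swab"]
        assessment = muc.predict_mucosity(model, rel.select_samples(swab_ids), measured)
        assessment.write(out / "mucosity_assessment.tsv")
        summary["mucosity_adjusted_variation"] = model.adjusted_variation
        summary["mucosity_permutation_p"] = model.permutation_p
        summary["validation_spearman_rho"] = assessment.validation_rho
        summary["validation_spearman_p"] = assessment.validation_p

        stage("diet_prda")
        swab_counts = table.select_samples(swab_ids)
        if df.loc[swab_ids, "treatment"].nunique() == 2 and all(
            s in measured.index and pd.notna(measured[s]) for s in swab_ids
        ):
            diet_model, diet_contrasts = muc.diet_effect_prda(
                swab_counts, meta, measured, n_perm=config.n_perm, seed=config.seed,
                response_threshold=config.response_threshold,
            )
            diet_model.save(out / "diet_prda")
            diet_contrasts.to_csv(out / "diet_contrasts.tsv", sep="\t", index=False,
                                  na_rep="NA", float_format="%.10g")
            summary["diet_adjusted_variation"] = diet_model.adjusted_variation
            summary["diet_permutation_p"] = diet_model.permutation_p
        else:
            logger.info("diet pRDA skipped: needs both treatments and full pairing")

        stage("heatmap")
        swab_rel = rel.select_samples(swab_ids)
        top = (
            st_contrasts.assign(absr=st_contrasts["response_score"].abs())
            .nlargest(config.heatmap_top_n, "absr")["taxon_id"]
            .tolist()
        )
        mat = pd.DataFrame(
            swab_rel.values, index=list(swab_rel.sample_ids), columns=list(swab_rel.taxon_ids)
        )[top].T  # taxa x samples
        order = hclust_order(mat.to_numpy())
        clustered = mat.iloc[list(order.row_order), list(order.col_order)]
        clustered.rename_axis("taxon_id").to_csv(
            out / "heatmap_matrix.tsv", sep="\t", float_format="%.10g"
        )

        stage("summary")
        with open(out / "summary.txt", "w") as fh:
            fh.write("mucoswab report\n===============\n")
            for k, v in summary.items():
                fh.write(f"{k}: {v}\n")
        return summary
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"report failed at stage {summary.get('last_stage')!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
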