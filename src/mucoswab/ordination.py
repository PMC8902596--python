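"""Unconstrained (PCA, PCoA) and constrained (RDA, pRDA) ordination.

Redundancy analysis (RDA) is a PCA of the fitted values of a multivariate
least-squares regression of the (column-centered) response matrix Y on a
constraint matrix X. The partial form (pRDA) first residualises both Y and
X on a covariate block W. Significance is assessed by a Monte-Carlo
permutation test on a pseudo-F statistic; explained variation is adjusted
with Ezekiel's formula.

Score conventions (frozen; downstream use is rank/correlation based):

* sample scores derived from the response variables ("CaseR") are the
  projection of centered Y onto the constrained axes, rescaled so training
  CaseR scores have unit variance per axis;
* fitted sample scores ("CaseE") are the projection of the fitted values
  onto the same axes, with the same rescaling;
* response (taxon) scores are Pearson correlations between each response
  column and the fitted axis scores, so they live in [-1, 1], a
  "response score > 0.60" cut-off reads as a correlation threshold, and a
  constraint that explains nothing yields uniformly small scores;
* each constrained axis is oriented so that it correlates non-negatively
  with its dominant constraint, making axis signs deterministic.

Supplementary samples are projected passively: the stored training means
(and axes) are applied to new rows, which therefore never influence the
ordination space itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tablesio import AbundanceTable, RelativeAbundanceTable
from .divdist import DistanceMatrix

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class OrdinationModel:
    """Fitted ordination: axes, scores, eigenvalues and fit statistics."""

    method: str  # "pca" | "rda" | "prda"
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    centering_means: np.ndarray  # per-taxon training means (proportions)
    scaling_divisors: np.ndarray | None  # per-taxon divisors, or None
    axes: np.ndarray  # taxa x axes orthonormal basis (projection axes)
    case_r_scale: np.ndarray  # per-axis divisor giving unit-variance CaseR
    response_scores: np.ndarray  # taxa x axes correlations
    case_r_scores: np.ndarray  # samples x axes
    case_e_scores: np.ndarray  # samples x axes (fitted/constrained)
    eigenvalues: np.ndarray  # per-axis variance explained
    total_variance: float
    explained_variation: float
    adjusted_variation: float
    permutation_p: float | None
    pseudo_f: float | None
    n_constrained_axes: int
    constraint_names: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if self.method in ("rda", "prda") and np.any(ev < -1e-12):
            raise ValueError("constrained eigenvalues must be non-negative")
        if not (-1e-12 <= self.explained_variation <= 1 + 1e-12):
            raise ValueError("explained_variation must lie in [0, 1]")
        if self.constraint_names and self.n_constrained_axes > len(self.constraint_names):
            raise ValueError("more constrained axes than constraints")

    def save(self, directory) -> None:
        """Serialise scores, loadings, eigenvalues and a fit summary as TSVs."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        taxa = pd.Index(list(self.taxon_ids), name="taxon_id")
        samples = pd.Index(list(self.sample_ids), name="sample_id")
        axes = [f"axis{i + 1}" for i in range(self.axes.shape[1])]
        pd.DataFrame(self.response_scores, index=taxa, columns=axes).to_csv(
            d / "response_scores.tsv", sep="\t", float_format="%.10g"
        )
        pd.DataFrame(self.case_r_scores, index=samples, columns=axes).to_csv(
            d / "case_r_scores.tsv", sep="\t", float_format="%.10g"
        )
        pd.DataFrame(self.case_e_scores, index=samples, columns=axes).to_csv(
            d / "case_e_scores.tsv", sep="\t", float_format="%.10g"
        )
        pd.DataFrame(
            {"taxon_id": list(self.taxon_ids), "centering_mean": self.centering_means}
        ).to_csv(d / "centering.tsv", sep="\t", index=False, float_format="%.10g")
        pd.DataFrame(self.axes, index=taxa, columns=axes).to_csv(
            d / "axes.tsv", sep="\t", float_format="%.10g"
        )
        summary = {
            "method": self.method,
            "n_samples": len(self.sample_ids),
            "n_taxa": len(self.taxon_ids),
            "n_constrained_axes": self.n_constrained_axes,
            "constraints": ",".join(self.constraint_names),
            "covariates": ",".join(self.covariate_names),
            "eigenvalues": ",".join(f"{e:.10g}" for e in self.eigenvalues),
            "total_variance": f"{self.total_variance:.10g}",
            "explained_variation": f"{self.explained_variation:.10g}",
            "adjusted_variation": f"{self.adjusted_variation:.10g}",
            "pseudo_f": "NA" if self.pseudo_f is None else f"{self.pseudo_f:.10g}",
            "permutation_p": "NA" if self.permutation_p is None else f"{self.permutation_p:.10g}",
        }
        with open(d / "fit_summary.tsv", "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in summary.items():
                fh.write(f"{k}\t{v}\n")


@dataclass(frozen=True)
class PcoaResult:
    """Classical scaling of a dissimilarity matrix."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # over positive eigenvalues


def as_relative_values(table) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Sample ids, taxon ids and a row-stochastic value matrix from either table type."""
    if isinstance(table, AbundanceTable):
        values = table.counts / table.counts.sum(axis=1, keepdims=True)
        return table.sample_ids, table.taxon_ids, values
    if isinstance(table, RelativeAbundanceTable):
        return table.sample_ids, table.taxon_ids, np.asarray(table.values, dtype=float)
    # generic response matrices (e.g. simulation studies) are used as-is
    if isinstance(table, pd.DataFrame):
        return (
            tuple(map(str, table.index)),
            tuple(map(str, table.columns)),
            table.to_numpy(dtype=float),
        )
    arr = np.asarray(table, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise TypeError(f"expected an abundance table or 2-D matrix, got {type(table).__name__}")
    n, g = arr.shape
    return (
        tuple(f"s{i + 1}" for i in range(n)),
        tuple(f"y{j + 1}" for j in range(g)),
        arr,
    )


def design_matrix(values: pd.Series, name: str) -> pd.DataFrame:
    """Centered 0/1 indicator columns for a factor; reference level is the
    lexicographically first. A numeric series is passed through centered."""
    if pd.api.types.is_numeric_dtype(values):
        col = values.astype(float)
        return pd.DataFrame({name: col - col.mean()})
    levels = sorted(values.astype(str).unique())
    cols = {}
    for level in levels[1:]:
        ind = (values.astype(str) == level).astype(float)
        cols[f"{name}[{level}]"] = ind - ind.mean()
    return pd.DataFrame(cols, index=values.index)


def _center(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = M.mean(axis=0)
    return M - means, means


def _residualise(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residuals of M after least-squares regression on W (already centered)."""
    coef, *_ = np.linalg.lstsq(W, M, rcond=None)
    return M - W @ coef


def _corr_columns(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with v; 0 for constant columns."""
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Mc.T @ vc / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def adjust_variation(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - r2)(n - 1)/(n - p - 1), floored at 0."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if n <= p + 1:
        raise ValueError("need n > p + 1 samples for the adjustment")
    return max(0.0, 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def pca(table, n_axes: int | None = None) -> OrdinationModel:
    """Principal component analysis of a (relative) abundance table.

    Columns are centered (not standardised); eigenvalues are squared singular
    values over n - 1. Axis signs are fixed by orienting each loading vector
    so its largest-magnitude entry is positive.
    """
    sample_ids, taxon_ids, Y = as_relative_values(table)
    n, g = Y.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 samples")
    Yc, means = _center(Y)
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    k = int((S > _RANK_TOL * max(S[0], 1)).sum()) if S.size else 0
    if n_axes is not None:
        k = min(k, n_axes)
    U, S, V = U[:, :k], S[:k], Vt[:k].T
    # deterministic sign: largest-|loading| entry of each axis positive
    for a in range(k):
        j = int(np.argmax(np.abs(V[:, a])))
        if V[j, a] < 0:
            V[:, a] *= -1
            U[:, a] *= -1
    eig = S**2 / (n - 1)
    scores_raw = U * S
    scale = scores_raw.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    scores = scores_raw / scale
    resp = np.column_stack([_corr_columns(Yc, scores_raw[:, a]) for a in range(k)]) if k else np.zeros((g, 0))
    total = float((Yc**2).sum() / (n - 1))
    return OrdinationModel(
        method="pca",
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        centering_means=means,
        scaling_divisors=None,
        axes=V,
        case_r_scale=scale,
        response_scores=resp,
        case_r_scores=scores,
        case_e_scores=scores,
        eigenvalues=eig,
        total_variance=total,
        explained_variation=1.0,
        adjusted_variation=1.0,
        permutation_p=None,
        pseudo_f=None,
        n_constrained_axes=0,
    )


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis (classical scaling, Gower centering).

    The supplied dissimilarities are squared, double-centered and
    eigendecomposed; coordinates come from the positive eigenvalues while
    negative eigenvalues are reported rather than silently dropped.
    """
    D = dist.values
    n = D.shape[0]
    A = -0.5 * D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals[0], 0) * 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for a in range(coords.shape[1]):  # deterministic reflection
        j = int(np.argmax(np.abs(coords[:, a])))
        if coords[j, a] < 0:
            coords[:, a] *= -1
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return PcoaResult(dist.sample_ids, coords, eigvals, prop)


def _constrained_fit(
    Yc: np.ndarray,
    Xc: np.ndarray,
    Y_for_caser: np.ndarray,
    Y_for_response: np.ndarray,
    sample_ids,
    taxon_ids,
    means,
    constraint_names,
    covariate_names,
    method: str,
    n_covariates: int,
    n_perm: int | None,
    seed: int | None,
) -> OrdinationModel:
    """Shared RDA engine operating on pre-centered (and pre-residualised) data."""
    n, g = Yc.shape
    p = Xc.shape[1]
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} constraints")
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("constraint matrix is rank-deficient after centering")
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ coef
    ss_tot = float((Yc**2).sum())
    ss_fit = float((Yhat**2).sum())
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    k = int((S > _RANK_TOL * max(S[0], 1.0)).sum())
    k = min(k, p)
    U, S, V = U[:, :k], S[:k], Vt[:k].T
    case_e_raw = U * S
    # orient each axis non-negatively with its dominant constraint
    for a in range(k):
        r = _corr_columns(Xc, case_e_raw[:, a])
        j = int(np.argmax(np.abs(r)))
        if r[j] < 0:
            V[:, a] *= -1
            case_e_raw[:, a] *= -1
    case_r_raw = Y_for_caser @ V
    scale = case_r_raw.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    case_r = case_r_raw / scale
    case_e = case_e_raw / scale
    # response scores: correlation of each response column with the *fitted*
    # axis scores, so weak constraints yield uniformly small scores
    resp = (
        np.column_stack([_corr_columns(Y_for_response, case_e_raw[:, a]) for a in range(k)])
        if k
        else np.zeros((g, 0))
    )
    eig = S**2 / (n - 1)
    explained = ss_fit / ss_tot if ss_tot > 0 else 0.0
    if n - n_covariates > p + 1:
        adjusted = adjust_variation(min(explained, 1.0), n - n_covariates, p)
    else:  # saturated fit: the adjustment is undefined
        adjusted = min(explained, 1.0)
    pseudo_f = p_value = None
    if n_perm is not None:
        pseudo_f, p_value = _permute(Yc, Xc, n_covariates, n_perm, seed)
    return OrdinationModel(
        method=method,
        sample_ids=tuple(sample_ids),
        taxon_ids=tuple(taxon_ids),
        centering_means=means,
        scaling_divisors=None,
        axes=V,
        case_r_scale=scale,
        response_scores=resp,
        case_r_scores=case_r,
        case_e_scores=case_e,
        eigenvalues=eig,
        total_variance=ss_tot / (n - 1),
        explained_variation=min(explained, 1.0),
        adjusted_variation=adjusted,
        permutation_p=p_value,
        pseudo_f=pseudo_f,
        n_constrained_axes=k,
        constraint_names=tuple(constraint_names),
        covariate_names=tuple(covariate_names),
    )


def rda(
    table,
    X,
    constraint_names=None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> OrdinationModel:
    """Redundancy analysis of a (relative) abundance table on constraints X.

    X may be a DataFrame (column names kept) or array; columns are centered
    internally. ``n_perm`` switches on the Monte-Carlo permutation test.
    """
    sample_ids, taxon_ids, Y = as_relative_values(table)
    Xa, names = _as_matrix(X, "x")
    if Xa.shape[0] != Y.shape[0]:
        raise ValueError("constraint rows do not match samples")
    Yc, means = _center(Y)
    Xc, _ = _center(Xa)
    return _constrained_fit(
        Yc, Xc, Yc, Yc, sample_ids, taxon_ids, means, names, (), "rda", 0, n_perm, seed
    )


def prda(
    table,
    X,
    W,
    constraint_names=None,
    covariate_names=None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> OrdinationModel:
    """Partial RDA: residualise Y and X on covariates W, then RDA the residuals.

    Explained variation is reported as a fraction of the covariate-free
    (residual) variance. An empty W degenerates to plain RDA. CaseR scores
    remain projections of the centered (non-residualised) responses so that
    supplementary samples — for which covariates are unknown — are placed in
    the same way as training samples.
    """
    sample_ids, taxon_ids, Y = as_relative_values(table)
    Xa, xnames = _as_matrix(X, "x")
    Wa, wnames = _as_matrix(W, "w", allow_empty=True)
    if Wa.shape[1] == 0:
        return rda(table, X, n_perm=n_perm, seed=seed)
    Yc, means = _center(Y)
    Xc, _ = _center(Xa)
    Wc, _ = _center(Wa)
    if np.linalg.matrix_rank(Wc) < Wc.shape[1]:
        raise ValueError("covariate matrix is rank-deficient after centering")
    Xres = _residualise(Xc, Wc)
    if np.linalg.matrix_rank(np.column_stack([Wc, Xc])) < Wc.shape[1] + Xc.shape[1]:
        raise ValueError("constraints are collinear with covariates: nothing to test")
    Yres = _residualise(Yc, Wc)
    return _constrained_fit(
        Yres, Xres, Yc, Yres, sample_ids, taxon_ids, means,
        xnames, wnames, "prda", Wa.shape[1], n_perm, seed,
    )


def _as_matrix(X, prefix: str, allow_empty: bool = False):
    if X is None:
        if allow_empty:
            return np.zeros((0, 0)), ()
        raise ValueError("constraint matrix is required")
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    if isinstance(X, pd.Series):
        return X.to_numpy(dtype=float)[:, None], (str(X.name or prefix),)
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if Xa.ndim != 2:
        raise ValueError("constraints must be a vector or matrix")
    names = tuple(f"{prefix}{j + 1}" for j in range(Xa.shape[1]))
    return Xa, names


def _ss_fit(Yc: np.ndarray, Xc: np.ndarray) -> float:
    Q, _ = np.linalg.qr(Xc)
    return float(((Q.T @ Yc) ** 2).sum())


def _permute(
    Yc: np.ndarray, Xc: np.ndarray, q: int, n_perm: int, seed: int | None
) -> tuple[float, float]:
    """Pseudo-F and Monte-Carlo p for (residualised) Yc against Xc.

    Permutations are unrestricted row shuffles of the residualised
    constraints; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    n, p = Xc.shape
    dof_res = n - p - q - 1
    if dof_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_tot = float((Yc**2).sum())
    ss_fit = _ss_fit(Yc, Xc)
    f_obs = (ss_fit / p) / ((ss_tot - ss_fit) / dof_res)
    rng = np.random.default_rng(seed)
    if p == 1:
        x = Xc[:, 0]
        xx = float(x @ x)
        perms = np.empty((n_perm, n), dtype=np.intp)
        for i in range(n_perm):
            perms[i] = rng.permutation(n)
        M = x[perms] @ Yc  # n_perm x g
        ss_fit_perm = (M**2).sum(axis=1) / xx
    else:
        ss_fit_perm = np.empty(n_perm)
        for i in range(n_perm):
            ss_fit_perm[i] = _ss_fit(Yc, Xc[rng.permutation(n)])
    f_perm = (ss_fit_perm / p) / ((ss_tot - ss_fit_perm) / dof_res)
    p_value = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return float(f_obs), float(p_value)


def permutation_test(table, X, W=None, n_perm: int = 999, seed: int | None = None):
    """Monte-Carlo permutation test for (partial) RDA; returns (pseudo_F, p)."""
    _, _, Y = as_relative_values(table)
    Xa, _ = _as_matrix(X, "x")
    Yc, _ = _center(Y)
    Xc, _ = _center(Xa)
    q = 0
    if W is not None:
        Wa, _ = _as_matrix(W, "w", allow_empty=True)
        if Wa.shape[1]:
            Wc, _ = _center(Wa)
            Yc = _residualise(Yc, Wc)
            Xc = _residualise(Xc, Wc)
            q = Wa.shape[1]
    return _permute(Yc, Xc, q, n_perm, seed)


def project_supplementary(model: OrdinationModel, table) -> pd.DataFrame:
    """Passive CaseR scores for supplementary samples.

    Rows are aligned to the model's taxa (missing taxa become 0, extra taxa
    are dropped with a warning), converted to relative abundance over the
    model taxa, centered with the *training* means and projected onto the
    training axes with the training scaling. The new samples never alter the
    ordination space.
    """
    sample_ids, taxon_ids, values = as_relative_values(table)
    df = pd.DataFrame(values, index=list(sample_ids), columns=list(taxon_ids))
    extra = [t for t in taxon_ids if t not in model.taxon_ids]
    if extra:
        warnings.warn(
            f"{len(extra)} taxa absent from the ordination model were dropped",
            stacklevel=2,
        )
    aligned = df.reindex(columns=list(model.taxon_ids), fill_value=0.0)
    totals = aligned.to_numpy().sum(axis=1)
    if np.any(totals <= 0):
        bad = aligned.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} shares no taxa with the model")
    rel = aligned.to_numpy() / totals[:, None]
    centered = rel - model.centering_means
    if model.scaling_divisors is not None:
        centered = centered / model.scaling_divisors
    scores = centered @ model.axes / model.case_r_scale
    cols = [f"axis{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=pd.Index(list(sample_ids), name="sample_id"), columns=cols)


def discriminant_taxa(
    model: OrdinationModel, threshold: float = 0.60, axis: int = 0
) -> list[tuple[str, float]]:
    """Taxa whose |response score| on the given axis exceeds the threshold,
    sorted by decreasing magnitude."""
    scores = model.response_scores[:, axis]
    hits = [(t, float(s)) for t, s in zip(model.taxon_ids, scores) if abs(s) > threshold]
    return sorted(hits, key=lambda ts: -abs(ts[1]))
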