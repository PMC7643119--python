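"""Weighted protein co-expression analysis.

Implements the standard weighted-network workflow on a proteins x samples
matrix: soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|^xi`` with the power
chosen by the scale-free topology criterion, topological overlap, module
detection by average-linkage clustering of the TOM dissimilarity, module
eigengenes, protein significance ``PS_i = |cor(x_i, S)|^xi`` against the
status trait S, module membership ``MM = cor(x_i, E)``, the eigengene network
``A = 0.5 + 0.5 cor(E, E)`` / ``diss = 1 - cor(E, E)``, and candidate driver
selection.

The fitted surface is :class:`CoexpressionModel` / :class:`CoexpressionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datasets import ExpressionStudy

__all__ = [
    "CoexpressionConfig",
    "CoexpressionModel",
    "CoexpressionResults",
    "adjacency_matrix",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "node_statistics",
    "eigengene_network",
    "scale_free_fit",
    "pick_soft_threshold",
    "select_candidates",
]


@dataclass(frozen=True)
class CoexpressionConfig:
    """Tuning parameters of the co-expression workflow.

    ``soft_power`` is the exponent xi applied to absolute correlations
    (must be >= 1); ``tree_cut_quantile`` sets the fixed-height dendrogram
    cut at that quantile of the merge heights.
    """

    soft_power: float = 6.0
    scale_free_r2_cut: float = 0.85
    min_module_size: int = 30
    tree_cut_quantile: float = 0.5
    merge_dissimilarity_cut: float = 0.25
    signed: bool = False

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.scale_free_r2_cut < 1:
            raise ValueError("scale_free_r2_cut must lie in (0, 1)")
        if not 0 < self.tree_cut_quantile < 1:
            raise ValueError("tree_cut_quantile must lie in (0, 1)")


def _corrcoef_rows(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X)
    return np.clip(c, -1.0, 1.0)


def adjacency_matrix(
    expr: ExpressionStudy | np.ndarray,
    soft_power: float,
    signed: bool = False,
) -> np.ndarray:
    """Soft-thresholded co-expression adjacency ``|cor(x_i, x_j)|^xi``.

    Rows with zero variance have undefined correlations; they are kept in the
    matrix with zero off-diagonal adjacency and flagged by a warning so index
    alignment with the input is preserved.
    """
    if soft_power < 1:
        raise ValueError("soft power must be >= 1")
    X = expr.expression.to_numpy() if isinstance(expr, ExpressionStudy) else np.asarray(expr)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profiles; "
            "their adjacency rows are set to 0",
            stacklevel=2,
        )
    c = _corrcoef_rows(X)
    c[np.isnan(c)] = 0.0
    if signed:
        a = (0.5 + 0.5 * c) ** soft_power
    else:
        a = np.abs(c) ** soft_power
    a[degenerate, :] = 0.0
    a[:, degenerate] = 0.0
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity ``k_i = sum_{u != i} a_iu``; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    # (off @ off)_{ij} = sum_u a_iu a_uj already excludes u = i and u = j
    # because the diagonal of `off` is zero
    numer = off @ off + off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return 0.5 * (tom + tom.T)


def detect_modules(tom: np.ndarray, config: CoexpressionConfig) -> np.ndarray:
    """Cluster the TOM dissimilarity and label modules.

    Average-linkage hierarchical clustering of ``1 - TOM``, cut at the
    configured quantile of merge heights; clusters smaller than
    ``min_module_size`` fall into module 0 (the unassigned "grey" set).
    Labels are renumbered by decreasing module size, so the result is
    invariant (up to nothing at all) to protein ordering.
    """
    n = tom.shape[0]
    if n < config.min_module_size:
        return np.zeros(n, dtype=int)
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = 0.5 * (diss + diss.T)
    Z = linkage(squareform(diss, checks=False), method="average")
    cut = np.quantile(Z[:, 2], config.tree_cut_quantile)
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_id = 1
    for cluster_id, size in sizes.items():
        if size >= config.min_module_size:
            labels[raw == cluster_id] = next_id
            next_id += 1
    return labels


def module_eigengenes(
    expr: ExpressionStudy | np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """First right-singular vector of each module's standardized submatrix.

    Each eigengene is a unit-norm per-sample score, sign-oriented so that its
    mean correlation with the member profiles is positive. Module 0 (grey)
    gets no eigengene.
    """
    X = expr.expression.to_numpy() if isinstance(expr, ExpressionStudy) else np.asarray(expr)
    labels = np.asarray(labels)
    module_ids = sorted(set(labels) - {0})
    cols = {}
    for q in module_ids:
        sub = X[labels == q]
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sd
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        corr = sub @ e  # proportional to cor(x_i, e) since rows standardized
        if corr.mean() < 0:
            e = -e
        cols[q] = e / np.linalg.norm(e)
    index = (
        expr.expression.columns
        if isinstance(expr, ExpressionStudy)
        else pd.RangeIndex(X.shape[1])
    )
    return pd.DataFrame(cols, index=index)


def _cor_with_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    nv = np.linalg.norm(vc)
    if nv == 0:
        raise ValueError("correlation against a constant vector is undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ vc) / (nx * nv)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def node_statistics(
    expr: ExpressionStudy | np.ndarray,
    status_trait: np.ndarray,
    eigengenes: pd.DataFrame,
    labels: np.ndarray,
    soft_power: float,
) -> tuple[np.ndarray, pd.DataFrame, dict[int, float]]:
    """Protein significance, module membership, and module significance.

    ``PS_i = |cor(x_i, S)|^xi``; ``MM_q(i) = cor(x_i, E_q)``; the module
    significance of q is the mean PS over its members.
    """
    X = expr.expression.to_numpy() if isinstance(expr, ExpressionStudy) else np.asarray(expr)
    S = np.asarray(status_trait, dtype=float)
    if np.ptp(S) == 0:
        raise ValueError("status trait is constant; PS is undefined")
    ps = np.abs(_cor_with_vector(X, S)) ** soft_power
    mm = pd.DataFrame(
        {q: _cor_with_vector(X, eigengenes[q].to_numpy()) for q in eigengenes.columns}
    )
    labels = np.asarray(labels)
    module_sig = {
        int(q): float(ps[labels == q].mean()) for q in sorted(set(labels) - {0})
    }
    return ps, mm, module_sig


def eigengene_network(eigengenes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Eigengene adjacency ``A = 0.5 + 0.5 cor`` and dissimilarity ``1 - cor``."""
    if eigengenes.shape[1] < 2:
        raise ValueError("need at least two eigengenes")
    c = np.clip(np.corrcoef(eigengenes.to_numpy().T), -1.0, 1.0)
    return 0.5 + 0.5 * c, 1.0 - c


# ---------------------------------------------------------------------------
# scale-free criterion
# ---------------------------------------------------------------------------


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10(frequency) on log10(mean connectivity) per bin.

    The scale-free topology criterion: a network whose connectivity follows a
    power law gives a straight line with negative slope on this plot.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    # equal-width bins over the connectivity range
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * xs + intercept
    ss_res = ((ys - yhat) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def pick_soft_threshold(
    expr: ExpressionStudy | np.ndarray,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    r2_cut: float = 0.85,
    signed: bool = False,
) -> tuple[float, pd.DataFrame, bool]:
    """Smallest candidate power reaching the scale-free fit cut.

    Returns ``(power, fit_table, satisfied)``; when no candidate reaches the
    cut, the power with maximal R^2 is returned with ``satisfied = False``.
    """
    powers = sorted(candidate_powers)
    if powers[0] < 1:
        raise ValueError("candidate powers must be >= 1")
    X = expr.expression.to_numpy() if isinstance(expr, ExpressionStudy) else np.asarray(expr)
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    c = _corrcoef_rows(X)
    c[np.isnan(c)] = 0.0
    base = 0.5 + 0.5 * c if signed else np.abs(c)
    rows = []
    for p in powers:
        a = base**p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "r2": r2, "slope": slope, "mean_k": k.mean()})
    table = pd.DataFrame(rows)
    ok = table[(table.r2 >= r2_cut) & (table.slope < 0)]
    if len(ok):
        return float(ok.power.iloc[0]), table, True
    best = table.loc[table.r2.idxmax()]
    warnings.warn(
        "no candidate power reached the scale-free R^2 cut; "
        f"returning power {best.power:g} with R^2 = {best.r2:.3f}",
        stacklevel=2,
    )
    return float(best.power), table, False


def select_candidates(
    results: "CoexpressionResults",
    ps_threshold: float = 0.005,
    mm_threshold: float = 0.5,
    preserved_modules: set[int] | None = None,
) -> pd.DataFrame:
    """Candidate driver proteins of preserved, status-correlated modules.

    Returns members of the eligible modules whose PS and |MM to their own
    module| exceed the thresholds, sorted by PS descending. Note PS lives on
    the soft-power scale: at xi = 6 a PS cut of 0.005 corresponds to an
    absolute status correlation of about 0.41.
    """
    if not 0 <= ps_threshold <= 1 or not 0 <= mm_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    labels = results.labels
    eligible = set(int(q) for q in set(labels) - {0})
    if preserved_modules is not None:
        eligible &= {int(q) for q in preserved_modules}
    rows = []
    for i, pid in enumerate(results.protein_ids):
        q = int(labels[i])
        if q not in eligible:
            continue
        mm = abs(results.membership.loc[i, q]) if q in results.membership.columns else 0.0
        if results.significance[i] >= ps_threshold and mm >= mm_threshold:
            rows.append(
                {"protein_id": pid, "module": q,
                 "ps": results.significance[i], "mm": mm}
            )
    out = pd.DataFrame(rows, columns=["protein_id", "module", "ps", "mm"])
    if out.empty:
        warnings.warn("candidate set is empty at these thresholds", stacklevel=2)
        return out
    return out.sort_values("ps", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class CoexpressionModel:
    """Weighted co-expression network model of one expression study.

    Parameters
    ----------
    study
        The proteins x samples study (with its status trait).
    config
        Workflow parameters; ``soft_power=None`` in :meth:`fit` triggers
        scale-free selection.
    """

    def __init__(self, study: ExpressionStudy, config: CoexpressionConfig | None = None):
        study.validate()
        self.study = study
        self.config = config or CoexpressionConfig()
        self.config.validate()

    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        status_trait: np.ndarray,
        config: CoexpressionConfig | None = None,
    ) -> "CoexpressionModel":
        meta = pd.DataFrame({"sample_id": expression.columns})
        study = ExpressionStudy(
            expression=expression,
            status_trait=np.asarray(status_trait, dtype=float),
            sample_meta=meta,
        )
        return cls(study, config)

    def fit(self, pick_power: bool = False) -> "CoexpressionResults":
        cfg = self.config
        power = cfg.soft_power
        power_table = None
        if pick_power:
            power, power_table, _ = pick_soft_threshold(
                self.study, r2_cut=cfg.scale_free_r2_cut, signed=cfg.signed
            )
        adj = adjacency_matrix(self.study, power, signed=cfg.signed)
        tom = tom_similarity(adj)
        labels = detect_modules(tom, cfg)
        eig = module_eigengenes(self.study, labels)
        ps, mm, msig = node_statistics(
            self.study, self.study.status_trait, eig, labels, power
        )
        if eig.shape[1] >= 2:
            eig_adj, eig_diss = eigengene_network(eig)
        else:
            eig_adj = eig_diss = np.zeros((eig.shape[1], eig.shape[1]))
        return CoexpressionResults(
            model=self,
            soft_power=power,
            power_table=power_table,
            adjacency=adj,
            tom=tom,
            labels=labels,
            eigengenes=eig,
            significance=ps,
            membership=mm,
            module_significance=msig,
            eigengene_adjacency=eig_adj,
            eigengene_dissimilarity=eig_diss,
        )


@dataclass
class CoexpressionResults:
    """Module decomposition of one study, as returned by ``CoexpressionModel.fit``."""

    model: CoexpressionModel
    soft_power: float
    power_table: pd.DataFrame | None
    adjacency: np.ndarray
    tom: np.ndarray
    labels: np.ndarray
    eigengenes: pd.DataFrame
    significance: np.ndarray
    membership: pd.DataFrame
    module_significance: dict[int, float]
    eigengene_adjacency: np.ndarray
    eigengene_dissimilarity: np.ndarray

    @property
    def protein_ids(self) -> list[str]:
        return self.model.study.protein_ids

    def module_members(self, q: int) -> list[str]:
        ids = np.asarray(self.protein_ids)
        return list(ids[self.labels == q])

    def select_candidates(self, **kwargs) -> pd.DataFrame:
        return select_candidates(self, **kwargs)

    def summary(self) -> str:
        lines = [
            "Co-expression module decomposition",
            "==================================",
            f"proteins: {len(self.labels)}   samples: {self.model.study.n_samples}",
            f"soft power xi: {self.soft_power:g}",
            f"modules (excl. grey): {len(self.module_significance)}",
            "",
            "module  size  module_significance",
        ]
        for q, sig in sorted(self.module_significance.items()):
            size = int((self.labels == q).sum())
            lines.append(f"{q:6d}  {size:4d}  {sig:8.4f}")
        grey = int((self.labels == 0).sum())
        lines.append(f"  grey  {grey:4d}        --")
        return "\n".join(lines)

    def to_tsv(self, labels_path=None, eigengenes_path=None, stats_path=None) -> None:
        if labels_path is not None:
            pd.DataFrame(
                {"protein_id": self.protein_ids, "module_id": self.labels}
            ).to_csv(labels_path, sep="\t", index=False)
        if eigengenes_path is not None:
            self.eigengenes.to_csv(eigengenes_path, sep="\t")
        if stats_path is not None:
            df = pd.DataFrame(
                {"protein_id": self.protein_ids, "module_id": self.labels,
                 "ps": self.significance}
            )
            df.to_csv(stats_path, sep="\t", index=False)
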