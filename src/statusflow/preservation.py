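"""Module preservation between replica cohorts (Zsummary composite).

A module found in a reference cohort is scored in a test cohort by density
statistics (is the module still tightly connected?) and connectivity
statistics (is its internal hub structure the same?). Each observed
statistic is converted to a Z score against a permutation null of random
same-size protein sets drawn from the test cohort, and

    z_density       = median of the density-statistic Z scores
    z_connectivity  = median of the connectivity-statistic Z scores
    Zsummary        = (z_density + z_connectivity) / 2

The conventional reading: Zsummary > 10 is strong evidence of preservation,
Zsummary < 2 says nothing.

Statistic families used here (a subset of the full composite in the WGCNA
literature, keeping its median/mean structure):

* density: mean within-module adjacency in the test cohort; mean absolute
  within-module correlation in the test cohort;
* connectivity: correlation between intramodular connectivity in reference
  and test; correlation between module membership (cor with the module
  eigengene) in reference and test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import adjacency_matrix, module_eigengenes, _cor_with_vector
from .datasets import ExpressionStudy

__all__ = ["ModulePreservation", "PreservationResults", "zsummary_preservation"]


def _upper_mean(m: np.ndarray) -> float:
    iu = np.triu_indices(m.shape[0], k=1)
    return float(m[iu].mean())


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _module_statistics(
    idx: np.ndarray,
    adj_ref: np.ndarray,
    adj_test: np.ndarray,
    cor_test: np.ndarray,
    X_ref: np.ndarray,
    X_test: np.ndarray,
) -> dict[str, float]:
    a_t = adj_test[np.ix_(idx, idx)]
    a_r = adj_ref[np.ix_(idx, idx)]
    c_t = cor_test[np.ix_(idx, idx)]
    k_ref = a_r.sum(axis=1) - 1.0
    k_test = a_t.sum(axis=1) - 1.0
    e_ref = module_eigengenes(X_ref[idx], np.ones(len(idx), dtype=int))[1].to_numpy()
    e_test = module_eigengenes(X_test[idx], np.ones(len(idx), dtype=int))[1].to_numpy()
    mm_ref = _cor_with_vector(X_ref[idx], e_ref)
    mm_test = _cor_with_vector(X_test[idx], e_test)
    return {
        "mean_adjacency": _upper_mean(a_t),
        "mean_abs_cor": _upper_mean(np.abs(c_t)),
        "cor_k": _safe_cor(k_ref, k_test),
        "cor_mm": _safe_cor(np.abs(mm_ref), np.abs(mm_test)),
    }


_DENSITY_STATS = ("mean_adjacency", "mean_abs_cor")
_CONNECTIVITY_STATS = ("cor_k", "cor_mm")


@dataclass
class PreservationResults:
    """Per-module Zsummary report; see the module docstring for the composite."""

    zsummary: dict[int, float]
    z_density: dict[int, float]
    z_connectivity: dict[int, float]
    observed: dict[int, dict[str, float]]
    n_permutations: int
    missing_modules: list[int]

    def summary(self) -> str:
        lines = [
            "Module preservation (permutation Zsummary)",
            "==========================================",
            f"permutations: {self.n_permutations}",
            "",
            "module  Zsummary  Z_density  Z_connectivity",
        ]
        for q in sorted(self.zsummary):
            lines.append(
                f"{q:6d}  {self.zsummary[q]:8.2f}  {self.z_density[q]:9.2f}"
                f"  {self.z_connectivity[q]:14.2f}"
            )
        if self.missing_modules:
            lines.append(f"missing from test universe: {self.missing_modules}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "zsummary": {str(q): v for q, v in self.zsummary.items()},
            "z_density": {str(q): v for q, v in self.z_density.items()},
            "z_connectivity": {str(q): v for q, v in self.z_connectivity.items()},
            "missing_modules": self.missing_modules,
        }


class ModulePreservation:
    """Permutation preservation model for modules of a reference cohort.

    Parameters
    ----------
    reference, test
        Two studies over the same protein universe.
    labels
        Module labels on the reference study's proteins (0 = unassigned).
    soft_power
        Soft power used for both adjacency matrices.
    """

    def __init__(
        self,
        reference: ExpressionStudy,
        test: ExpressionStudy,
        labels: np.ndarray,
        soft_power: float = 6.0,
    ):
        self.reference = reference
        self.test = test
        self.labels = np.asarray(labels)
        self.soft_power = soft_power
        ref_ids = list(reference.protein_ids)
        test_ids = set(test.protein_ids)
        self._present = np.array([pid in test_ids for pid in ref_ids])

    def fit(self, n_permutations: int = 100, seed: int = 0) -> PreservationResults:
        if n_permutations < 50:
            raise ValueError("need at least 50 permutations for a stable null")
        rng = np.random.default_rng(seed)
        X_ref = self.reference.expression.to_numpy()
        test_expr = self.test.expression.reindex(self.reference.protein_ids)
        missing = [
            int(q)
            for q in sorted(set(self.labels) - {0})
            if not self._present[self.labels == q].all()
        ]
        X_test = test_expr.to_numpy()
        adj_ref = adjacency_matrix(X_ref, self.soft_power)
        adj_test = adjacency_matrix(np.nan_to_num(X_test), self.soft_power)
        with np.errstate(invalid="ignore"):
            cor_test = np.corrcoef(np.nan_to_num(X_test))
        cor_test = np.nan_to_num(np.clip(cor_test, -1, 1))

        universe = np.flatnonzero(self._present)
        zsum, zden, zcon, observed = {}, {}, {}, {}
        for q in sorted(set(self.labels) - {0}):
            if q in missing:
                continue
            idx = np.flatnonzero(self.labels == q)
            obs = _module_statistics(idx, adj_ref, adj_test, cor_test, X_ref, X_test)
            null = {name: np.empty(n_permutations) for name in obs}
            for p in range(n_permutations):
                ridx = rng.choice(universe, size=len(idx), replace=False)
                stats = _module_statistics(
                    ridx, adj_ref, adj_test, cor_test, X_ref, X_test
                )
                for name, v in stats.items():
                    null[name][p] = v
            z = {}
            for name in obs:
                sd = null[name].std(ddof=1)
                z[name] = (obs[name] - null[name].mean()) / sd if sd > 0 else 0.0
            zd = float(np.median([z[s] for s in _DENSITY_STATS]))
            zc = float(np.median([z[s] for s in _CONNECTIVITY_STATS]))
            zden[int(q)] = zd
            zcon[int(q)] = zc
            zsum[int(q)] = 0.5 * (zd + zc)
            observed[int(q)] = obs
        return PreservationResults(
            zsummary=zsum,
            z_density=zden,
            z_connectivity=zcon,
            observed=observed,
            n_permutations=n_permutations,
            missing_modules=missing,
        )


def zsummary_preservation(
    reference: ExpressionStudy,
    test: ExpressionStudy,
    labels: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    soft_power: float = 6.0,
) -> PreservationResults:
    """Functional wrapper over :class:`ModulePreservation`."""
    return ModulePreservation(reference, test, labels, soft_power).fit(
        n_permutations=n_permutations, seed=seed
    )
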