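"""Reference-gene expression-stability ranking (geNorm M value).

A candidate reference gene's stability M is the mean, over all other
candidates k, of the pairwise variation V_jk — the sample standard
deviation across samples of log2(rq_j / rq_k).  Because V is built on
ratios, M is invariant to any per-gene positive rescaling of the relative
quantities, so quantities may enter on any consistent per-gene scale.
Selection proceeds by iteratively discarding the least stable gene
(largest M) and recomputing M until the requested number remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_COMPLETE_PAIRS = 3


@dataclass
class StabilityRanking:
    """Result of iterative geNorm selection.

    ``m_values`` holds, for each candidate, the M value from the round in
    which that gene was scored last (excluded genes keep the M that
    triggered their exclusion; selected genes keep their final-round M).
    """

    m_values: dict[str, float]
    exclusion_order: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        round_excluded = {g: i + 1 for i, g in enumerate(self.exclusion_order)}
        return pd.DataFrame(
            {
                "gene": list(self.m_values),
                "M": [self.m_values[g] for g in self.m_values],
                "round_excluded": [round_excluded.get(g, 0) for g in self.m_values],
                "selected": [g in self.selected for g in self.m_values],
            }
        ).sort_values("M", ignore_index=True)


def stability_relative_quantities(
    mean_ct: pd.DataFrame, efficiency: float = 2.0
) -> pd.DataFrame:
    """Per-sample relative quantities for stability ranking.

    ``mean_ct`` is long format with columns ``animal_id, region, gene,
    mean_ct``; one sample = one (animal, region).  Quantities are computed
    per gene as efficiency ** (gene mean Ct - sample Ct); the per-gene
    centering constant is irrelevant to M by ratio invariance.
    """
    wide = mean_ct.pivot_table(
        index=["animal_id", "region"], columns="gene", values="mean_ct"
    )
    centered = wide.mean(axis=0) - wide
    return efficiency**centered


def pairwise_variation(rq_j: np.ndarray, rq_k: np.ndarray) -> float:
    """V_jk: sample SD over samples of log2(rq_j / rq_k).

    Samples missing either quantity are dropped pairwise; at least
    3 complete pairs are required.  Symmetric in (j, k).
    """
    rq_j = np.asarray(rq_j, dtype=float)
    rq_k = np.asarray(rq_k, dtype=float)
    if rq_j.shape != rq_k.shape:
        raise ValueError("rq_j and rq_k must cover the same samples")
    ok = ~(np.isnan(rq_j) | np.isnan(rq_k))
    if np.any((rq_j[ok] <= 0) | (rq_k[ok] <= 0)):
        raise ValueError("relative quantities must be strictly positive")
    if ok.sum() < MIN_COMPLETE_PAIRS:
        raise ValueError(
            f"need at least {MIN_COMPLETE_PAIRS} complete sample pairs, got {int(ok.sum())}"
        )
    ratios = np.log2(rq_j[ok] / rq_k[ok])
    return float(np.std(ratios, ddof=1))


def stability_m(rq_matrix: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of V_jk, for every candidate gene (column)."""
    genes = list(rq_matrix.columns)
    if len(genes) < 3:
        raise ValueError("stability M requires at least 3 candidate genes")
    vals = rq_matrix.to_numpy(dtype=float)
    m = {}
    for j, gj in enumerate(genes):
        vs = [
            pairwise_variation(vals[:, j], vals[:, k])
            for k in range(len(genes))
            if k != j
        ]
        m[gj] = float(np.mean(vs))
    return pd.Series(m, name="M")


def genorm_select(rq_matrix: pd.DataFrame, n_keep: int = 3) -> StabilityRanking:
    """Iteratively exclude the least stable gene until ``n_keep`` remain.

    Ties in M are broken by lexicographic gene label (the lexicographically
    last of the tied genes is excluded) so the procedure is deterministic.
    """
    candidates = list(rq_matrix.columns)
    if not (2 <= n_keep <= len(candidates)):
        raise ValueError(
            f"n_keep must be in [2, {len(candidates)}], got {n_keep}"
        )
    m_values: dict[str, float] = {}
    exclusion_order: list[str] = []
    remaining = list(candidates)
    while True:
        m = stability_m(rq_matrix[remaining])
        for g in remaining:
            m_values[g] = float(m[g])
        if len(remaining) == n_keep:
            break
        # largest M, ties broken by gene label (last label wins exclusion)
        worst = max(remaining, key=lambda g: (m[g], g))
        exclusion_order.append(worst)
        remaining.remove(worst)
        if len(remaining) < 3:
            # M is undefined below 3 genes; final pair keeps its last M
            break
    return StabilityRanking(
        m_values=m_values,
        exclusion_order=exclusion_order,
        selected=sorted(remaining),
    )
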