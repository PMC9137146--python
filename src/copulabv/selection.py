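"""Breeder selection: random choice or within-family truncation on an EBV index.

Selection operates on paternal half-sib families (the progeny of one sire):
among each sire's candidate male offspring the best one is kept (1 of 34 at
full scale, a 2.9% rate) and among the candidate female offspring the best 17
(of 170, a 10% rate).  The selection index is a 50/50-weighted sum of the two
estimated breeding values; in the random phase the same quotas are drawn
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionRule", "selection_index", "select_breeders"]


@dataclass(frozen=True)
class SelectionRule:
    mode: str = "truncation"            # or "random"
    index_weights: tuple[float, float] = (0.5, 0.5)
    males_per_family: int = 1
    females_per_family: int = 17

    def __post_init__(self):
        if self.mode not in ("random", "truncation"):
            raise ValueError("mode must be 'random' or 'truncation'")
        if abs(sum(self.index_weights) - 1.0) > 1e-12:
            raise ValueError("index weights must sum to 1")


def selection_index(ebv: np.ndarray, weights=(0.5, 0.5)) -> np.ndarray:
    """w1 * EBV1 + w2 * EBV2 (rows of ``ebv`` are animals)."""
    ebv = np.atleast_2d(np.asarray(ebv, dtype=float))
    return ebv @ np.asarray(weights, dtype=float)


def select_breeders(candidate_rows: np.ndarray, sire_of: np.ndarray,
                    sex: np.ndarray, rule: SelectionRule, rng,
                    ebv: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pick the next round's sires and dams family by family.

    Parameters
    ----------
    candidate_rows : row indices of the selection candidates
    sire_of, sex : per-row sire index and sex arrays for the whole population
    ebv : (n, 2) estimated breeding values (whole population), required in
        truncation mode
    rng : numpy Generator, used for random-mode draws and index tie-breaks

    Returns (selected_sire_rows, selected_dam_rows).  Raises if a family
    holds fewer candidates of either sex than its quota.
    """
    candidate_rows = np.asarray(candidate_rows)
    fams = np.unique(sire_of[candidate_rows])
    if rule.mode == "truncation":
        if ebv is None:
            raise ValueError("truncation selection requires EBVs")
        idx_all = selection_index(ebv, rule.index_weights)
    sires, dams = [], []
    for fam in fams:
        members = candidate_rows[sire_of[candidate_rows] == fam]
        for target, quota in (("M", rule.males_per_family),
                              ("F", rule.females_per_family)):
            pool = members[sex[members] == target]
            if len(pool) < quota:
                raise RuntimeError(
                    f"family {fam}: {len(pool)} candidate {target} for quota {quota}")
            if rule.mode == "random":
                keep = rng.choice(pool, size=quota, replace=False)
            else:
                # seeded uniform jitter breaks exact index ties reproducibly
                jitter = rng.uniform(size=len(pool))
                order = np.lexsort((jitter, -idx_all[pool]))
                keep = pool[order[:quota]]
            (sires if target == "M" else dams).append(keep)
    return np.sort(np.concatenate(sires)), np.sort(np.concatenate(dams))
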