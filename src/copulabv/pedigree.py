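"""Pedigree container and the inverse numerator relationship matrix.

The additive-genetic covariance of an animal model is ``Sigma (x) A`` with A
the pedigree numerator relationship matrix.  Henderson's mixed-model
equations only need ``A^{-1}``, which for a non-inbred pedigree is assembled
directly from parent links: each animal contributes 1/d_i to its own
diagonal, -1/(2 d_i) to animal-parent entries and 1/(4 d_i) to parent-parent
entries, where d_i is the Mendelian-sampling variance fraction (1 with no
known parent, 3/4 with one, 1/2 with both).  det A = prod d_i falls out of
the same factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Pedigree", "a_inverse"]

UNKNOWN = -1  # internal code for an unknown parent (0-based arrays)


@dataclass
class Pedigree:
    """Column-array pedigree; row i is the animal with 1-based id i+1.

    ``sire`` / ``dam`` hold 0-based row indices, ``UNKNOWN`` (-1) for
    founders.  Parents must precede offspring, which also guarantees
    acyclicity.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray          # 'M' / 'F'
    generation: np.ndarray
    candidate: np.ndarray    # eligible for selection
    trait2_missing: np.ndarray

    def __post_init__(self):
        n = len(self.sire)
        for name in ("dam", "sex", "generation", "candidate", "trait2_missing"):
            if len(getattr(self, name)) != n:
                raise ValueError("pedigree columns must have equal length")
        idx = np.arange(n)
        for par in (self.sire, self.dam):
            known = par != UNKNOWN
            if np.any(par[known] >= idx[known]):
                raise ValueError("parents must precede offspring")
        both = (self.sire == UNKNOWN) != (self.dam == UNKNOWN)
        # the breeding schemes here always know both parents or neither,
        # but single known parents are legal pedigree input
        del both

    def __len__(self) -> int:
        return len(self.sire)

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from columns id, sire, dam (0 = unknown), sex, generation
        and optional candidate / trait2_missing flags."""
        df = df.sort_values("id").reset_index(drop=True)
        ids = df["id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(df) + 1)):
            raise ValueError("ids must be consecutive integers 1..n in birth order")
        def _parent(col):
            p = df[col].fillna(0).to_numpy(dtype=int)
            return p - 1  # 0 -> -1 (unknown)
        n = len(df)
        return cls(
            sire=_parent("sire"),
            dam=_parent("dam"),
            sex=df["sex"].to_numpy(),
            generation=df["generation"].to_numpy(dtype=int),
            candidate=(df["candidate"].to_numpy(dtype=bool)
                       if "candidate" in df else np.ones(n, dtype=bool)),
            trait2_missing=(df["trait2_missing"].to_numpy(dtype=bool)
                            if "trait2_missing" in df else np.zeros(n, dtype=bool)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sire": np.where(self.sire == UNKNOWN, 0, self.sire + 1),
            "dam": np.where(self.dam == UNKNOWN, 0, self.dam + 1),
            "sex": self.sex,
            "generation": self.generation,
            "candidate": self.candidate,
            "trait2_missing": self.trait2_missing,
        })

    def a_inverse(self) -> tuple[sparse.csc_matrix, float]:
        return a_inverse(self.sire, self.dam)


def a_inverse(sire: np.ndarray, dam: np.ndarray) -> tuple[sparse.csc_matrix, float]:
    """Henderson's direct inverse of the numerator relationship matrix.

    Parameters are 0-based parent indices with -1 for unknown; parents must
    precede offspring.  Returns ``(A_inv, logdet_A)`` with A_inv sparse
    symmetric; ``logdet_A = sum log d_i`` comes free from the underlying
    ``A = (I-P)^{-1} D (I-P)^{-T}`` factorisation.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.size
    idx = np.arange(n)
    for par in (sire, dam):
        known = par != UNKNOWN
        if np.any(par[known] >= idx[known]):
            raise ValueError("parents must precede offspring")

    n_known = (sire != UNKNOWN).astype(int) + (dam != UNKNOWN).astype(int)
    d = np.where(n_known == 2, 0.5, np.where(n_known == 1, 0.75, 1.0))
    k = 1.0 / d

    rows = [idx]
    cols = [idx]
    vals = [k]
    for par in (sire, dam):
        m = par != UNKNOWN
        # animal-parent (both triangles)
        rows += [idx[m], par[m]]
        cols += [par[m], idx[m]]
        vals += [-0.5 * k[m], -0.5 * k[m]]
    for p1 in (sire, dam):
        for p2 in (sire, dam):
            m = (p1 != UNKNOWN) & (p2 != UNKNOWN)
            rows.append(p1[m])
            cols.append(p2[m])
            vals.append(0.25 * k[m])

    ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    ainv.sum_duplicates()
    return ainv, float(np.log(d).sum())
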