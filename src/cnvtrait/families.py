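"""Sibship-aware resampling machinery.

Two operations recur throughout the pipeline:

* **family-respecting permutation** of a per-sample vector (used as the
  null for probe-wise association): scores are shuffled *within* each
  sibship and whole sibship score blocks are swapped *across* sibships of
  equal size, so the exchangeability structure of siblings is preserved;
* **one-per-family draws** (used by the burden statistics): each resample
  picks one member uniformly from every sibship, yielding a set of
  unrelated individuals.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def _family_groups(family_ids) -> dict[int, np.ndarray]:
    """Group sample positions by sibship size: size -> (m, size) array."""
    fam = pd.Series(family_ids).reset_index(drop=True)
    groups: dict[int, list[np.ndarray]] = {}
    for _, idx in fam.groupby(fam, sort=True).groups.items():
        arr = np.asarray(idx, dtype=np.int64)
        groups.setdefault(len(arr), []).append(arr)
    return {size: np.vstack(members) for size, members in groups.items()}


class FamilyPermuter:
    """Generates permutation index arrays that respect sibship structure.

    ``indices(n_perms, rng)`` returns an ``(n_perms, n)`` integer array
    ``I`` such that ``values[I[p]]`` is the p-th permuted vector: position
    ``i`` receives the value originally at ``I[p, i]``.
    """

    def __init__(self, family_ids):
        self.n = len(family_ids)
        self.n_families = pd.Series(family_ids).nunique()
        self._groups = _family_groups(family_ids)

    def indices(self, n_perms: int, rng: np.random.Generator) -> np.ndarray:
        out = np.tile(np.arange(self.n, dtype=np.int64), (n_perms, 1))
        for size, idx in self._groups.items():
            m = idx.shape[0]
            # family-block swap across equal-size sibships
            order = np.argsort(rng.random((n_perms, m)), axis=1)
            # within-family shuffle of the source family's scores
            within = np.argsort(rng.random((n_perms, m, size)), axis=2)
            src_within = np.take_along_axis(within, order[:, :, None], axis=1)
            flat = order[:, :, None] * size + src_within
            src = idx.ravel()[flat]  # (n_perms, m, size)
            out[:, idx.ravel()] = src.reshape(n_perms, m * size)
        return out

    def permute(self, values, n_perms: int, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values)
        return values[self.indices(n_perms, rng)]


def one_per_family(family_ids, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n_families) sample positions, one random member per sibship."""
    cols = []
    for size, idx in _family_groups(family_ids).items():
        m = idx.shape[0]
        pick = rng.integers(0, size, size=(n_draws, m))
        cols.append(np.take_along_axis(idx[None, :, :].repeat(n_draws, axis=0),
                                       pick[:, :, None], axis=2)[:, :, 0])
    return np.concatenate(cols, axis=1)
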