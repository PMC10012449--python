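"""Reference-free cell-composition adjustment (ReFACTor-style).

Whole-blood methylation mixes signals from several leukocyte types whose
proportions vary between donors, confounding association tests.  Instead of
estimating absolute cell counts from a reference panel, this module computes
sample-level components correlated with the (unobserved) cell-type mixture:

1. standardize each probe across samples;
2. form the best rank-``d`` approximation of the standardized matrix
   (``d`` = assumed number of cell types);
3. rank probes by the Euclidean distance between their observed profile and
   its rank-``d`` reconstruction and keep the ``t`` best-captured probes —
   these are the most cell-type-informative sites;
4. run PCA on the selected sub-matrix and return the first ``k`` sample-score
   components.

The components enter downstream regression models as covariates, absorbing
cell-composition variation without claiming absolute proportions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MethylationMatrix


@dataclass
class CompositionComponents:
    """Sample-score components plus the probes they were computed from."""

    components: pd.DataFrame      # samples x (PC1..PCk)
    selected_probes: list[str]    # in ascending low-rank-residual order
    d: int
    t: int
    k: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.components.index


def refactor_components(
    mvalues: MethylationMatrix,
    d: int = 5,
    t: int = 500,
    k: int = 3,
) -> CompositionComponents:
    """Compute ``k`` cell-composition components from an M-value matrix.

    Parameters
    ----------
    mvalues : complete (no-NaN) probe x sample matrix, M-value scale.
    d : assumed number of underlying cell types (rank of the approximation).
    t : number of most-informative probes kept for the final PCA.
    k : number of returned components, ``1 <= k <= t``.

    Component signs follow the convention that the largest-magnitude probe
    loading of each component is positive, making the output deterministic.
    """
    if d < 1:
        raise ValueError("d must be at least 1")
    if not 1 <= k <= t:
        raise ValueError("need 1 <= k <= t")
    x = mvalues.values.to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; preprocess first")
    n_probes, n_samples = x.shape
    if k > n_samples:
        raise ValueError("k cannot exceed the number of samples")

    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    # exact range test: np.std of a constant row is O(eps), not 0
    constant = x.max(axis=1) == x.min(axis=1)
    sd[constant, 0] = 1.0  # placeholder; rows dropped below
    if constant.any():
        warnings.warn(f"excluding {int(constant.sum())} constant probes from standardization")
    keep = ~constant
    if int(keep.sum()) < t:
        raise ValueError(f"t={t} exceeds the {int(keep.sum())} usable probes")
    z = (x[keep] - mean[keep]) / sd[keep]
    kept_ids = np.asarray(mvalues.probe_ids)[keep]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    dd = min(d, len(s))
    recon = (u[:, :dd] * s[:dd]) @ vt[:dd]
    dist = np.linalg.norm(z - recon, axis=1)
    order = np.argsort(dist, kind="mergesort")
    sel = order[:t]
    selected = [str(p) for p in kept_ids[sel]]

    y = z[sel].T                                   # samples x t, columns mean-0
    uy, sy, vty = np.linalg.svd(y, full_matrices=False)
    scores = uy[:, :k] * sy[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vty[j])))
        if vty[j, i] < 0:
            scores[:, j] = -scores[:, j]

    comp = pd.DataFrame(scores, index=mvalues.sample_ids,
                        columns=[f"PC{j + 1}" for j in range(k)])
    return CompositionComponents(comp, selected, d=d, t=t, k=k)


def canonical_correlations(x, y, tol: float = 1e-10) -> np.ndarray:
    """Canonical correlations between two sample-aligned score matrices.

    Columns are centered; rank-deficient blocks (e.g. compositional
    proportions, which lose one degree of freedom to the sum constraint) are
    truncated to their numerical rank, so the number of returned correlations
    is min(rank(x), rank(y)).  Used to score how well estimated components
    recover true cell proportions.
    """
    def basis(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, float)
        a = a - a.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(a, full_matrices=False)
        rank = int((s > tol * s[0]).sum()) if len(s) and s[0] > 0 else 0
        return u[:, :rank]

    bx, by = basis(x), basis(y)
    if bx.shape[1] == 0 or by.shape[1] == 0:
        return np.array([])
    vals = np.linalg.svd(bx.T @ by, compute_uv=False)
    return np.clip(vals, 0.0, 1.0)
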