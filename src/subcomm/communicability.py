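"""Weighted network communicability and derived subcortical node statistics.

Communicability between nodes p and q sums contributions from walks of every
length k, down-weighted by 1/k!, and equals the (p, q) entry of the matrix
exponential of the strength-normalized adjacency

    G = exp(M),    M = D^{-1/2} W D^{-1/2},

where D = diag(S) and S_i = sum_j w_ij is the strength (weighted degree) of
node i.  The normalization keeps high-strength hubs from dominating the
exponential.

Three subcortical representations are built from a whole-brain matrix W:

* ``Wsub``            — the raw 12x12 subcortical weight block;
* ``G(Wsub)``         — communicability of the isolated subcortical network
                        (walks confined to subcortical regions; D from the
                        12x12 block's own strengths);
* ``[G(W)]sub``       — whole-network communicability restricted to the
                        subcortical rows/columns (walks may route through
                        cortex; D from whole-network strengths).

Node summaries: the intra-strength communicability of subcortical node i is
the row sum of G(Wsub) over the subcortical set (including the i = i
self-communicability term); the inter-strength communicability is the sum of
whole-network communicability from i to cortical nodes only.

Zero-strength (isolated) nodes make D^{-1/2} undefined; their M row/column is
taken as 0 — the vanishing-weight limit — so they communicate only with
themselves (G row equals the identity row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .connectome_io import ConnectivityMatrix, RegionAtlas, extract_subnetwork

#: Source tags for CommunicabilityMatrix.
SOURCE_TAGS = ("subnetwork", "whole", "extracted")


@dataclass
class CommunicabilityMatrix:
    """Dense symmetric matrix of pairwise communicability values."""

    values: np.ndarray
    atlas: RegionAtlas
    source: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCE_TAGS:
            raise ValueError(f"source must be one of {SOURCE_TAGS}")
        self.values = np.asarray(self.values, dtype=float)


def strengths(matrix: ConnectivityMatrix) -> np.ndarray:
    """Node strengths S_i = sum_j w_ij (diagonal term counted once)."""
    return matrix.weights.sum(axis=1)


def normalized_adjacency(matrix: ConnectivityMatrix) -> np.ndarray:
    """M = D^{-1/2} W D^{-1/2}; zero-strength rows/columns are left at 0."""
    W = matrix.weights
    S = W.sum(axis=1)
    inv_sqrt = np.zeros_like(S)
    positive = S > 0
    inv_sqrt[positive] = 1.0 / np.sqrt(S[positive])
    return inv_sqrt[:, None] * W * inv_sqrt[None, :]


def _expm_symmetric(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition.

    Exact symmetry is restored after reconstruction; round-off negatives
    (analytically every entry of exp(M) with M >= 0 is >= 0) are clipped.
    """
    vals, vecs = eigh(M)
    G = (vecs * np.exp(vals)) @ vecs.T
    G = (G + G.T) / 2.0
    tiny = (G < 0) & (G > -1e-12)
    G[tiny] = 0.0
    return G


def weighted_communicability(
    matrix: ConnectivityMatrix, source: str = "whole"
) -> CommunicabilityMatrix:
    """G = exp(M) for the strength-normalized adjacency of ``matrix``."""
    G = _expm_symmetric(normalized_adjacency(matrix))
    return CommunicabilityMatrix(
        G, matrix.atlas, source=source, subject_id=matrix.subject_id
    )


def subnetwork_communicability(matrix: ConnectivityMatrix) -> CommunicabilityMatrix:
    """Communicability of the isolated subcortical block, G(Wsub).

    The strength normalization uses the 12x12 sub-matrix's own strengths,
    so only walks confined to the subcortical set contribute.
    """
    return weighted_communicability(extract_subnetwork(matrix), source="subnetwork")


def whole_communicability(matrix: ConnectivityMatrix) -> CommunicabilityMatrix:
    """Whole-network communicability G(W) (D from whole-network strengths)."""
    return weighted_communicability(matrix, source="whole")


def extracted_communicability(matrix: ConnectivityMatrix) -> CommunicabilityMatrix:
    """[G(W)]sub: whole-network communicability restricted to subcortical rows/cols.

    Unlike G(Wsub), entries here include walks passing through cortical
    nodes, so a subcortical pair with zero direct weight can still have
    positive communicability.
    """
    whole = whole_communicability(matrix)
    idx = matrix.atlas.subcortical_indices
    sub = whole.values[np.ix_(idx, idx)]
    return CommunicabilityMatrix(
        sub,
        matrix.atlas.subcortical_atlas(),
        source="extracted",
        subject_id=matrix.subject_id,
    )


def intra_strength(g_sub: CommunicabilityMatrix) -> np.ndarray:
    """Intra-strength communicability: row sums of G(Wsub) over the subcortical set.

    The sum runs over all subcortical j including j = i, so each node's own
    self-communicability (diagonal term, >= 1 for connected nodes)
    contributes.
    """
    if g_sub.source != "subnetwork":
        raise ValueError("intra_strength expects a subnetwork communicability matrix")
    return g_sub.values.sum(axis=1)


def inter_strength(g_whole: CommunicabilityMatrix) -> np.ndarray:
    """Inter-strength communicability of each subcortical node.

    For subcortical node i: sum of whole-network communicability G(W)_ij
    over cortical j only (all j outside the subcortical set; i itself and
    the other subcortical nodes are excluded by construction).
    """
    if g_whole.source != "whole":
        raise ValueError("inter_strength expects a whole-network communicability matrix")
    atlas = g_whole.atlas
    sub_idx = atlas.subcortical_indices
    cortical = np.setdiff1d(np.arange(atlas.n_regions), sub_idx)
    return g_whole.values[np.ix_(sub_idx, cortical)].sum(axis=1)
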