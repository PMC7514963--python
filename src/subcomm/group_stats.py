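"""Group-wise comparison of subcortical network features (HC vs. AD).

Each subject contributes one of five feature sets:

* pair features — the upper triangle (diagonal included, 12*13/2 = 78
  entries) of one of the three 12x12 representations ``Wsub``, ``G(Wsub)``
  or ``[G(W)]sub``;
* node features — the 12 intra- or inter-strength communicability values
  (``SC_intra``, ``SC_inter``).

Group differences are assessed feature-by-feature with a two-sided
permutation test on the difference of group means (labels shuffled with
group sizes preserved), followed by Benjamini–Hochberg FDR correction
within the feature family.  Effect sizes are reported as relative
differences (mean_HC - mean_AD) / mean_HC, so positive values mean a
reduction in AD.

Whole-brain matrices are max-normalized before the subcortical block is
extracted, so pair weights are expressed on each subject's global [0, 1]
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import communicability as comm
from .connectome_io import Cohort, ConnectivityMatrix, RegionAtlas, normalize_max

#: Feature-set tags operating on 12x12 matrices (78 pair features each).
PAIR_TAGS = ("Wsub", "G(Wsub)", "[G(W)]sub")
#: Feature-set tags operating on the 12 subcortical nodes.
NODE_TAGS = ("SC_intra", "SC_inter")
ALL_TAGS = PAIR_TAGS + NODE_TAGS


def pair_feature_ids(atlas: RegionAtlas) -> list[str]:
    """Region-pair labels in the fixed feature order.

    Order: row-major upper triangle including the diagonal, i.e. pairs
    (i, j) with i <= j sorted by (i, j) over subcortical positions.  For 12
    regions this yields 78 labels like ``"(left Hippocampus, left Putamen)"``.
    """
    names = atlas.subcortical_names
    iu, ju = np.triu_indices(len(names))
    return [f"({names[i]}, {names[j]})" for i, j in zip(iu, ju)]


def node_feature_ids(atlas: RegionAtlas) -> list[str]:
    return list(atlas.subcortical_names)


def pair_vector(matrix12: np.ndarray) -> np.ndarray:
    """Vectorize a 12x12 feature matrix in the fixed pair order."""
    n = matrix12.shape[0]
    return matrix12[np.triu_indices(n)]


def subject_pair_matrix(matrix: ConnectivityMatrix, tag: str) -> np.ndarray:
    """The subject's 12x12 representation for a pair-type feature set.

    The whole-brain matrix is max-normalized first; extraction and (for the
    communicability tags) exponentiation follow.
    """
    if tag not in PAIR_TAGS:
        raise ValueError(f"unknown pair tag {tag!r}; expected one of {PAIR_TAGS}")
    norm = normalize_max(matrix)
    if tag == "Wsub":
        from .connectome_io import extract_subnetwork

        return extract_subnetwork(norm).weights
    if tag == "G(Wsub)":
        return comm.subnetwork_communicability(norm).values
    return comm.extracted_communicability(norm).values


def subject_features(matrix: ConnectivityMatrix, tag: str) -> np.ndarray:
    """Feature vector (78 pair or 12 node values) for one subject."""
    if tag in PAIR_TAGS:
        return pair_vector(subject_pair_matrix(matrix, tag))
    if tag == "SC_intra":
        norm = normalize_max(matrix)
        return comm.intra_strength(comm.subnetwork_communicability(norm))
    if tag == "SC_inter":
        norm = normalize_max(matrix)
        return comm.inter_strength(comm.whole_communicability(norm))
    raise ValueError(f"unknown feature tag {tag!r}; expected one of {ALL_TAGS}")


@dataclass
class FeatureTable:
    """Subjects x features matrix with group labels and a feature-set tag."""

    data: pd.DataFrame  # index: subject_id, columns: feature ids
    groups: pd.Series  # index: subject_id, values in {"HC", "AD"}
    tag: str

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise ValueError("feature table and group labels must share an index")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def build_feature_table(cohort: Cohort, tag: str) -> FeatureTable:
    """Compute the tagged feature set for every subject in the cohort."""
    atlas = cohort.atlas
    ids = (
        pair_feature_ids(atlas) if tag in PAIR_TAGS else node_feature_ids(atlas)
    )
    rows = np.stack([subject_features(s.matrix, tag) for s in cohort.subjects])
    index = pd.Index(cohort.subject_ids, name="subject_id")
    return FeatureTable(
        data=pd.DataFrame(rows, index=index, columns=ids),
        groups=pd.Series(cohort.labels, index=index, name="group"),
        tag=tag,
    )


def permutation_test(
    table: FeatureTable, n_perm: int = 10_000, seed: int | None = None
) -> np.ndarray:
    """Two-sided permutation p-values for the difference of group means.

    The statistic for each feature is mean(HC) - mean(AD).  Group labels are
    reassigned uniformly at random ``n_perm`` times with group sizes
    preserved, and the add-one estimator

        p = (1 + #{ |stat_perm| >= |stat_obs| }) / (n_perm + 1)

    is returned (never exactly zero; the observed labelling counts as one
    permutation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = table.groups.to_numpy()
    is_hc = labels == "HC"
    n_hc = int(is_hc.sum())
    n_ad = int((~is_hc).sum())
    if n_hc == 0 or n_ad == 0:
        raise ValueError("permutation test requires both groups non-empty")
    X = table.data.to_numpy()
    order = np.argsort(~is_hc, kind="stable")  # HC rows first
    X = X[order]
    obs = X[:n_hc].mean(axis=0) - X[n_hc:].mean(axis=0)
    rng = np.random.default_rng(seed)
    n = n_hc + n_ad
    exceed = np.zeros(X.shape[1], dtype=int)
    abs_obs = np.abs(obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = X[perm[:n_hc]].mean(axis=0) - X[perm[n_hc:]].mean(axis=0)
        # tiny slack absorbs round-off so exact re-draws of the observed
        # labelling always count as exceedances
        exceed += np.abs(stat) >= abs_obs - 1e-12 * np.maximum(abs_obs, 1.0)
    return (1 + exceed) / (n_perm + 1)


def fdr_correct(
    p_raw: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and rejection flags.

    Returns ``(p_fdr, significant)`` with ``significant = p_fdr < q``.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def relative_difference(mean_hc: np.ndarray, mean_ad: np.ndarray) -> np.ndarray:
    """(mean_HC - mean_AD) / mean_HC; NaN (flagged) where mean_HC is zero.

    Positive values indicate a reduction in AD; negative values an AD
    increase.  Rendered as a percentage via ``abs(value) * 100``.
    """
    mean_hc = np.asarray(mean_hc, dtype=float)
    mean_ad = np.asarray(mean_ad, dtype=float)
    out = np.full(np.broadcast(mean_hc, mean_ad).shape, np.nan)
    np.divide(mean_hc - mean_ad, mean_hc, out=out, where=mean_hc != 0)
    return out


@dataclass
class GroupStatsResult:
    """Per-feature group comparison table with run metadata."""

    table: pd.DataFrame  # feature_id, mean_HC, mean_AD, rel_diff, p_raw, p_fdr, significant
    tag: str
    n_perm: int
    seed: int | None
    q: float

    @property
    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature_id"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "tag": self.tag,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "q": self.q,
            "n_features": int(len(self.table)),
            "n_significant": int(self.table["significant"].sum()),
        }

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2) + "\n")


def compare_groups_table(
    table: FeatureTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    q: float = 0.05,
) -> GroupStatsResult:
    """Permutation test + FDR correction on a prebuilt feature table."""
    is_hc = table.groups.to_numpy() == "HC"
    X = table.data.to_numpy()
    mean_hc = X[is_hc].mean(axis=0)
    mean_ad = X[~is_hc].mean(axis=0)
    p_raw = permutation_test(table, n_perm=n_perm, seed=seed)
    p_fdr, significant = fdr_correct(p_raw, q=q)
    frame = pd.DataFrame(
        {
            "feature_id": table.data.columns,
            "mean_HC": mean_hc,
            "mean_AD": mean_ad,
            "rel_diff": relative_difference(mean_hc, mean_ad),
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "significant": significant,
        }
    )
    frame = frame.sort_values("feature_id", kind="stable").reset_index(drop=True)
    return GroupStatsResult(frame, table.tag, n_perm, seed, q)


def group_compare(
    cohort: Cohort,
    tag: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    q: float = 0.05,
) -> GroupStatsResult:
    """Full group comparison for one feature set of a cohort.

    Deterministic given ``seed``; the result table is sorted by feature id.
    """
    cohort.require_two_groups()
    return compare_groups_table(
        build_feature_table(cohort, tag), n_perm=n_perm, seed=seed, q=q
    )
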