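"""Reading, validation and normalization of structural connectome matrices.

A structural connectome is a square, symmetric, non-negative region-by-region
matrix whose entry ``w_ij`` counts the (SIFT2-weighted) streamlines connecting
parcellated brain regions ``i`` and ``j``.  This module handles the plain-text
matrix files such pipelines emit (one row per line, comma- or whitespace-
delimited), region-label lists, cohort manifests, and the basic per-matrix
operations the downstream analysis relies on: max-weight normalization,
density and inter-subject correlation quality control, and extraction of the
12-region subcortical sub-network.

The analysis convention throughout the package is: normalize the whole-brain
matrix first (divide by its global maximum), then extract the subcortical
block.  ``extract_subnetwork`` itself is a pure index restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Relative asymmetry accepted (and silently symmetrized) on input.
#: Tractography connectomes are symmetric by construction; anything beyond
#: round-off signals a corrupted file.
SYMMETRY_RTOL = 1e-8

#: Valid diagnostic group labels.
GROUPS = ("HC", "AD")

#: Subcortical structures of interest, one per hemisphere (12 regions total).
SUBCORTICAL_BASENAMES = (
    "Hippocampus",
    "Amygdala",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
)


def default_subcortical_names() -> tuple[str, ...]:
    """The 12 default subcortical region names, left/right per structure."""
    return tuple(
        f"{side} {base}"
        for base in SUBCORTICAL_BASENAMES
        for side in ("left", "right")
    )


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region names plus the subset forming the subcortical network.

    ``names`` defines matrix row/column order.  ``subcortical_names`` must be
    a subset of ``names`` listed in atlas order, so that the resolved index
    set is strictly increasing.
    """

    names: tuple[str, ...]
    subcortical_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        sub = tuple(self.subcortical_names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "subcortical_names", sub)
        if len(set(names)) != len(names):
            raise ValueError("atlas region names must be unique")
        missing = [s for s in sub if s not in names]
        if missing:
            raise ValueError(f"subcortical names not in atlas: {missing}")
        idx = [names.index(s) for s in sub]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                "subcortical names must be listed in atlas order "
                "(resolved indices must be strictly increasing)"
            )

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def subcortical_indices(self) -> np.ndarray:
        """Row/column indices of the subcortical regions, strictly increasing."""
        pos = {n: i for i, n in enumerate(self.names)}
        return np.array([pos[s] for s in self.subcortical_names], dtype=int)

    def subcortical_atlas(self) -> "RegionAtlas":
        """Atlas of the extracted sub-network (all regions subcortical)."""
        return RegionAtlas(self.subcortical_names, self.subcortical_names)

    @classmethod
    def from_label_file(
        cls,
        path: str | Path,
        subcortical_names: Sequence[str] | None = None,
    ) -> "RegionAtlas":
        """Read one region name per line; order defines matrix row order.

        If ``subcortical_names`` is omitted, the 12 default subcortical
        structures are looked up in the file (in atlas order).
        """
        names = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        if subcortical_names is None:
            wanted = set(default_subcortical_names())
            subcortical_names = [n for n in names if n in wanted]
        return cls(tuple(names), tuple(subcortical_names))

    def to_label_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.names) + "\n")


@dataclass
class ConnectivityMatrix:
    """A subject's symmetric non-negative weighted connectivity matrix."""

    weights: np.ndarray
    atlas: RegionAtlas
    subject_id: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"non-square matrix with shape {W.shape}")
        if W.shape[0] != self.atlas.n_regions:
            raise ValueError(
                f"matrix dimension {W.shape[0]} does not match atlas "
                f"({self.atlas.n_regions} regions)"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite entry in connectivity matrix")
        if np.any(W < 0):
            raise ValueError("negative weight in connectivity matrix")
        asym = np.abs(W - W.T).max()
        scale = np.abs(W).max()
        if asym > SYMMETRY_RTOL * max(scale, 1.0):
            raise ValueError(
                f"asymmetry {asym:.3g} exceeds tolerance "
                f"(rel. {SYMMETRY_RTOL:g}); refusing to symmetrize"
            )
        if asym > 0:
            W = (W + W.T) / 2.0
        self.weights = W

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _detect_delimiter(path: Path) -> str | None:
    """Return ',' for comma-delimited files, None (any whitespace) otherwise."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," if "," in line else None
    raise ValueError(f"empty connectome file: {path}")


def load_connectome(
    path: str | Path, atlas: RegionAtlas, subject_id: str | None = None
) -> ConnectivityMatrix:
    """Load and validate a plain-text square connectivity matrix.

    Comma- and whitespace-delimited dialects are auto-detected; scientific
    notation is accepted.  Validation (squareness, atlas dimension, sign,
    symmetry) happens in the :class:`ConnectivityMatrix` constructor.
    """
    path = Path(path)
    delim = _detect_delimiter(path)
    try:
        W = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:  # non-numeric token or ragged rows
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return ConnectivityMatrix(
        W, atlas, subject_id=subject_id if subject_id is not None else path.stem
    )


def write_connectome(
    matrix: ConnectivityMatrix, path: str | Path, delimiter: str = " "
) -> None:
    """Write the matrix in the same text dialect accepted by ``load_connectome``.

    ``%.17g`` formatting round-trips float64 exactly, so load→write→load is
    bit-identical.
    """
    np.savetxt(path, matrix.weights, fmt="%.17g", delimiter=delimiter)


def normalize_max(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide all weights by the global maximum, mapping entries into [0, 1].

    Idempotent; preserves the zero/nonzero pattern; the maximum entry becomes
    exactly 1.  An all-zero matrix has no meaningful scale and is an error.
    """
    wmax = matrix.weights.max()
    if wmax <= 0:
        raise ValueError(
            f"cannot normalize all-zero matrix (subject {matrix.subject_id!r})"
        )
    return replace(matrix, weights=matrix.weights / wmax)


def density(matrix: ConnectivityMatrix) -> float:
    """Fraction of strictly positive off-diagonal upper-triangle entries."""
    iu = np.triu_indices(matrix.n_regions, k=1)
    vals = matrix.weights[iu]
    return float(np.count_nonzero(vals > 0) / vals.size)


def extract_subnetwork(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Restrict rows and columns to the atlas's subcortical regions.

    Pure index restriction (order preserved): entry (a, b) of the result is
    entry (idx[a], idx[b]) of the input.
    """
    idx = matrix.atlas.subcortical_indices
    sub = matrix.weights[np.ix_(idx, idx)]
    return ConnectivityMatrix(
        sub, matrix.atlas.subcortical_atlas(), subject_id=matrix.subject_id
    )


@dataclass
class Subject:
    subject_id: str
    group: str
    matrix: ConnectivityMatrix

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class Cohort:
    """Ordered collection of subjects with diagnosis labels sharing one atlas."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subjects:
            atlas = self.subjects[0].matrix.atlas
            for s in self.subjects:
                if s.matrix.atlas != atlas:
                    raise ValueError("all subjects in a cohort must share one atlas")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def atlas(self) -> RegionAtlas:
        if not self.subjects:
            raise ValueError("empty cohort has no atlas")
        return self.subjects[0].matrix.atlas

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def group_subjects(self, group: str) -> list[Subject]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [s for s in self.subjects if s.group == group]

    def require_two_groups(self) -> None:
        for g in GROUPS:
            if not self.group_subjects(g):
                raise ValueError(f"group comparison requires non-empty {g} group")


def load_cohort(manifest_path: str | Path, atlas: RegionAtlas) -> Cohort:
    """Load a cohort from a CSV manifest with columns subject_id,group,path.

    Matrix paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    subjects = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        matrix = load_connectome(p, atlas, subject_id=str(row.subject_id))
        subjects.append(Subject(str(row.subject_id), str(row.group), matrix))
    return Cohort(subjects)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject matrix files plus a manifest CSV; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.txt"
        write_connectome(s.matrix, out_dir / fname)
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def cohort_pairwise_correlation(cohort: Cohort, group: str) -> tuple[float, float]:
    """Mean and SD of Pearson correlations between all subject pairs in a group.

    Each subject is vectorized as the upper triangle of its weight matrix
    (diagonal excluded); the correlation is computed for every unordered
    pair.  Subjects with zero-variance vectors cannot be correlated and are
    skipped with a warning.
    """
    members = cohort.group_subjects(group)
    if len(members) < 2:
        raise ValueError(f"group {group!r} needs >= 2 subjects for correlations")
    n = members[0].matrix.n_regions
    iu = np.triu_indices(n, k=1)
    vecs = np.stack([s.matrix.weights[iu] for s in members])
    sd = vecs.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        ids = [members[i].subject_id for i in degenerate]
        warnings.warn(
            f"zero-variance upper triangle for subjects {ids}; pairs skipped",
            stacklevel=2,
        )
        vecs = np.delete(vecs, degenerate, axis=0)
        if vecs.shape[0] < 2:
            raise ValueError("fewer than 2 usable subjects after degeneracy filter")
    corr = np.corrcoef(vecs)
    pair_vals = corr[np.triu_indices(corr.shape[0], k=1)]
    return float(pair_vals.mean()), float(pair_vals.std())
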