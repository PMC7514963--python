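"""End-to-end study orchestration.

``run_full_study`` composes the whole analysis on a cohort (loaded from a
manifest or simulated): quality control (density, inter-subject
correlation), group statistics for the three pair representations and the
two node-strength summaries, nested-CV classification for the three pair
feature sets, and a comparison table — writing every stage's output to
disk as CSV/JSON plus a run manifest with config echo and checksums.

A single root seed deterministically derives per-stage seeds (simulation,
permutation per feature set, cross-validation), so stages can be re-run in
isolation and the whole run is byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import ClassifierConfig, CVReport, comparison_table, run_cv
from .connectome_io import Cohort, cohort_pairwise_correlation, density
from .group_stats import ALL_TAGS, PAIR_TAGS, GroupStatsResult, group_compare
from .synthetic_data import SimulationConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("subcomm")

#: Filesystem-safe names for the feature-set tags.
TAG_SLUGS = {
    "Wsub": "wsub",
    "G(Wsub)": "g_wsub",
    "[G(W)]sub": "g_whole_sub",
    "SC_intra": "sc_intra",
    "SC_inter": "sc_inter",
}

_STAGE = {"simulate": 1, "groupstats": 2, "classify": 3}


def stage_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    ss = np.random.SeedSequence([root_seed, _STAGE[stage], index])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class StudyResults:
    cohort: Cohort
    qc: dict
    group_stats: dict[str, GroupStatsResult]
    cv: dict[str, CVReport]
    comparison: pd.DataFrame
    manifest: RunManifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def cohort_qc(cohort: Cohort) -> dict:
    """Density and inter-subject correlation summaries per diagnostic group."""
    out: dict = {}
    for group in ("HC", "AD"):
        members = cohort.group_subjects(group)
        dens = [density(s.matrix) for s in members]
        corr_mean, corr_sd = cohort_pairwise_correlation(cohort, group)
        out[group] = {
            "n_subjects": len(members),
            "density_mean": float(np.mean(dens)),
            "density_sd": float(np.std(dens)),
            "correlation_mean": corr_mean,
            "correlation_sd": corr_sd,
        }
    return out


def run_full_study(
    cohort: Cohort | SyntheticCohort | SimulationConfig,
    out_dir: str | Path,
    n_perm: int = 10_000,
    q: float = 0.05,
    clf_config: ClassifierConfig | None = None,
    seed: int = 0,
) -> StudyResults:
    """Run QC, group statistics, classification and comparison; write outputs.

    ``cohort`` may be a loaded :class:`Cohort`, an already-generated
    :class:`SyntheticCohort`, or a :class:`SimulationConfig` (in which case
    the cohort is simulated here with a seed derived from ``seed``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_echo: dict | None = None
    if isinstance(cohort, SimulationConfig):
        sim_config = replace(cohort, seed=stage_seed(seed, "simulate"))
        logger.info("simulating cohort (seed %d)", sim_config.seed)
        cohort = generate_cohort(sim_config)
    if isinstance(cohort, SyntheticCohort):
        sim_echo = asdict(cohort.config)
        (out_dir / "ground_truth.json").write_text(
            json.dumps(cohort.ground_truth, indent=2) + "\n"
        )
        cohort = cohort.cohort

    if clf_config is None:
        clf_config = ClassifierConfig()
    clf_config = replace(clf_config, seed=stage_seed(seed, "classify"))

    logger.info("quality control")
    qc = cohort_qc(cohort)
    (out_dir / "qc.json").write_text(json.dumps(qc, indent=2) + "\n")

    group_stats: dict[str, GroupStatsResult] = {}
    stats_meta = {}
    for i, tag in enumerate(ALL_TAGS):
        logger.info("group statistics: %s", tag)
        result = group_compare(
            cohort, tag, n_perm=n_perm, seed=stage_seed(seed, "groupstats", i), q=q
        )
        result.to_csv(out_dir / f"groupstats_{TAG_SLUGS[tag]}.csv")
        group_stats[tag] = result
        stats_meta[tag] = result.metadata()
    (out_dir / "groupstats_summary.json").write_text(
        json.dumps(stats_meta, indent=2) + "\n"
    )

    cv: dict[str, CVReport] = {}
    for tag in PAIR_TAGS:
        logger.info("classification: %s", tag)
        report = run_cv(cohort, tag, clf_config)
        report.to_json(out_dir / f"cv_{TAG_SLUGS[tag]}.json")
        cv[tag] = report
    comparison = comparison_table(cv)
    comparison.to_csv(out_dir / "comparison.csv", index=False)

    manifest = RunManifest(
        seed=seed,
        version=__version__,
        config={
            "n_perm": n_perm,
            "q": q,
            "classifier": asdict(clf_config),
            "simulation": sim_echo,
        },
    )
    for f in sorted(out_dir.iterdir()):
        if f.name != "run_manifest.json" and f.is_file():
            manifest.outputs[f.name] = _sha256(f)
    manifest.write(out_dir / "run_manifest.json")
    logger.info("study complete: %s", out_dir)
    return StudyResults(cohort, qc, group_stats, cv, comparison, manifest)
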