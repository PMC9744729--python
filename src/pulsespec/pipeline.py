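"""End-to-end orchestration: generate, extract, compare, score, classify.

A single seeded run produces the subject table, the 41-index feature
table, the group-comparison report, the bar-scoring report, the
eight-method CV report and a JSON manifest sufficient to reproduce every
output bit for bit. Group pooling (e.g. robust vs the union of dynapenia,
presarcopenia and sarcopenia, optionally restricting the robust side to
no-MetS subjects) is part of the run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ValidationError
from .groupstats import compare_two_groups, comparisons_to_frame
from .ml import METHODS, reports_to_frame, run_cv
from .scoring import (
    POSSIBLE_LABEL,
    ROBUST_LABEL,
    calibrations_to_frame,
    cross_validated_scoring,
    fit_and_score,
)
from .spectral import DEFAULT_NORMALIZATION, extract_features
from .synthetic import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoolingSpec:
    """How four groups (and MetS labels) collapse to a binary contrast.

    ``negative_mets`` / ``positive_mets`` optionally restrict a side to one
    MetS status; subjects on neither side are excluded (with a logged
    count).
    """

    positive_groups: tuple = ("dynapenia", "presarcopenia", "sarcopenia")
    negative_groups: tuple = ("robust",)
    positive_mets: str | None = None
    negative_mets: str | None = None
    positive_label: str = POSSIBLE_LABEL
    negative_label: str = ROBUST_LABEL


def pool_groups(subjects: pd.DataFrame, spec: PoolingSpec) -> pd.Series:
    """Binary label per retained subject, indexed like ``subjects``.

    Raises when the two sides overlap or reference unknown groups.
    """
    pos = set(spec.positive_groups)
    neg = set(spec.negative_groups)
    if pos & neg:
        raise ValidationError(f"pooling sides overlap: {sorted(pos & neg)}")
    known = set(subjects["group"].unique())
    unknown = (pos | neg) - known
    if unknown:
        raise ValidationError(f"pooling references unknown groups: {sorted(unknown)}")
    mask_pos = subjects["group"].isin(pos)
    mask_neg = subjects["group"].isin(neg)
    if spec.positive_mets is not None:
        mask_pos &= subjects["mets_status"] == spec.positive_mets
    if spec.negative_mets is not None:
        mask_neg &= subjects["mets_status"] == spec.negative_mets
    labels = pd.Series(pd.NA, index=subjects.index, dtype=object)
    labels[mask_neg] = spec.negative_label
    labels[mask_pos] = spec.positive_label
    excluded = int(labels.isna().sum())
    if excluded:
        logger.info("pooling excluded %d subjects outside both sides", excluded)
    return labels.dropna()


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pooling: PoolingSpec = field(default_factory=PoolingSpec)
    normalization: str = DEFAULT_NORMALIZATION
    ml_methods: tuple = METHODS
    ml_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        # the top-level seed fans out to per-stage children
        child = np.random.SeedSequence(self.seed, spawn_key=(0,))
        cohort_seed = int(child.generate_state(1)[0] % (2**31))
        self.cohort = dataclasses.replace(self.cohort, seed=cohort_seed)
        ml_child = np.random.SeedSequence(self.seed, spawn_key=(1,))
        self.ml_seed = int(ml_child.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.get("cohort", {}))
        pooling_raw = dict(raw.get("pooling", {}))
        for key in ("positive_groups", "negative_groups"):
            if key in pooling_raw:
                pooling_raw[key] = tuple(pooling_raw[key])
        pooling = PoolingSpec(**pooling_raw)
        kwargs = {
            k: v
            for k, v in raw.items()
            if k in ("normalization", "ml_folds", "seed")
        }
        if "ml_methods" in raw:
            kwargs["ml_methods"] = tuple(raw["ml_methods"])
        return cls(cohort=cohort, pooling=pooling, **kwargs)


def features_table(cohort: Cohort, normalization: str = DEFAULT_NORMALIZATION) -> pd.DataFrame:
    """Extract the 41 indices for every recording of a cohort.

    Returns one row per subject: metadata columns then the indices.
    """
    rows = []
    for (_, meta), rec in zip(cohort.subjects.iterrows(), cohort.recordings):
        fv = extract_features(rec, normalization=normalization)
        row = {
            "subject_id": meta["subject_id"],
            "group": meta["group"],
            "mets_status": meta["mets_status"],
        }
        row.update(fv.to_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop metadata columns, keeping the 41 numeric indices."""
    meta = [c for c in ("subject_id", "group", "mets_status") if c in table.columns]
    return table.drop(columns=meta)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute generate → extract → compare → score → ML, writing all
    reports.

    Returns the in-memory results keyed by stage; every output is also
    written to ``outdir`` as delimited text or JSON, together with a
    manifest (config, seed, package and library versions).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("generating cohort (seed %d)", config.cohort.seed)
    cohort = generate_cohort(config.cohort, normalization=config.normalization)
    logger.info("extracting features for %d subjects", len(cohort.recordings))
    table = features_table(cohort, normalization=config.normalization)

    labels = pool_groups(table, config.pooling)
    pooled = table.loc[labels.index]
    x = feature_matrix(pooled)
    y = labels.to_numpy()

    comparisons = compare_two_groups(x, y)
    calibrations, _, scoring_report = fit_and_score(x, y)
    scoring_cv = cross_validated_scoring(
        x, y, k=config.ml_folds, seed=config.ml_seed
    )
    ml_reports = run_cv(
        x,
        y,
        methods=config.ml_methods,
        k=config.ml_folds,
        seed=config.ml_seed,
        positive_label=config.pooling.positive_label,
    )

    table.to_csv(outdir / "features.csv", index=False)
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    comparisons_to_frame(comparisons).to_csv(outdir / "comparisons.csv", index=False)
    calibrations_to_frame(calibrations).to_csv(outdir / "calibration.csv", index=False)
    with (outdir / "scoring_report.json").open("w") as fh:
        json.dump({"in_sample": scoring_report, "cross_validated": scoring_cv}, fh, indent=2)
    reports_to_frame(ml_reports).to_csv(outdir / "ml_report.csv", index=False)

    manifest = {
        "pulsespec_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "cohort": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(config.cohort).items()
        },
        "pooling": dataclasses.asdict(config.pooling),
        "normalization": config.normalization,
        "ml_methods": list(config.ml_methods),
        "ml_folds": config.ml_folds,
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "cohort": cohort,
        "features": table,
        "labels": labels,
        "comparisons": comparisons,
        "scoring": scoring_report,
        "scoring_cv": scoring_cv,
        "ml": ml_reports,
    }
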