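"""End-to-end orchestration: dataset -> TE classes -> features -> results.

This is the programmatic counterpart of chaining the CLI subcommands; it
is also what the acceptance script and the recovery tests drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bin_stats, classify, struct_features, te_quant
from .iolib import ReactivityTrack, TranscriptModel, feature_groups
from .seq_features import sequence_feature_table


@dataclass
class StudyResult:
    expression: pd.DataFrame  # transcript_id -> rpkm_ribo, rpkm_rna, te, te_class
    features: pd.DataFrame  # labeled transcripts x all features
    groups: dict[str, str]  # feature name -> group
    labels: pd.Series  # transcript_id -> 1 (high) / 0 (low)
    splits: list[classify.SplitResult] = field(default_factory=list)
    importance: classify.ImportanceSummary | None = None
    vivo_profiles: pd.DataFrame | None = None
    vitro_profiles: pd.DataFrame | None = None
    bin_summary: pd.DataFrame | None = None


def label_transcripts(
    dataset: Mapping,
    rpkm_threshold: float = 1.0,
    quantile: float = 0.25,
    length_mode: str = "transcript",
) -> pd.DataFrame:
    """Counts -> RPKM -> TE -> expression filter -> high/low classes."""
    records = te_quant.quantify(
        dataset["counts"], dataset["transcripts"], dataset["ribo_total"], dataset["rna_total"],
        length_mode=length_mode,
    )
    records = te_quant.filter_expressed(records, threshold=rpkm_threshold)
    records = te_quant.select_te_groups(records, q=quantile)
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "rpkm_ribo": [r.rpkm_ribo for r in records],
            "rpkm_rna": [r.rpkm_rna for r in records],
            "te": [r.te for r in records],
            "te_class": [r.te_class for r in records],
        }
    ).set_index("transcript_id")
    return df


def build_feature_table(
    transcripts: Sequence[TranscriptModel],
    vivo: Sequence[ReactivityTrack],
    vitro: Sequence[ReactivityTrack],
    seq_registry: Mapping | None = None,
    external_mfe: Mapping | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Sequence + structural features side by side, with the group registry."""
    seq = sequence_feature_table(transcripts, seq_registry)
    struct = struct_features.structural_feature_table(
        transcripts, vivo, vitro, external_mfe=external_mfe
    )
    features = seq.join(struct)
    return features, feature_groups(features.columns)


def run_study(
    dataset: Mapping,
    rpkm_threshold: float = 1.0,
    quantile: float = 0.25,
    n_splits: int = classify.N_SPLITS,
    cv_folds: int = classify.CV_FOLDS,
    base_seed: int = 0,
    rf_grid: Mapping | None = None,
    en_grid: Mapping | None = None,
    models: Sequence[str] = ("rf",),
    with_bin_stats: bool = True,
) -> StudyResult:
    """The whole analysis on an in-memory dataset.

    Only high/low-labeled transcripts enter the classifier (label 1 =
    high TE). Per-bin statistics use the same labeling.
    """
    expression = label_transcripts(dataset, rpkm_threshold, quantile)
    keep = expression.index[expression["te_class"].isin(["high", "low"])]
    transcripts = [t for t in dataset["transcripts"] if t.transcript_id in set(keep)]
    features, groups = build_feature_table(transcripts, dataset["vivo"], dataset["vitro"])
    labels = (expression.loc[features.index, "te_class"] == "high").astype(int)

    result = StudyResult(
        expression=expression, features=features, groups=groups, labels=labels
    )
    if n_splits > 0:
        result.splits = classify.run_splits(
            features,
            labels.to_numpy(),
            n_splits=n_splits,
            cv_folds=cv_folds,
            base_seed=base_seed,
            rf_grid=rf_grid,
            en_grid=en_grid,
            models=models,
        )
        if "rf" in models:
            result.importance = classify.grouped_importance(result.splits, groups)
    if with_bin_stats:
        label_map = expression.loc[keep, "te_class"].to_dict()
        result.vivo_profiles = struct_features.profile_matrix(transcripts, dataset["vivo"])
        result.vitro_profiles = struct_features.profile_matrix(transcripts, dataset["vitro"])
        result.bin_summary = bin_stats.bin_summary(
            result.vivo_profiles, result.vitro_profiles, label_map
        )
    return result
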