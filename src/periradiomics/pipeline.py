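"""End-to-end experiment orchestration on synthetic cohorts.

Experiment 1 (all-comers): a 78-patient training cohort (24 pCR / 54
non-pCR) and a 39-patient holdout (12 / 27).  Feature discovery, feature
normalization and classifier training touch only the training cohort; the
holdout is evaluated once.  Consensus clustering is run on the training
cohort with four feature sets: combined intratumoral + peritumoral top
features, intratumoral-only, peritumoral-only, and the 15 PK statistical
features.

Experiment 2 (receptor groups): group-restricted discovery and repeated
cross-validated evaluation, with per-iteration downsampling of the
majority class to 20 in the imbalanced HR+HER2- group (10 pCR / 60
non-pCR) and no downsampling in the TN/HER2+ group (26 / 21).  Discovery
and evaluation share the same patient pool, as in the study protocol; this
is logged as optimistic in the report bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify, consensus, discovery, features, synthetic
from .features import FeatureTable
from .regions import peritumoral_ring

RECEPTOR_GROUPS = {
    "all_comers": None,
    "HR+HER2-": {"n_pcr": 10, "n_non_pcr": 60, "downsample": 20},
    "TN/HER2+": {"n_pcr": 26, "n_non_pcr": 21, "downsample": None},
}


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str = "all_comers"
    seed: int = 0
    phantom_defaults: synthetic.PhantomConfig = field(default_factory=synthetic.PhantomConfig)
    discovery_config: discovery.DiscoveryConfig = field(default_factory=discovery.DiscoveryConfig)
    consensus_config: consensus.ConsensusConfig = field(default_factory=consensus.ConsensusConfig)
    classifier_kinds: tuple[str, ...] = classify.CLASSIFIER_KINDS
    cv_repeats: int = 50
    cv_folds: int = 3
    n_train_pcr: int = 24
    n_train_non_pcr: int = 54
    n_test_pcr: int = 12
    n_test_non_pcr: int = 27
    include_pk: bool = True


@dataclass
class LeakageAudit:
    """Patient-id provenance of every training-side computation."""

    training_ids: set = field(default_factory=set)
    holdout_ids: set = field(default_factory=set)
    normalization_reference_ids: set = field(default_factory=set)
    discovery_ids: set = field(default_factory=set)
    model_fit_ids: set = field(default_factory=set)

    def holdout_is_clean(self) -> bool:
        touched = self.normalization_reference_ids | self.discovery_ids | self.model_fit_ids
        return not (touched & self.holdout_ids)


def extract_cohort_features(
    patients: list[synthetic.PhantomPatient],
    include_pk: bool = True,
) -> FeatureTable:
    """Run ring construction + feature extraction over a phantom cohort."""
    rows, labels, groups, ids = [], [], [], []
    for p in patients:
        region = peritumoral_ring(p.tumor_mask, p.series.pixel_spacing_mm)
        rows.append(features.extract_patient_features(p.series, region, include_pk=include_pk))
        labels.append(1 if p.label == "pCR" else 0)
        groups.append(p.group)
        ids.append(p.patient_id)
    df = pd.DataFrame(rows, index=ids)
    return FeatureTable(df, labels=np.asarray(labels), groups=np.asarray(groups))


def _column_subsets(table: FeatureTable) -> dict[str, list[str]]:
    """Radiomic / intratumoral / peritumoral / PK column groups."""
    radiomic, intra, peri, pk = [], [], [], []
    for name in table.columns:
        fid = features.FeatureId.from_name(name)
        if fid.family == "PK":
            pk.append(name)
            continue
        radiomic.append(name)
        (intra if fid.region == "intratumoral" else peri).append(name)
    return {"radiomic": radiomic, "intratumoral": intra, "peritumoral": peri, "PK": pk}


def run_experiment1(
    config: ExperimentConfig,
    precomputed: tuple[FeatureTable, FeatureTable] | None = None,
) -> dict:
    """All-comers pipeline: discovery, four consensus runs, CV, holdout."""
    audit = LeakageAudit()
    if precomputed is None:
        train_patients = synthetic.generate_cohort(
            synthetic.CohortSpec(config.n_train_pcr, config.n_train_non_pcr, "train", config.seed),
            config.phantom_defaults,
        )
        test_patients = synthetic.generate_cohort(
            synthetic.CohortSpec(config.n_test_pcr, config.n_test_non_pcr, "test", config.seed + 10_000),
            config.phantom_defaults,
        )
        train_raw = extract_cohort_features(train_patients, config.include_pk)
        test_raw = extract_cohort_features(test_patients, config.include_pk)
    else:
        train_raw, test_raw = precomputed
    audit.training_ids = set(train_raw.df.index)
    audit.holdout_ids = set(test_raw.df.index)

    train = features.normalize_features(train_raw)
    test = features.normalize_features(test_raw, reference=train_raw)
    audit.normalization_reference_ids = set(train_raw.df.index)

    subsets = _column_subsets(train)
    y_train = train.labels.to_numpy()
    y_test = test.labels.to_numpy()

    disc_cfg = replace(config.discovery_config, seed=config.seed)
    disc = {}
    for name in ("radiomic", "intratumoral", "peritumoral"):
        disc[name] = discovery.discovery_protocol(
            train.subset_features(subsets[name]), y_train, disc_cfg
        )
    audit.discovery_ids = set(train.df.index)

    cons_cfg = replace(config.consensus_config, seed=config.seed)
    consensus_sets = {
        "combined": disc["radiomic"].top_features,
        "intratumoral": disc["intratumoral"].top_features,
        "peritumoral": disc["peritumoral"].top_features,
        "PK": subsets["PK"],
    }
    cons = {}
    for name, cols in consensus_sets.items():
        if not cols:
            continue
        cm = consensus.consensus_cluster(train.subset_features(cols), cons_cfg)
        cons[name] = {
            "matrix": cm,
            "accuracy": consensus.cluster_label_accuracy(cm.final_assignment, y_train),
        }

    top = disc["radiomic"].top_features
    cv_reports, holdout_reports = {}, {}
    for kind in config.classifier_kinds:
        cv_reports[kind] = classify.sequential_feature_eval(
            train, y_train, top, kind,
            mode="cv", n_repeats=config.cv_repeats, n_folds=config.cv_folds,
            seed=config.seed,
        )
        holdout_reports[kind] = classify.sequential_feature_eval(
            train, y_train, top, kind,
            mode="holdout", test_table=test, test_labels=y_test,
        )
    audit.model_fit_ids = set(train.df.index)

    return {
        "experiment": "all_comers",
        "seed": config.seed,
        "discovery": disc,
        "consensus": cons,
        "cv_reports": cv_reports,
        "holdout_reports": holdout_reports,
        "audit": audit,
        "n_train": train.n_patients,
        "n_test": test.n_patients,
    }


def run_experiment2(
    config: ExperimentConfig,
    precomputed: FeatureTable | None = None,
) -> dict:
    """Receptor-group pipeline: group discovery + repeated CV evaluation."""
    group = config.experiment
    if group not in RECEPTOR_GROUPS or group == "all_comers":
        raise ValueError(f"experiment must name a receptor group, got {group!r}")
    sizes = RECEPTOR_GROUPS[group]
    if precomputed is None:
        patients = synthetic.generate_cohort(
            synthetic.CohortSpec(sizes["n_pcr"], sizes["n_non_pcr"], group, config.seed),
            config.phantom_defaults,
        )
        raw = extract_cohort_features(patients, config.include_pk)
    else:
        raw = precomputed
    if raw.n_patients < 6:
        raise ValueError("receptor group must have at least 6 patients")
    table = features.normalize_features(raw)
    y = table.labels.to_numpy()

    subsets = _column_subsets(table)
    disc_cfg = replace(
        config.discovery_config,
        seed=config.seed,
        downsample_majority_to=sizes["downsample"],
    )
    disc = discovery.discovery_protocol(table.subset_features(subsets["radiomic"]), y, disc_cfg)

    cv_reports = {
        kind: classify.sequential_feature_eval(
            table, y, disc.top_features, kind,
            mode="cv", n_repeats=config.cv_repeats, n_folds=config.cv_folds,
            seed=config.seed,
        )
        for kind in config.classifier_kinds
    }
    return {
        "experiment": group,
        "seed": config.seed,
        "discovery": disc,
        "cv_reports": cv_reports,
        "n_patients": table.n_patients,
        "note": "discovery and evaluation share the patient pool (optimistic)",
    }


def bundle_summary(bundle: dict) -> dict:
    """JSON-serializable summary of a report bundle (for hashing/diffing)."""
    out = {"experiment": bundle["experiment"], "seed": bundle["seed"]}
    disc = bundle["discovery"]
    if isinstance(disc, dict):
        out["top_features"] = {k: v.top_features for k, v in disc.items()}
    else:
        out["top_features"] = disc.top_features
    if "consensus" in bundle:
        out["consensus_accuracy"] = {k: v["accuracy"] for k, v in bundle["consensus"].items()}
    for key in ("cv_reports", "holdout_reports"):
        if key in bundle:
            out[key] = {
                kind: [r.as_dict() for r in reports]
                for kind, reports in bundle[key].items()
            }
    return out


def bundle_hash(bundle: dict) -> str:
    payload = json.dumps(bundle_summary(bundle), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
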