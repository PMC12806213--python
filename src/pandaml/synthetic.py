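"""Synthetic multi-batch LC-MS cohort generator with known ground truth.

Emulates the statistical structure the pipeline assumes: log-normal base
intensities spanning 1e4-1e7 (so the 1e5 QC intensity filter has bite),
class effects on a subset of informative features (standardized mean
difference ``effect_size`` on the log scale), per-batch multiplicative
batch effects, interleaved HSQC/PQC quality-control injections with a
target replicate CV, blanks near zero, stage-linear trend features, shared
latent-factor correlation blocks, and MCAR missingness.

Every generator is a pure function of its spec and seed. Informative
features are drawn from the features whose base intensity clears the
default 1e5 QC filter with margin, so injected class signal survives the
standard preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, PathwayDB, write_pathway_db

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_staged_cohort",
    "generate_pathway_structure",
]


@dataclass
class CohortSpec:
    """Knobs of the simulated study design (defaults mirror a multi-batch
    plasma metabolomics cohort: 240 features across 11 analytical batches)."""

    n_per_class: dict = field(default_factory=lambda: {"HC": 100, "CRC": 100})
    n_features: int = 240
    n_informative: int = 20
    effect_size: float = 1.0
    n_batches: int = 11
    batch_effect_sd: float = 0.3
    qc_per_batch: int = 3
    pqc_per_batch: int = 1
    qc_cv: float = 0.1
    missing_rate: float = 0.02
    correlated_blocks: list = field(default_factory=list)  # [(size, rho), ...]
    stage_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for size, rho in self.correlated_blocks:
            if not -1 < rho < 1:
                raise ValueError(f"block correlation {rho} outside (-1, 1)")
            if size > self.n_features:
                raise ValueError("correlated block larger than feature count")
        if self.n_batches < 1 or self.n_features < 1:
            raise ValueError("n_batches and n_features must be positive")


@dataclass
class GroundTruth:
    """What was injected: signed effects, trends, batch multipliers."""

    informative_effects: dict        # feature id -> signed log-scale effect (d units)
    trend_slopes: dict               # feature id -> per-stage log slope
    batch_multipliers: dict          # batch -> per-feature multiplier array
    feature_log_mean: np.ndarray
    feature_log_sd: np.ndarray
    pathways: dict = field(default_factory=dict)


def _base_feature_params(spec: CohortSpec, rng: np.random.Generator):
    log_mean = rng.uniform(np.log(1e4), np.log(1e7), size=spec.n_features)
    log_sd = rng.uniform(0.2, 0.6, size=spec.n_features)
    return log_mean, log_sd


def _pick_informative(spec: CohortSpec, log_mean, rng):
    """Informative ids come from features comfortably above the intensity
    filter, so class signal is not destroyed by QC filtering."""
    eligible = np.flatnonzero(log_mean > np.log(3e5))
    if len(eligible) < spec.n_informative:
        eligible = np.argsort(log_mean)[-spec.n_informative:]
    return np.sort(rng.choice(eligible, size=spec.n_informative, replace=False))


def _assign_blocks(spec: CohortSpec, informative_idx, rng):
    """Correlated noise blocks drawn from non-informative features."""
    pool = np.setdiff1d(np.arange(spec.n_features), informative_idx)
    rng.shuffle(pool)
    blocks = []
    start = 0
    for size, rho in spec.correlated_blocks:
        take = pool[start:start + size]
        if len(take) < size:
            raise ValueError("not enough non-informative features for the "
                             "requested correlation blocks")
        blocks.append((take, rho))
        start += size
    return blocks


def _sample_layout(spec: CohortSpec, rng):
    """Class labels, batch assignment and QC/blank injections."""
    classes = list(spec.n_per_class)
    labels = [c for c in classes for _ in range(spec.n_per_class[c])]
    rng.shuffle(labels)  # randomized run order across batches
    n_bio = len(labels)
    batch_of_bio = np.array_split(np.arange(n_bio), spec.n_batches)
    return classes, labels, batch_of_bio


def generate_cohort(spec: CohortSpec):
    """Simulate a two-(or multi-)class cohort; returns (FeatureTable, GroundTruth).

    Class 0 in ``n_per_class`` order is the reference; each later class k
    shifts every informative feature by ``k * effect_size * sigma_j`` on
    the log scale, with a random sign per feature shared across classes.
    """
    rng = np.random.default_rng(spec.seed)
    log_mean, log_sd = _base_feature_params(spec, rng)
    informative_idx = _pick_informative(spec, log_mean, rng)
    signs = rng.choice([-1.0, 1.0], size=len(informative_idx))
    blocks = _assign_blocks(spec, informative_idx, rng)
    classes, labels, batch_of_bio = _sample_layout(spec, rng)
    class_index = {c: k for k, c in enumerate(classes)}

    batch_names = [f"B{b + 1:02d}" for b in range(spec.n_batches)]
    batch_mult = {b: np.exp(rng.normal(0.0, spec.batch_effect_sd,
                                       size=spec.n_features))
                  for b in batch_names}

    sample_ids, roles, batches, class_col = [], [], [], []
    rows = []
    grand_median = np.exp(log_mean)

    for b, bio_idx in enumerate(batch_of_bio):
        bname = batch_names[b]
        mult = batch_mult[bname]
        # biological samples of this batch
        for i in bio_idx:
            lab = labels[i]
            z = rng.standard_normal(spec.n_features)
            for cols, rho in blocks:
                f = rng.standard_normal()
                z[cols] = np.sqrt(rho) * f + np.sqrt(1 - rho) * z[cols]
            logx = log_mean + log_sd * z
            logx[informative_idx] += (class_index[lab] * spec.effect_size
                                      * signs * log_sd[informative_idx])
            rows.append(np.exp(logx) * mult)
            sample_ids.append(f"S{i + 1:04d}")
            roles.append("biological")
            batches.append(bname)
            class_col.append(lab)
        # QC injections and blanks
        for kind, count in (("hsqc", spec.qc_per_batch),
                            ("pqc", spec.pqc_per_batch)):
            for r in range(count):
                noise = np.clip(rng.normal(1.0, spec.qc_cv, spec.n_features),
                                0.05, None)
                rows.append(grand_median * mult * noise)
                sample_ids.append(f"{kind.upper()}_{bname}_{r + 1}")
                roles.append(kind)
                batches.append(bname)
                class_col.append("")
        rows.append(rng.uniform(1.0, 50.0, size=spec.n_features))
        sample_ids.append(f"BLANK_{bname}")
        roles.append("blank")
        batches.append(bname)
        class_col.append("")

    X = np.vstack(rows)
    bio_rows = np.asarray([r == "biological" for r in roles])
    if spec.missing_rate > 0:
        miss = rng.random(X.shape) < spec.missing_rate
        miss[~bio_rows] = False
        X[miss] = np.nan

    table = FeatureTable(
        sample_ids=sample_ids,
        feature_ids=[f"met_{j + 1:03d}" for j in range(spec.n_features)],
        intensities=X, batch=batches, role=roles,
        class_label=[c if c else None for c in class_col])
    truth = GroundTruth(
        informative_effects={table.feature_ids[j]: float(s * spec.effect_size)
                             for j, s in zip(informative_idx, signs)},
        trend_slopes={},
        batch_multipliers=batch_mult,
        feature_log_mean=log_mean, feature_log_sd=log_sd)
    return table, truth


def generate_staged_cohort(spec: CohortSpec, stages=("T1", "T2", "T3", "T4")):
    """Simulate a staged (ordinal multiclass) cohort.

    ``n_per_class`` is reinterpreted as stage -> count if its keys match
    ``stages``; otherwise samples are split evenly across stages. Trend
    features (``n_informative`` of them) get mean log-abundance
    ``baseline + stage_slope * stage_index``; all other features are flat.
    The stage label is stored both as the class label (for classification
    workflows) and in ``stage_t``/``stage_n`` as appropriate.
    """
    stages = list(stages)
    if len(stages) < 3:
        raise ValueError("need at least 3 ordered stages")
    rng = np.random.default_rng(spec.seed)
    log_mean, log_sd = _base_feature_params(spec, rng)
    trend_idx = _pick_informative(spec, log_mean, rng)
    blocks = _assign_blocks(spec, trend_idx, rng)

    if set(spec.n_per_class) == set(stages):
        counts = {s: spec.n_per_class[s] for s in stages}
    else:
        total = sum(spec.n_per_class.values())
        per = total // len(stages)
        counts = {s: per for s in stages}
        for s in stages[: total - per * len(stages)]:
            counts[s] += 1
    labels = [s for s in stages for _ in range(counts[s])]
    rng.shuffle(labels)
    stage_code = {s: k for k, s in enumerate(stages)}

    batch_names = [f"B{b + 1:02d}" for b in range(spec.n_batches)]
    batch_mult = {b: np.exp(rng.normal(0.0, spec.batch_effect_sd,
                                       size=spec.n_features))
                  for b in batch_names}
    batch_of_bio = np.array_split(np.arange(len(labels)), spec.n_batches)
    grand_median = np.exp(log_mean)

    sample_ids, roles, batches, stage_col = [], [], [], []
    rows = []
    for b, bio_idx in enumerate(batch_of_bio):
        bname = batch_names[b]
        mult = batch_mult[bname]
        for i in bio_idx:
            lab = labels[i]
            z = rng.standard_normal(spec.n_features)
            for cols, rho in blocks:
                f = rng.standard_normal()
                z[cols] = np.sqrt(rho) * f + np.sqrt(1 - rho) * z[cols]
            logx = log_mean + log_sd * z
            logx[trend_idx] += spec.stage_slope * stage_code[lab]
            rows.append(np.exp(logx) * mult)
            sample_ids.append(f"S{i + 1:04d}")
            roles.append("biological")
            batches.append(bname)
            stage_col.append(lab)
        for r in range(spec.qc_per_batch):
            noise = np.clip(rng.normal(1.0, spec.qc_cv, spec.n_features),
                            0.05, None)
            rows.append(grand_median * mult * noise)
            sample_ids.append(f"HSQC_{bname}_{r + 1}")
            roles.append("hsqc")
            batches.append(bname)
            stage_col.append("")

    X = np.vstack(rows)
    bio_rows = np.asarray([r == "biological" for r in roles])
    if spec.missing_rate > 0:
        miss = rng.random(X.shape) < spec.missing_rate
        miss[~bio_rows] = False
        X[miss] = np.nan

    is_t = str(stages[0]).upper().startswith("T")
    stage_list = [s if s else None for s in stage_col]
    table = FeatureTable(
        sample_ids=sample_ids,
        feature_ids=[f"met_{j + 1:03d}" for j in range(spec.n_features)],
        intensities=X, batch=batches, role=roles,
        class_label=stage_list,
        stage_t=stage_list if is_t else None,
        stage_n=None if is_t else stage_list)
    truth = GroundTruth(
        informative_effects={},
        trend_slopes={table.feature_ids[j]: float(spec.stage_slope)
                      for j in trend_idx},
        batch_multipliers=batch_mult,
        feature_log_mean=log_mean, feature_log_sd=log_sd)
    return table, truth


def generate_pathway_structure(n_pathways: int, sizes, n_signal: int,
                               db_path, feature_ids, signal_feature_ids,
                               seed: int = 0):
    """Write a GMT where the first ``n_signal`` pathways are loaded with
    signal-carrying features and the rest draw members at random.

    ``sizes`` is an int or a per-pathway sequence. Returns the PathwayDB
    and a mapping pathway -> its signal members.
    """
    rng = np.random.default_rng(seed)
    if isinstance(sizes, int):
        sizes = [sizes] * n_pathways
    sizes = list(sizes)
    if len(sizes) != n_pathways:
        raise ValueError("sizes must match n_pathways")
    feature_ids = list(feature_ids)
    signal_pool = list(signal_feature_ids)
    if max(sizes) > len(feature_ids):
        raise ValueError("pathway size exceeds feature count")
    pathways, descriptions, signal_map = {}, {}, {}
    for k in range(n_pathways):
        name = f"PW{k + 1:03d}"
        size = sizes[k]
        if k < n_signal:
            n_sig = min(size, len(signal_pool))
            sig = list(rng.choice(signal_pool, size=n_sig, replace=False))
            rest_pool = [f for f in feature_ids if f not in sig]
            rest = list(rng.choice(rest_pool, size=size - n_sig, replace=False))
            members = sig + rest
            signal_map[name] = sig
            descriptions[name] = "signal pathway"
        else:
            members = list(rng.choice(feature_ids, size=size, replace=False))
            descriptions[name] = "null pathway"
        pathways[name] = set(members)
    db = PathwayDB(pathways, descriptions)
    write_pathway_db(db, db_path)
    return db, signal_map
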