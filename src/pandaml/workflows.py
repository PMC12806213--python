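"""Benchmark harness: splits, the four classification workflows, metrics.

The four workflows share one stratified 60:30:10 train/validation/test
split of the biological samples (a 90:10 outer split for modelling vs test,
with the 90 split 60:30 into train vs validation):

- ``plsda_classifier`` — PLS-DA fit on train+validation, test classified by
  Mahalanobis distance to class centroids in score space.
- ``ann_raw`` — hyperparameter-searched MLP on all features.
- ``ann_autoencoder`` — autoencoder compression (latent dim selected by
  validation accuracy) then an MLP on the latent codes.
- ``panda`` — PLS reduction (default 8 components) fit on the training
  partition only, validation/test projected, then a hyperparameter-searched
  MLP on the component scores.

Repeated Monte-Carlo resampling (``cross_validate``) and a paired
comparison across workflows on identical partitions (``compare_workflows``)
give the aggregate accuracy/AUC/loss numbers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import neuralnet as nn
from . import plsda
from .io import FeatureTable, RunConfig

logger = logging.getLogger(__name__)

WORKFLOW_KINDS = ("plsda_classifier", "ann_raw", "ann_autoencoder", "panda")

__all__ = [
    "SplitSpec",
    "WorkflowResult",
    "WORKFLOW_KINDS",
    "split_dataset",
    "run_workflow",
    "evaluate",
    "cross_validate",
    "compare_workflows",
]


@dataclass
class SplitSpec:
    train_frac: float = 0.60
    val_frac: float = 0.30
    test_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions sum to {total}, expected 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("split fractions must be positive")


@dataclass
class WorkflowResult:
    kind: str
    accuracy: list[float] = field(default_factory=list)
    auc: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    chosen: list = field(default_factory=list)
    histories: list = field(default_factory=list)
    split_digests: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        def agg(v):
            a = np.asarray(v, dtype=float)
            return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0}
        return {"kind": self.kind, "n_repeats": len(self.accuracy),
                "accuracy": agg(self.accuracy), "auc": agg(self.auc),
                "loss": agg(self.loss)}


def split_dataset(table: FeatureTable, spec: SplitSpec):
    """Stratified train/validation/test partition of biological samples.

    QC and blank roles are excluded. Partitions are disjoint, exhaustive
    over the biological samples, reproducible from the seed, and every
    class lands in every partition (at least one sample) when feasible.
    """
    if table.class_label is None:
        raise ValueError("table has no class labels")
    bio_idx = np.flatnonzero(table.role_mask("biological"))
    y = np.asarray([table.class_label[i] for i in bio_idx], dtype=object)
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for c in sorted({str(v) for v in y}):
        members = bio_idx[y == c]
        n_c = len(members)
        if n_c < 3:
            raise ValueError(
                f"class {c!r} has only {n_c} biological samples; cannot place "
                "it in all three partitions")
        members = rng.permutation(members)
        n_test = max(1, int(round(spec.test_frac * n_c)))
        n_val = max(1, int(round(spec.val_frac * n_c)))
        if n_test + n_val >= n_c:
            n_test, n_val = 1, 1
        test_idx.extend(members[:n_test])
        val_idx.extend(members[n_test:n_test + n_val])
        train_idx.extend(members[n_test + n_val:])
    parts = tuple(table.subset_samples(np.asarray(sorted(ix), dtype=int))
                  for ix in (train_idx, val_idx, test_idx))
    return parts


def split_digest(parts) -> str:
    """Stable hash of a partition (for asserting paired designs)."""
    h = hashlib.sha256()
    for part in parts:
        h.update("|".join(part.sample_ids).encode())
        h.update(b";")
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _binary_auc(scores, positive_mask):
    """Mann-Whitney AUC with midranks for ties."""
    n_pos = int(positive_mask.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[positive_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate(prob_matrix, truth, class_levels):
    """(accuracy, auc, loss) of row-stochastic predictions against labels.

    AUC is the rank-based (Mann-Whitney) statistic for binary problems and
    the macro one-vs-rest average over classes present in ``truth`` for
    multiclass; loss is mean categorical cross-entropy.
    """
    P = np.asarray(prob_matrix, dtype=float)
    truth = np.asarray(truth, dtype=object)
    if P.shape[0] != len(truth):
        raise ValueError("probability rows do not match number of labels")
    if P.shape[1] != len(class_levels):
        raise ValueError("probability columns do not match class count")
    unseen = set(truth.tolist()) - set(class_levels)
    if unseen:
        raise ValueError(f"truth contains unseen classes: {sorted(unseen)}")
    Y, _ = plsda.dummy_code(truth, class_levels)
    accuracy = float((P.argmax(axis=1) == Y.argmax(axis=1)).mean())
    aucs = []
    for k in range(len(class_levels)):
        auc_k = _binary_auc(P[:, k], Y[:, k] == 1)
        if np.isfinite(auc_k):
            aucs.append(auc_k)
    auc = float(np.mean(aucs)) if aucs else np.nan
    loss = -float(np.sum(Y * np.log(np.clip(P, 1e-12, None)))) / len(truth)
    return accuracy, auc, loss


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def _xy(part: FeatureTable):
    return part.intensities, np.asarray(part.class_label, dtype=object)


def _grid_for(config: RunConfig):
    if config.grid is not None:
        return config.grid
    return nn.compact_search_grid(epochs=config.epochs, seed=config.seed)


def run_workflow(table: FeatureTable, kind: str, config: RunConfig,
                 split=None):
    """Run one workflow on one split; returns a single-repeat WorkflowResult."""
    if kind not in WORKFLOW_KINDS:
        raise ValueError(f"unknown workflow kind {kind!r}; "
                         f"choose from {WORKFLOW_KINDS}")
    if split is None:
        split = split_dataset(table, SplitSpec(config.train_frac,
                                               config.val_frac,
                                               config.test_frac, config.seed))
    train, val, test = split
    X_tr, y_tr = _xy(train)
    X_va, y_va = _xy(val)
    X_te, y_te = _xy(test)
    result = WorkflowResult(kind=kind)
    result.split_digests.append(split_digest(split))

    if kind == "plsda_classifier":
        # PLS-DA plot is built on train+validation; test classified by
        # Mahalanobis distance in the retained component space.
        X_fit = np.vstack([X_tr, X_va])
        y_fit = np.concatenate([y_tr, y_va])
        ncomp = min(config.n_components, X_fit.shape[0] - 1, X_fit.shape[1])
        model = plsda.fit_pls(X_fit, y_fit, n_components=ncomp)
        P = plsda.classify_proba(model, X_te)
        acc, auc, loss = evaluate(P, y_te, model.class_levels)
        result.chosen.append({"n_components": model.n_components})
        result.histories.append(None)
    elif kind == "ann_raw":
        best, model, _tab = nn.hyperparameter_search(
            X_tr, y_tr, X_va, y_va, _grid_for(config), seed=config.seed)
        P = nn.predict_proba(model, X_te)
        acc, auc, loss = evaluate(P, y_te, model.class_levels)
        result.chosen.append(best)
        result.histories.append(_tab)
    elif kind == "ann_autoencoder":
        base = nn.AnnConfig(hidden_layers=1, layer_size=30,
                            learning_rate=1e-3, epochs=config.epochs,
                            seed=config.seed)
        ae_cfg = nn.AnnConfig(hidden_layers=0, layer_size=30,
                              learning_rate=1e-2, epochs=config.epochs,
                              seed=config.seed)
        dims = [d for d in config.ae_dims if d < X_tr.shape[1]]
        best_dim, _dim_tab = nn.select_latent_dim(
            X_tr, y_tr, X_va, y_va, dims=dims, config=ae_cfg)
        ae = nn.train_autoencoder(X_tr, best_dim, ae_cfg)
        best, model, _tab = nn.hyperparameter_search(
            ae.encode(X_tr), y_tr, ae.encode(X_va), y_va,
            _grid_for(config), seed=config.seed)
        P = nn.predict_proba(model, ae.encode(X_te))
        acc, auc, loss = evaluate(P, y_te, model.class_levels)
        result.chosen.append({"latent_dim": best_dim, "ann": best})
        result.histories.append(_tab)
    else:  # panda
        ncomp = min(config.n_components, X_tr.shape[0] - 1, X_tr.shape[1])
        pls_model = plsda.fit_pls(X_tr, y_tr, n_components=ncomp)
        T_tr = plsda.project(pls_model, X_tr)
        T_va = plsda.project(pls_model, X_va)
        T_te = plsda.project(pls_model, X_te)
        best, model, _tab = nn.hyperparameter_search(
            T_tr, y_tr, T_va, y_va, _grid_for(config), seed=config.seed)
        P = nn.predict_proba(model, T_te)
        acc, auc, loss = evaluate(P, y_te, model.class_levels)
        result.chosen.append({"n_components": pls_model.n_components,
                              "ann": best})
        result.histories.append(_tab)

    result.accuracy.append(acc)
    result.auc.append(auc)
    result.loss.append(loss)
    return result


def cross_validate(table: FeatureTable, kind: str, n_repeats: int,
                   config: RunConfig) -> WorkflowResult:
    """Repeated Monte-Carlo splitting: repeat i uses split seed seed+i."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    agg = WorkflowResult(kind=kind)
    for i in range(n_repeats):
        spec = SplitSpec(config.train_frac, config.val_frac,
                         config.test_frac, config.seed + i)
        split = split_dataset(table, spec)
        rep = run_workflow(table, kind, config, split=split)
        agg.accuracy += rep.accuracy
        agg.auc += rep.auc
        agg.loss += rep.loss
        agg.chosen += rep.chosen
        agg.histories += rep.histories
        agg.split_digests += rep.split_digests
    return agg


def compare_workflows(table: FeatureTable, kinds, n_repeats: int,
                      config: RunConfig) -> pd.DataFrame:
    """Paired comparison: every kind sees identical partitions per repeat.

    Returns one row per kind with mean/sd metrics plus the paired mean
    accuracy difference to the first kind listed.
    """
    kinds = list(kinds)
    if len(kinds) < 2:
        raise ValueError("need at least 2 workflow kinds to compare")
    results = [WorkflowResult(kind=k) for k in kinds]
    for i in range(n_repeats):
        spec = SplitSpec(config.train_frac, config.val_frac,
                         config.test_frac, config.seed + i)
        split = split_dataset(table, spec)
        digest = split_digest(split)
        for res in results:
            rep = run_workflow(table, res.kind, config, split=split)
            assert rep.split_digests[0] == digest  # paired design
            res.accuracy += rep.accuracy
            res.auc += rep.auc
            res.loss += rep.loss
            res.split_digests += rep.split_digests
    base_acc = np.asarray(results[0].accuracy)
    rows = []
    for res in results:
        k = res.kind
        acc = np.asarray(res.accuracy)
        rows.append({
            "kind": k,
            "accuracy_mean": float(acc.mean()),
            "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            "auc_mean": float(np.nanmean(res.auc)),
            "loss_mean": float(np.mean(res.loss)),
            "paired_accuracy_diff_vs_first": float((acc - base_acc).mean()),
        })
    return pd.DataFrame(rows).set_index("kind")
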