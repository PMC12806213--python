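"""Feature-level and pathway-level statistics.

Covers volcano-style differential selection (Welch t + Benjamini-Hochberg),
the strict fold-change/FDR gene filter used for mutation subgroups,
reference-group metabolite z-scores, ordinal stage trend screening (OLS
slope on integer-coded stages) and one-way ANOVA stage selection, and
directional pathway aggregation by Stouffer's method (sum z / sqrt(n)),
including the two-layer gene+metabolite integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, PathwayDB

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureStat",
    "PathwayScore",
    "volcano_select",
    "gene_mutation_filter",
    "metabolite_zscore",
    "stage_trend_test",
    "stage_anova_select",
    "pathway_zscore",
    "integrate_omics",
]

STAGE_CODES = {"T1": 0, "T2": 1, "T3": 2, "T4": 3, "N0": 0, "N1": 1, "N2": 2}


@dataclass
class FeatureStat:
    feature_id: str
    log2fc: float
    p: float
    q: float
    mean_a: float
    mean_b: float
    significant: bool


@dataclass
class PathwayScore:
    name: str
    n_members: int
    z: float
    member_ids: list[str]
    member_z: dict
    direction: int  # sign of the aggregate


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_values(table: FeatureTable, label, field: str = "class_label"):
    vec = getattr(table, field)
    if vec is None:
        raise ValueError(f"table has no {field} metadata")
    bio = table.role_mask("biological")
    mask = bio & np.asarray([v == label for v in vec])
    return table.intensities[mask]


def volcano_select(table: FeatureTable, group_a, group_b,
                   fc_threshold: float = np.log2(1.5),
                   q_threshold: float = 0.05) -> list[FeatureStat]:
    """Differential features between two groups on log-scale values.

    Per feature: Welch two-sided t-test of B vs A; log2 fold change is the
    difference of group means (values are assumed already log2-scale);
    BH adjustment across all features. A feature is flagged significant
    when q < ``q_threshold`` and |log2fc| > ``fc_threshold``.
    """
    A = _group_values(table, group_a)
    B = _group_values(table, group_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 biological samples")
    t, p = stats.ttest_ind(B, A, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    log2fc = B.mean(axis=0) - A.mean(axis=0)
    q = bh_adjust(p)
    out = []
    for j, fid in enumerate(table.feature_ids):
        sig = bool(q[j] < q_threshold and abs(log2fc[j]) > fc_threshold)
        out.append(FeatureStat(fid, float(log2fc[j]), float(p[j]), float(q[j]),
                               float(A[:, j].mean()), float(B[:, j].mean()), sig))
    return out


def gene_mutation_filter(expression_stats: list[FeatureStat],
                         fc_max: float = 0.5,
                         q_max: float = 0.05) -> list[FeatureStat]:
    """Keep genes with linear-scale fold change < ``fc_max`` AND q < ``q_max``
    (both strict). ``log2fc`` in the stats is converted back to the linear
    ratio for the comparison."""
    kept = []
    for s in expression_stats:
        fc_linear = 2.0 ** s.log2fc
        if fc_linear < fc_max and s.q < q_max:
            kept.append(s)
    return kept


def metabolite_zscore(table: FeatureTable, reference_group, target_group):
    """Per-sample z-scores relative to the reference group.

    z(sample, feature) = (x - mean_ref) / sd_ref; the summary is the mean z
    over target-group samples. Features with zero reference sd are skipped
    with a warning. Returns ``(z_frame, mean_z_series)`` where ``z_frame``
    covers both groups' samples.
    """
    R = _group_values(table, reference_group)
    if R.shape[0] < 2:
        raise ValueError("reference group needs at least 2 samples")
    mean_ref = R.mean(axis=0)
    sd_ref = R.std(axis=0, ddof=1)
    usable = sd_ref > 0
    if not usable.all():
        skipped = [f for f, u in zip(table.feature_ids, usable) if not u]
        logger.warning("skipping %d features with zero reference sd: %s",
                       len(skipped), skipped[:10])
    vec = np.asarray(table.class_label)
    bio = table.role_mask("biological")
    both = bio & np.isin(vec, [reference_group, target_group])
    Z = (table.intensities[both][:, usable] - mean_ref[usable]) / sd_ref[usable]
    z_frame = pd.DataFrame(
        Z, index=[s for s, m in zip(table.sample_ids, both) if m],
        columns=[f for f, u in zip(table.feature_ids, usable) if u])
    target = bio & (vec == target_group)
    Zt = (table.intensities[target][:, usable] - mean_ref[usable]) / sd_ref[usable]
    mean_z = pd.Series(Zt.mean(axis=0), index=z_frame.columns, name="mean_z")
    return z_frame, mean_z


def _stage_codes(labels):
    coded = []
    for lab in labels:
        if lab in STAGE_CODES:
            coded.append(STAGE_CODES[lab])
        else:
            coded.append(None)
    known = sorted({c for c in coded if c is not None})
    if not known:  # arbitrary ordinal labels: code by sort order
        uniq = sorted({str(x) for x in labels if x not in (None, "")})
        mapping = {u: i for i, u in enumerate(uniq)}
        coded = [mapping.get(str(x)) for x in labels]
    return np.asarray([np.nan if c is None else float(c) for c in coded])


def stage_trend_test(table: FeatureTable, stage_field: str = "stage_t") -> pd.DataFrame:
    """Per-feature OLS of value on integer-coded ordinal stage.

    T1..T4 code to 0..3 and N0..N2 to 0..2; other label sets code by sorted
    order. Two-sided t-test on the slope, BH across features. Returns a
    frame with columns slope, p, q indexed by feature id.
    """
    labels = getattr(table, stage_field)
    if labels is None:
        raise ValueError(f"table has no {stage_field} metadata")
    bio = table.role_mask("biological")
    codes = _stage_codes(labels)
    mask = bio & np.isfinite(codes)
    x = codes[mask]
    if len(np.unique(x)) < 3:
        raise ValueError("need >=3 distinct stage levels for a trend test; "
                         "use volcano_select for two groups")
    X = table.intensities[mask]
    slopes = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        res = stats.linregress(x, X[:, j])
        slopes[j] = res.slope
        pvals[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    q = bh_adjust(pvals)
    return pd.DataFrame({"slope": slopes, "p": pvals, "q": q},
                        index=pd.Index(table.feature_ids, name="feature_id"))


def stage_anova_select(table: FeatureTable, stage_field: str = "stage_t",
                       q_threshold: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across stage groups per feature, BH-adjusted.

    Levels with fewer than 2 samples are dropped (one pooled warning).
    Returns a frame with columns F, p, q, significant.
    """
    labels = getattr(table, stage_field)
    if labels is None:
        raise ValueError(f"table has no {stage_field} metadata")
    bio = table.role_mask("biological")
    vec = np.asarray(labels, dtype=object)
    groups = {}
    for lev in sorted({str(v) for v in vec[bio] if v not in (None, "")}):
        m = bio & (vec == lev)
        if m.sum() < 2:
            logger.warning("stage level %r has <2 samples; dropped", lev)
            continue
        groups[lev] = table.intensities[m]
    if len(groups) < 2:
        raise ValueError("fewer than 2 usable stage levels")
    arrays = list(groups.values())
    F = np.empty(table.n_features)
    p = np.empty(table.n_features)
    for j in range(table.n_features):
        res = stats.f_oneway(*[a[:, j] for a in arrays])
        F[j] = res.statistic
        p[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    q = bh_adjust(p)
    return pd.DataFrame(
        {"F": F, "p": p, "q": q, "significant": q < q_threshold},
        index=pd.Index(table.feature_ids, name="feature_id"))


def pathway_zscore(member_z, db: PathwayDB, universe) -> list[PathwayScore]:
    """Directional pathway scores by Stouffer combination.

    ``member_z`` maps feature id -> z value; per pathway, members are
    intersected with ``universe`` and aggregated as sum(z) / sqrt(n).
    Pathways with no mapped member are omitted with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty feature universe")
    member_z = dict(member_z)
    out = []
    for name, members in db.items():
        mapped = sorted(members & universe & set(member_z))
        if not mapped:
            logger.warning("pathway %r has no members in the universe; omitted",
                           name)
            continue
        zvals = np.asarray([member_z[m] for m in mapped], dtype=float)
        agg = float(zvals.sum() / np.sqrt(len(zvals)))
        out.append(PathwayScore(name=name, n_members=len(mapped), z=agg,
                                member_ids=mapped,
                                member_z={m: float(z) for m, z in zip(mapped, zvals)},
                                direction=int(np.sign(agg))))
    return out


def stats_to_z(feature_stats: list[FeatureStat]) -> dict:
    """Signed z from a two-sided p-value: z = sign(log2fc) * Phi^-1(1 - p/2)."""
    out = {}
    for s in feature_stats:
        p = min(max(s.p, 1e-300), 1.0)
        z = stats.norm.isf(p / 2.0)
        out[s.feature_id] = float(np.sign(s.log2fc) * z) if s.log2fc != 0 else 0.0
    return out


def integrate_omics(metabolite_stats: list[FeatureStat],
                    gene_stats: list[FeatureStat],
                    db: PathwayDB) -> pd.DataFrame:
    """Joint gene+metabolite pathway table.

    Per pathway: Stouffer aggregate per omics layer, a combined aggregate
    over the union of members, member counts per layer, dominant direction
    per layer, and flags for partial coverage (one layer absent) and for
    layers moving in opposite directions. Empty output (with a warning) if
    no pathway maps to either id space.
    """
    met_z = stats_to_z(metabolite_stats)
    gene_z = stats_to_z(gene_stats)
    rows = []
    for name, members in db.items():
        met_members = sorted(members & set(met_z))
        gene_members = sorted(members & set(gene_z))
        if not met_members and not gene_members:
            continue
        met_vals = np.asarray([met_z[m] for m in met_members])
        gene_vals = np.asarray([gene_z[m] for m in gene_members])
        met_agg = (float(met_vals.sum() / np.sqrt(len(met_vals)))
                   if len(met_vals) else np.nan)
        gene_agg = (float(gene_vals.sum() / np.sqrt(len(gene_vals)))
                    if len(gene_vals) else np.nan)
        all_vals = np.concatenate([met_vals, gene_vals])
        combined = float(all_vals.sum() / np.sqrt(len(all_vals)))
        rows.append({
            "pathway": name,
            "n_metabolites": len(met_members),
            "n_genes": len(gene_members),
            "metabolite_z": met_agg,
            "gene_z": gene_agg,
            "combined_z": combined,
            "metabolite_direction": int(np.sign(met_agg)) if len(met_vals) else 0,
            "gene_direction": int(np.sign(gene_agg)) if len(gene_vals) else 0,
            "partial": not (met_members and gene_members),
            "opposite_directions": bool(
                met_members and gene_members
                and np.sign(met_agg) * np.sign(gene_agg) < 0),
        })
    if not rows:
        logger.warning("no pathway shares members with either omics layer")
        return pd.DataFrame(columns=[
            "pathway", "n_metabolites", "n_genes", "metabolite_z", "gene_z",
            "combined_z", "metabolite_direction", "gene_direction", "partial",
            "opposite_directions"])
    frame = pd.DataFrame(rows).set_index("pathway")
    return frame.sort_values("combined_z", key=np.abs, ascending=False)
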