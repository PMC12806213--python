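"""Data model and file I/O for intensity tables, metadata, pathways and config.

The on-disk contract: an intensity matrix as CSV/TSV (header row = feature
ids, first column = sample ids), a metadata table keyed by ``sample_id``
(columns ``class``, ``batch``, ``role``, and optionally ``stage_t``,
``stage_n``, ``mutation``) and pathway membership as GMT text. Missing
intensities are empty cells on disk and NaN in memory; zeros are measured
values, never missing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_ROLES = ("biological", "hsqc", "pqc", "blank")

__all__ = [
    "FeatureTable",
    "PathwayDB",
    "RunConfig",
    "VALID_ROLES",
    "read_feature_table",
    "write_feature_table",
    "read_pathway_db",
    "load_config",
]


class ValidationError(ValueError):
    """Raised when a table or config violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with per-sample metadata.

    ``intensities`` is a float array where NaN marks a missing measurement.
    ``role`` distinguishes biological samples from HSQC/PQC quality-control
    injections and blanks; statistics are computed on the role that each
    operation declares (QC filtering on HSQC, modelling on biological).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    intensities: np.ndarray
    batch: list[str]
    role: list[str]
    class_label: list | None = None
    stage_t: list | None = None
    stage_n: list | None = None
    mutation: list | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, p = len(self.sample_ids), len(self.feature_ids)
        if self.intensities.shape != (n, p):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{n} samples x {p} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicate {name} ids: {dupes}")
        for vec, label in ((self.batch, "batch"), (self.role, "role")):
            if len(vec) != n:
                raise ValidationError(f"{label} length {len(vec)} != {n} samples")
        bad_roles = sorted(set(self.role) - set(VALID_ROLES))
        if bad_roles:
            raise ValidationError(
                f"unknown sample roles {bad_roles}; allowed: {VALID_ROLES}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0) and not self.transformed:
                raise ValidationError("negative intensities are not allowed")
        for attr in ("class_label", "stage_t", "stage_n", "mutation"):
            vec = getattr(self, attr)
            if vec is not None and len(vec) != n:
                raise ValidationError(f"{attr} length {len(vec)} != {n} samples")

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def role_mask(self, role: str) -> np.ndarray:
        return np.asarray([r == role for r in self.role])

    def batches(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.batch:
            seen.setdefault(b, None)
        return list(seen)

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask

        def take(vec):
            return None if vec is None else [vec[i] for i in idx]

        out = FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            intensities=self.intensities[idx],
            batch=[self.batch[i] for i in idx],
            role=[self.role[i] for i in idx],
            class_label=take(self.class_label),
            stage_t=take(self.stage_t),
            stage_n=take(self.stage_n),
            mutation=take(self.mutation),
            transformed=self.transformed,
        )
        return out

    def subset_features(self, keep: Sequence[str]) -> "FeatureTable":
        index = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [index[f] for f in keep]
        return dataclasses.replace(
            self, feature_ids=list(keep), intensities=self.intensities[:, cols]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=self.sample_ids, columns=self.feature_ids
        )

    def metadata_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "class": self.class_label,
                "batch": self.batch, "role": self.role,
                "stage_t": self.stage_t, "stage_n": self.stage_n,
                "mutation": self.mutation}
        return pd.DataFrame({k: v for k, v in data.items() if v is not None})


@dataclass
class PathwayDB:
    """Mapping from pathway name to a set of member feature identifiers."""

    pathways: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> set[str]:
        return self.pathways[name]

    def items(self):
        return self.pathways.items()


@dataclass
class RunConfig:
    """Run-level parameters shared across subcommands.

    Split fractions follow the 60:30:10 design (train:validation:test over
    the whole cohort; the outer 90:10 split then 60:30 within the 90).
    """

    train_frac: float = 0.60
    val_frac: float = 0.30
    test_frac: float = 0.10
    epochs: int = 100
    n_components: int = 8
    seed: int = 0
    cv_max: float = 0.3
    intensity_min: float = 1e5
    fc_threshold: float = 1.5
    q_threshold: float = 0.05
    n_repeats: int = 10
    grid: list | None = None
    ae_dims: tuple = (2, 3, 4, 5, 6, 7, 8, 9, 10)

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"split fractions sum to {total}, expected 1")
        if self.epochs < 1 or self.n_components < 1:
            raise ValidationError("epochs and n_components must be positive")
        for name in ("cv_max", "intensity_min", "fc_threshold", "q_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_table(intensity_path, metadata_path) -> FeatureTable:
    """Read an intensity CSV/TSV plus a metadata CSV/TSV into a FeatureTable.

    Empty cells become NaN (the missing marker). Every sample in the
    intensity file must appear in the metadata, keyed by ``sample_id``.
    """
    intensity_path, metadata_path = Path(intensity_path), Path(metadata_path)
    mat = pd.read_csv(intensity_path, sep=_sep_for(intensity_path), index_col=0,
                      dtype=str, keep_default_na=False)
    values = np.full(mat.shape, np.nan)
    for j, col in enumerate(mat.columns):
        for i, raw in enumerate(mat[col]):
            if raw == "":
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValidationError(
                    f"non-numeric cell {raw!r} at sample {mat.index[i]!r}, "
                    f"feature {col!r}"
                ) from None
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str,
                       keep_default_na=False)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    missing = [s for s in mat.index if s not in meta.index]
    if missing:
        raise ValidationError(f"sample ids absent from metadata: {missing}")
    meta = meta.loc[mat.index]

    def col(name):
        if name not in meta.columns:
            return None
        vals = meta[name].tolist()
        return None if all(v == "" for v in vals) else vals

    with np.errstate(invalid="ignore"):
        has_negative = bool(np.any(values < 0))
    return FeatureTable(
        sample_ids=[str(s) for s in mat.index],
        feature_ids=[str(c) for c in mat.columns],
        intensities=values,
        batch=col("batch") or ["batch1"] * len(mat.index),
        role=col("role") or ["biological"] * len(mat.index),
        class_label=col("class"),
        stage_t=col("stage_t"),
        stage_n=col("stage_n"),
        mutation=col("mutation"),
        # negative values can only come from transformed (log/autoscaled)
        # tables; raw intensities are non-negative by contract
        transformed=has_negative,
    )


def write_feature_table(table: FeatureTable, intensity_path, metadata_path=None) -> None:
    """Write a FeatureTable to disk; missing values become empty cells.

    Values are serialized with ``repr`` so finite floats round-trip exactly.
    If ``metadata_path`` is None it is derived from the intensity path.
    """
    intensity_path = Path(intensity_path)
    if metadata_path is None:
        metadata_path = intensity_path.with_name(
            intensity_path.stem + "_metadata" + intensity_path.suffix)
    sep = _sep_for(intensity_path)
    with open(intensity_path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["sample_id", *table.feature_ids]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            cells = ["" if np.isnan(v) else repr(float(v))
                     for v in table.intensities[i]]
            fh.write(sep.join([sid, *cells]) + "\n")
    meta = table.metadata_frame()
    meta.to_csv(metadata_path, sep=_sep_for(Path(metadata_path)), index=False)


def read_pathway_db(path) -> PathwayDB:
    """Read a GMT file: tab-separated ``name<TAB>description<TAB>member...``.

    Members absent from any particular feature table are retained here;
    intersection with a measurement universe happens at scoring time.
    """
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"line {lineno}: GMT needs name, description and >=1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in pathways:
                raise ValidationError(f"duplicate pathway name {name!r}")
            if not members:
                raise ValidationError(f"pathway {name!r} has an empty member list")
            pathways[name] = set(members)
            descriptions[name] = desc
    return PathwayDB(pathways, descriptions)


def write_pathway_db(db: PathwayDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in db.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def load_config(path=None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML/JSON; keyword overrides win over the file."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "ae_dims" in data:
        data["ae_dims"] = tuple(data["ae_dims"])
    return RunConfig(**data)
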