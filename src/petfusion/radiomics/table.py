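"""Cohort-level radiomics feature tables with training-cohort z-scoring."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volume import AtlasLabels
from .features import FAMILIES, compute_features, feature_column_names

__all__ = ["RadiomicsFeatureTable", "extract_table", "normalize_table"]


@dataclass
class RadiomicsFeatureTable:
    """Subjects x named-features matrix with extraction provenance.

    ``normalization`` holds the reference-cohort mean/sd per column once
    :func:`normalize_table` has been applied, together with the id of the
    (single) reference cohort the stats came from.
    """

    data: pd.DataFrame
    bin_width: float
    families: tuple[str, ...]
    atlas_hash: str = ""
    normalization: pd.DataFrame | None = None
    reference_id: str | None = None
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bin_width={self.bin_width}\n")
            fh.write(f"# families={','.join(self.families)}\n")
            fh.write(f"# atlas_hash={self.atlas_hash}\n")
            self.data.to_csv(fh, sep="\t")


def _atlas_hash(atlas: AtlasLabels) -> str:
    h = hashlib.sha256(np.ascontiguousarray(atlas.labels).tobytes())
    h.update(repr(sorted(atlas.registry.items())).encode())
    return h.hexdigest()[:16]


def extract_table(cohort, atlas: AtlasLabels,
                  families: tuple[str, ...] = FAMILIES,
                  bin_width: float = 0.05) -> RadiomicsFeatureTable:
    """One row per subject; regions x enabled-family features per row."""
    region_names = [atlas.registry[label] for label in atlas.label_ids]
    cols = feature_column_names(region_names, families)
    rows = []
    index = []
    masks = {label: atlas.labels == label for label in atlas.label_ids}
    shape_cache: dict[int, dict] = {}
    if "shape" in families and cohort.subjects:
        from .features import shape_features

        spacing = cohort.subjects[0].volume.spacing
        shape_cache = {label: shape_features(m, spacing) for label, m in masks.items()}
    for subject in cohort.subjects:
        if subject.volume.shape != atlas.labels.shape:
            raise ValueError(f"subject {subject.subject_id} grid does not match atlas")
        row: list[float] = []
        for label in atlas.label_ids:
            feats = compute_features(subject.volume, masks[label], families, bin_width,
                                     shape_cache=shape_cache.get(label))
            row.extend(feats.values())
        rows.append(row)
        index.append(subject.subject_id)
    data = pd.DataFrame(rows, index=index, columns=cols)
    return RadiomicsFeatureTable(data=data, bin_width=bin_width, families=tuple(families),
                                 atlas_hash=_atlas_hash(atlas))


def normalize_table(table: RadiomicsFeatureTable,
                    reference: RadiomicsFeatureTable,
                    reference_id: str | None = None) -> RadiomicsFeatureTable:
    """Z-score every column with the reference cohort's mean and sd.

    Columns with zero variance in the reference are flagged and dropped
    (they carry no information and would divide by zero).
    """
    if list(table.data.columns) != list(reference.data.columns):
        raise ValueError("column mismatch between table and reference")
    mu = reference.data.mean(axis=0)
    sd = reference.data.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(sd.index[~keep])
    cols = sd.index[keep]
    z = (table.data[cols] - mu[cols]) / sd[cols]
    stats = pd.DataFrame({"mean": mu[cols], "sd": sd[cols]})
    return RadiomicsFeatureTable(
        data=z, bin_width=table.bin_width, families=table.families,
        atlas_hash=table.atlas_hash, normalization=stats,
        reference_id=reference_id or "reference", dropped_columns=dropped,
    )
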