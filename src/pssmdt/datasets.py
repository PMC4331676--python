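"""Labeled feature datasets and their on-disk table + schema-sidecar format.

An encoded dataset is written as a dense TSV (one row per sequence: id,
label, then one column per descriptor) accompanied by a JSON-lines sidecar
mapping every column index to its descriptor (aa1, aa2, lg), so external
tools can interpret coordinates. The sidecar's first line is a header record
with the scheme name and maximum lag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import DescriptorSchema, SchemaError


@dataclass
class LabeledDataset:
    """Feature matrix with sequence ids, ±1 labels and a descriptor schema."""

    ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    schema: DescriptorSchema

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.ids)
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise SchemaError(
                f"inconsistent dataset sizes: {n} ids, {self.features.shape[0]} "
                f"feature rows, {self.labels.shape[0]} labels"
            )
        if self.features.shape[1] != len(self.schema):
            raise SchemaError(
                f"{self.features.shape[1]} feature columns for a schema of "
                f"length {len(self.schema)}"
            )
        if not np.all(np.isfinite(self.features)):
            raise SchemaError("dataset contains non-finite feature values")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise SchemaError("labels must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            ids=[self.ids[i] for i in indices],
            features=self.features[indices],
            labels=self.labels[indices],
            schema=self.schema,
        )


def write_dataset_table(dataset: LabeledDataset, table_path, sidecar_path) -> None:
    df = pd.DataFrame(dataset.features, columns=[f"f{i}" for i in range(dataset.features.shape[1])])
    df.insert(0, "label", dataset.labels)
    df.insert(0, "id", dataset.ids)
    df.to_csv(table_path, sep="\t", index=False)
    with open(sidecar_path, "w") as fh:
        header = {"scheme": dataset.schema.scheme, "lg": dataset.schema.lg}
        fh.write(json.dumps(header) + "\n")
        for rec in dataset.schema.to_records():
            fh.write(json.dumps(rec) + "\n")


def read_dataset_table(table_path, sidecar_path) -> LabeledDataset:
    df = pd.read_csv(table_path, sep="\t")
    with open(sidecar_path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    header, records = lines[0], lines[1:]
    entries = tuple((r["aa1"], r["aa2"], r["lg"]) for r in records)
    schema = DescriptorSchema(scheme=header["scheme"], entries=entries, lg=header.get("lg", 0))
    return LabeledDataset(
        ids=df["id"].astype(str).tolist(),
        features=df.drop(columns=["id", "label"]).to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        schema=schema,
    )
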