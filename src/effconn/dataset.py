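"""Example/Dataset containers and their HDF5 serialization.

An :class:`Example` pairs one M-channel timeseries with the causal
configuration that generated it.  A :class:`Dataset` is an ordered
collection of examples plus generator metadata, written to an HDF5
container with one group per example and a JSON metadata block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from effconn.graphs import CausalConfiguration, DagCatalog, enumerate_dags

__all__ = ["Timeseries", "Example", "Dataset", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Timeseries:
    """M-channel real-valued timeseries sampled at a fixed interval (ms)."""

    values: np.ndarray  # (M_channels, N_timepoints)
    sampling_interval: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"timeseries must be 2-D, got shape {values.shape}")
        if len(self.channel_names) != values.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if not np.isfinite(values).all():
            raise ValueError("timeseries contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Example:
    """One (timeseries, causal configuration) pair with provenance."""

    timeseries: Timeseries
    config: CausalConfiguration
    generator_metadata: dict = field(default_factory=dict)
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.timeseries.n_channels != self.config.M:
            raise ValueError(
                f"timeseries has {self.timeseries.n_channels} channels but "
                f"configuration has M={self.config.M}"
            )


class Dataset:
    """Ordered collection of examples from one generator run."""

    def __init__(
        self,
        examples: Iterable[Example],
        generator: str,
        catalog: DagCatalog,
        metadata: dict | None = None,
    ):
        self.examples: list[Example] = list(examples)
        self.generator = generator
        self.catalog = catalog
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self) -> Iterator[Example]:
        return iter(self.examples)

    def __getitem__(self, k: int) -> Example:
        return self.examples[k]

    @property
    def labels(self) -> np.ndarray:
        return np.array([ex.config.class_index for ex in self.examples], dtype=np.int64)

    def feature_matrix(self) -> np.ndarray:
        """Stack per-example feature vectors; raises if any are missing."""
        rows = []
        for k, ex in enumerate(self.examples):
            if ex.features is None:
                raise ValueError(f"example {k} has no features; run featurization first")
            rows.append(ex.features)
        return np.vstack(rows)

    def with_features(self, features: np.ndarray, lag: int) -> "Dataset":
        """Copy of the dataset with one feature row attached per example."""
        if features.shape[0] != len(self):
            raise ValueError("feature row count must match example count")
        examples = [
            Example(ex.timeseries, ex.config, ex.generator_metadata, np.asarray(features[k]))
            for k, ex in enumerate(self.examples)
        ]
        meta = dict(self.metadata)
        meta["feature_lag"] = int(lag)
        return Dataset(examples, self.generator, self.catalog, meta)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["generator"] = self.generator
            f.attrs["n_examples"] = len(self)
            f.attrs["catalog_json"] = self.catalog.to_json()
            f.attrs["metadata_json"] = json.dumps(self.metadata, default=str)
            grp = f.create_group("examples")
            for k, ex in enumerate(self.examples):
                g = grp.create_group(str(k))
                g.create_dataset("timeseries", data=ex.timeseries.values, dtype=np.float32)
                g.attrs["label"] = ex.config.class_index
                g.attrs["sampling_interval"] = ex.timeseries.sampling_interval
                g.attrs["channel_names"] = json.dumps(list(ex.timeseries.channel_names))
                g.attrs["generator_metadata"] = json.dumps(ex.generator_metadata, default=str)
                if ex.features is not None:
                    g.create_dataset("features", data=ex.features, dtype=np.float64)
            f.attrs["complete"] = True

    @classmethod
    def load(cls, path: str | Path) -> "Dataset":
        import h5py

        path = Path(path)
        with h5py.File(path, "r") as f:
            version = int(f.attrs["schema_version"])
            if version > SCHEMA_VERSION:
                raise ValueError(
                    f"container schema version {version} is newer than supported "
                    f"{SCHEMA_VERSION}; upgrade the package to read it"
                )
            if not f.attrs.get("complete", False):
                raise IOError(f"container {path} is incomplete (partial write detected)")
            catalog = DagCatalog.from_json(f.attrs["catalog_json"])
            metadata = json.loads(f.attrs["metadata_json"])
            examples = []
            for k in range(int(f.attrs["n_examples"])):
                g = f["examples"][str(k)]
                ts = Timeseries(
                    values=g["timeseries"][()].astype(np.float64),
                    sampling_interval=float(g.attrs["sampling_interval"]),
                    channel_names=tuple(json.loads(g.attrs["channel_names"])),
                )
                config = catalog[int(g.attrs["label"])]
                features = g["features"][()] if "features" in g else None
                examples.append(
                    Example(ts, config, json.loads(g.attrs["generator_metadata"]), features)
                )
            return cls(examples, str(f.attrs["generator"]), catalog, metadata)


def default_catalog(M: int = 3) -> DagCatalog:
    return enumerate_dags(M)
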