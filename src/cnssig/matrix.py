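"""Probe-by-sample expression containers and TSV round-tripping.

The central container is :class:`ExpressionMatrix`: a probes x samples
pandas DataFrame plus a scale tag (``linear`` or ``log2``) and optional
per-sample class labels and brain-compartment annotations. Both the
microarray discovery stage and the count-based detection stage use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

LINEAR = "linear"
LOG2 = "log2"

SUPRATENTORIAL = "supratentorial"
INFRATENTORIAL = "infratentorial"
COMPARTMENTS = (SUPRATENTORIAL, INFRATENTORIAL)


@dataclass
class ExpressionMatrix:
    """Numeric probe x sample matrix with sample annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are probes, columns are samples.
    scale : str
        ``"linear"`` for raw intensities/counts, ``"log2"`` for log-scale.
    labels : pandas.Series, optional
        Class label per sample (index = sample ids).
    compartment : pandas.Series, optional
        ``"supratentorial"`` / ``"infratentorial"`` per sample.
    """

    values: pd.DataFrame
    scale: str = LINEAR
    labels: pd.Series | None = None
    compartment: pd.Series | None = None

    def __post_init__(self):
        if self.scale not in (LINEAR, LOG2):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        for name, ann in (("labels", self.labels), ("compartment", self.compartment)):
            if ann is not None and not ann.index.equals(self.values.columns):
                raise ConfigurationError(
                    f"{name} index does not match the sample columns"
                )

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Restrict to the given samples (order follows ``sample_ids``)."""
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids],
            scale=self.scale,
            labels=None if self.labels is None else self.labels[sample_ids],
            compartment=None
            if self.compartment is None
            else self.compartment[sample_ids],
        )

    def split_by_compartment(self) -> dict[str, "ExpressionMatrix"]:
        """Partition samples by brain compartment.

        Supra- and infratentorial tumors differ in type composition, so all
        downstream normalization and clustering runs per compartment. This is
        a labeled split, not two code paths.
        """
        if self.compartment is None:
            raise ConfigurationError("matrix carries no compartment annotation")
        out = {}
        for comp in self.compartment.unique():
            ids = self.compartment.index[self.compartment == comp]
            out[comp] = self.subset_samples(ids)
        return out

    def to_tsv(self, path) -> None:
        """Write the value matrix as TSV (probes as rows, sample-id header)."""
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path, scale: str = LINEAR, labels: pd.Series | None = None):
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, scale=scale, labels=labels)


@dataclass
class SampleSheet:
    """Per-sample annotations (class label, compartment) as a tidy table."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "class")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ConfigurationError(f"sample sheet misses column {col!r}")

    def labels(self) -> pd.Series:
        return self.table.set_index("sample_id")["class"]

    def compartments(self) -> pd.Series | None:
        if "compartment" not in self.table.columns:
            return None
        return self.table.set_index("sample_id")["compartment"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def attach_labels(matrix: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Return a copy of ``matrix`` annotated from a sample sheet."""
    labels = sheet.labels().reindex(matrix.samples)
    comp = sheet.compartments()
    if comp is not None:
        comp = comp.reindex(matrix.samples)
    return ExpressionMatrix(
        values=matrix.values, scale=matrix.scale, labels=labels, compartment=comp
    )
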