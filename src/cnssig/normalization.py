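"""Technical and biological normalization of probe counts, plus QC.

Raw lane counts are rescaled in two geometric-mean steps, the documented
default scheme of the vendor's analysis software:

1. *Technical* normalization: each lane is scaled by
   (cohort mean of positive-control geometric means) / (lane's
   positive-control geometric mean), removing hybridization/scanning
   efficiency differences (including FFPE degradation effects on lane
   yield).
2. *Biological* (housekeeping) normalization: same construction with the
   geometric mean of the housekeeping genes (ACTB, GAPDH, LDHA), removing
   RNA-input differences.

Values are then log2-transformed with pseudocount 1. Background
subtraction from negative controls (mean + 2 SD, floored at 0) is
available behind a flag but off by default.

The good-hybridization QC statistic is the *reference fold*: a marker
probe's normalized linear expression in the known-positive reference
sample divided by the mean over all remaining samples; a probe hybridizes
usefully only if this fold exceeds 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .rcc import CodeSet, CountMatrices, RCCSample, assemble_count_matrix


@dataclass
class NormalizedMatrix:
    """Normalized counts on both scales plus per-sample factors and QC flags."""

    values: pd.DataFrame  # log2(scaled + pseudocount), probes x samples
    linear: pd.DataFrame  # scaled counts before log2
    tech_factors: pd.Series
    bio_factors: pd.Series
    qc_flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if (self.tech_factors <= 0).any() or (self.bio_factors <= 0).any():
            raise ConfigurationError("scale factors must be > 0")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ConfigurationError("normalized values must be finite")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def restrict(self, probes: list[str]) -> "NormalizedMatrix":
        present = [p for p in probes if p in self.values.index]
        missing = sorted(set(probes) - set(present))
        if missing:
            raise ConfigurationError(f"probes not measured: {missing}")
        return NormalizedMatrix(
            values=self.values.loc[present],
            linear=self.linear.loc[present],
            tech_factors=self.tech_factors,
            bio_factors=self.bio_factors,
            qc_flags=self.qc_flags,
        )


def _geometric_means(block: pd.DataFrame, skip_zeros: bool = False) -> pd.Series:
    """Column-wise geometric mean; optionally ignore zero entries per column."""
    X = block.to_numpy(dtype=float)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if skip_zeros:
            col = col[col > 0]
        if col.size == 0:
            out[j] = 0.0
        elif (col <= 0).any():
            out[j] = 0.0
        else:
            out[j] = float(np.exp2(np.log2(col).mean()))
    return pd.Series(out, index=block.columns)


def _scaling_step(
    counts: pd.DataFrame,
    anchor: pd.DataFrame,
    flag_label: str,
    qc_flags: dict[str, list[str]],
    target: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One geometric-mean scaling pass against ``anchor`` probes.

    By default the target is the arithmetic mean across samples of the
    anchor geometric means; each sample's factor is target / (its anchor
    geomean). Passing a fixed ``target`` makes each lane's factor depend on
    that lane alone, which is what allows lanes from different runs to be
    compared against stored reference lanes and makes the cancellation of
    any per-lane scale factor exact. A sample with a zero anchor count is
    QC-flagged: its geometric mean is taken over its remaining positive
    anchor probes, and if none remain the factor falls back to 1.
    """
    if anchor.shape[0] == 0:
        raise ConfigurationError("no anchor probes available for normalization")
    has_zero = (anchor.to_numpy() <= 0).any(axis=0)
    geo = _geometric_means(anchor, skip_zeros=True)
    factors = pd.Series(1.0, index=counts.columns)
    usable = geo > 0
    if usable.any():
        if target is None:
            target = float(geo[usable].mean())
        factors[usable] = target / geo[usable]
    for j, sample in enumerate(counts.columns):
        if has_zero[j]:
            qc_flags.setdefault(sample, []).append(flag_label)
            if not usable.iloc[j]:
                warnings.warn(
                    f"sample {sample!r}: all {flag_label} probes are zero; "
                    "factor of 1 applied",
                    stacklevel=3,
                )
    return counts.mul(factors, axis=1), factors


def technical_normalize(
    raw: pd.DataFrame,
    positive_controls: pd.DataFrame,
    qc_flags: dict[str, list[str]] | None = None,
    target: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale lanes so positive-control geometric means match the target.

    Default target: the cohort mean of the per-lane positive-control
    geometric means.
    """
    qc_flags = qc_flags if qc_flags is not None else {}
    return _scaling_step(
        raw, positive_controls, "zero-positive-control", qc_flags, target
    )


def housekeeping_normalize(
    scaled: pd.DataFrame,
    housekeeping: pd.DataFrame,
    qc_flags: dict[str, list[str]] | None = None,
    target: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale lanes so housekeeping geometric means match the target.

    Default target: the cohort mean of the per-lane housekeeping geometric
    means (computed on technically normalized counts).
    """
    qc_flags = qc_flags if qc_flags is not None else {}
    return _scaling_step(scaled, housekeeping, "zero-housekeeping", qc_flags, target)


def log2_counts(scaled: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count + pseudocount); count 0 maps to 0 at the default pseudocount."""
    if (scaled.to_numpy() < 0).any():
        raise ConfigurationError("counts must be >= 0")
    return np.log2(scaled + pseudocount)


def background_subtract(
    counts: pd.DataFrame, negative_controls: pd.DataFrame
) -> pd.DataFrame:
    """Subtract per-sample background (negative-control mean + 2 SD), floor 0."""
    neg = negative_controls.to_numpy(dtype=float)
    threshold = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    return (counts - threshold).clip(lower=0.0)


def normalize_counts(
    matrices: CountMatrices,
    pseudocount: float = 1.0,
    subtract_background: bool = False,
    tech_target: float | None = None,
    bio_target: float | None = None,
) -> NormalizedMatrix:
    """Full normalization of an assembled cohort.

    Technical scaling (positive controls), then housekeeping scaling, then
    log2 with pseudocount. Housekeeping factors are computed on the
    technically normalized housekeeping counts. Endogenous and housekeeping
    probes are carried through; control probes are used for factors only.
    """
    endo = matrices.endogenous.astype(float)
    hk = matrices.housekeeping.astype(float)
    if subtract_background:
        endo = background_subtract(endo, matrices.negative)
        hk = background_subtract(hk, matrices.negative)
    qc_flags: dict[str, list[str]] = {}
    stacked = pd.concat([endo, hk])
    tech_scaled, tech = technical_normalize(
        stacked, matrices.positive.astype(float), qc_flags, target=tech_target
    )
    hk_scaled = tech_scaled.loc[hk.index]
    bio_scaled, bio = housekeeping_normalize(
        tech_scaled, hk_scaled, qc_flags, target=bio_target
    )
    linear = bio_scaled.loc[endo.index.append(hk.index)]
    return NormalizedMatrix(
        values=log2_counts(linear, pseudocount),
        linear=linear,
        tech_factors=tech,
        bio_factors=bio,
        qc_flags=qc_flags,
    )


def normalize_cohort(
    samples: list[RCCSample],
    codeset: CodeSet,
    pseudocount: float = 1.0,
    subtract_background: bool = False,
    tech_target: float | None = None,
    bio_target: float | None = None,
) -> NormalizedMatrix:
    """Assemble RCC lanes and normalize them in one call."""
    return normalize_counts(
        assemble_count_matrix(samples, codeset),
        pseudocount=pseudocount,
        subtract_background=subtract_background,
        tech_target=tech_target,
        bio_target=bio_target,
    )


@dataclass
class HybridizationQC:
    probe: str
    reference_sample: str
    fold: float | None  # None when indeterminate (zero mean of the rest)
    passed: bool

    @property
    def indeterminate(self) -> bool:
        return self.fold is None


def good_hybridization_fold(
    matrix: NormalizedMatrix, probe: str, reference_sample: str
) -> HybridizationQC:
    """Reference fold of a probe: reference sample over mean of the rest.

    Computed on post-normalization *linear* counts. Pass requires fold > 1;
    a zero mean of the remaining samples makes the QC indeterminate (not a
    pass).
    """
    if matrix.linear.shape[1] < 2:
        raise ConfigurationError("reference-fold QC needs >= 2 samples")
    if probe not in matrix.linear.index:
        raise ConfigurationError(f"probe {probe!r} not measured")
    if reference_sample not in matrix.linear.columns:
        raise ConfigurationError(f"reference sample {reference_sample!r} not present")
    row = matrix.linear.loc[probe]
    ref_value = float(row[reference_sample])
    rest = row.drop(reference_sample)
    rest_mean = float(rest.mean())
    if rest_mean == 0.0:
        return HybridizationQC(probe, reference_sample, None, passed=False)
    fold = ref_value / rest_mean
    return HybridizationQC(probe, reference_sample, fold, passed=fold > 1.0)


def hybridization_report(
    matrix: NormalizedMatrix, codeset: CodeSet, references: dict[str, str],
    compartment: str,
) -> pd.DataFrame:
    """Reference-fold QC for every marker probe of every referenced entity."""
    rows = []
    for entity, ref in references.items():
        for probe in codeset.markers_for(entity, compartment):
            qc = good_hybridization_fold(matrix, probe, ref)
            rows.append(
                {
                    "entity": entity,
                    "probe": probe,
                    "reference_sample": ref,
                    "fold": np.nan if qc.fold is None else qc.fold,
                    "passed": qc.passed,
                }
            )
    return pd.DataFrame(rows)
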