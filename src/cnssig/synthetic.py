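"""Synthetic cohorts with planted entity signatures.

Two generators provide ground truth for every downstream stage:

* :func:`generate_discovery_dataset` emulates probe-set-level microarray
  intensity matrices (log-normal intensities; selected marker probes
  up-regulated by a configured log2 effect in their class), standing in for
  the public expression series used for in-silico marker discovery.
* :func:`generate_nanostring_cohort` emulates an nCounter run on an FFPE
  tumor series: negative-binomial probe counts with stable housekeeping
  genes, a positive-control spike-in ladder, low negative controls, a
  per-lane efficiency factor (degradation/hybridization) and a per-lane
  RNA-content factor. Planted entity samples have their marker probes
  elevated so that the *expected reference fold* — reference-sample
  expression over the mean of all remaining samples, the hybridization QC
  statistic — lands inside the configured range (default 3.9x to 92.7x).

Both generators are deterministic given their config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import (
    COMPARTMENTS,
    INFRATENTORIAL,
    LINEAR,
    SUPRATENTORIAL,
    ExpressionMatrix,
)
from .rcc import CodeSet, RCCRecord, RCCSample

# ---------------------------------------------------------------------------
# Discovery stage (microarray-like intensities)
# ---------------------------------------------------------------------------


def probe_ids(n_probes: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n_probes)]


@dataclass
class DiscoveryConfig:
    """Configuration for a planted-marker intensity matrix.

    ``planted_markers`` maps class name -> list of (probe_id, log2_effect).
    A planted probe's expected log2 intensity in its class exceeds its own
    baseline by the effect. Each probe has a class-independent baseline
    mean drawn once from Normal(baseline_mean_log2, probe_spread_sd_log2) —
    probe-level means on real arrays span many log2 units, and that spread
    is what lets quantile normalization preserve per-probe effects — and
    per-sample noise Normal(0, baseline_sd_log2).
    """

    classes: dict[str, int]
    n_probes: int
    planted_markers: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 0.6
    probe_spread_sd_log2: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise ConfigurationError("classes must be nonempty")
        for cls, n in self.classes.items():
            if n < 2:
                raise ConfigurationError(
                    f"class {cls!r} has {n} samples; t-tests need >= 2 per side"
                )
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        if self.baseline_sd_log2 <= 0:
            raise ConfigurationError("baseline_sd_log2 must be > 0")
        if self.probe_spread_sd_log2 < 0:
            raise ConfigurationError("probe_spread_sd_log2 must be >= 0")
        valid = set(probe_ids(self.n_probes))
        seen: dict[str, str] = {}
        for cls, markers in self.planted_markers.items():
            if cls not in self.classes:
                raise ConfigurationError(f"planted class {cls!r} not in classes")
            for probe, effect in markers:
                if probe not in valid:
                    raise ConfigurationError(f"planted probe {probe!r} not in matrix")
                if probe in seen:
                    raise ConfigurationError(
                        f"probe {probe!r} planted in both {seen[probe]!r} and {cls!r}"
                    )
                seen[probe] = cls
                if not math.isfinite(effect) or effect < 0:
                    raise ConfigurationError(
                        f"log2 effect for {probe!r} must be finite and >= 0"
                    )


def generate_discovery_dataset(config: DiscoveryConfig) -> ExpressionMatrix:
    """Draw a linear-scale intensity matrix with planted class markers.

    Returns an :class:`ExpressionMatrix` (probes x samples, linear scale)
    whose ``labels`` attribute carries the per-sample class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probes = probe_ids(config.n_probes)
    sample_ids: list[str] = []
    labels: list[str] = []
    for cls in config.classes:  # insertion order: deterministic
        for i in range(config.classes[cls]):
            sample_ids.append(f"{cls}_{i:03d}")
            labels.append(cls)
    n = len(sample_ids)

    probe_means = rng.normal(
        config.baseline_mean_log2, config.probe_spread_sd_log2, size=config.n_probes
    )
    log2 = probe_means[:, None] + rng.normal(
        0.0, config.baseline_sd_log2, size=(config.n_probes, n)
    )
    probe_index = {p: i for i, p in enumerate(probes)}
    labels_arr = np.asarray(labels)
    for cls, markers in config.planted_markers.items():
        cols = np.flatnonzero(labels_arr == cls)
        for probe, effect in markers:
            log2[probe_index[probe], cols] += effect

    values = pd.DataFrame(
        np.exp2(log2), index=pd.Index(probes, name="probe_id"), columns=sample_ids
    )
    return ExpressionMatrix(
        values=values,
        scale=LINEAR,
        labels=pd.Series(labels, index=values.columns, name="class"),
    )


# ---------------------------------------------------------------------------
# Detection stage (nCounter-like counts)
# ---------------------------------------------------------------------------

# Spike-in positive-control ladder: geometric, factor 4 between steps.
POSITIVE_LADDER = (8192.0, 2048.0, 512.0, 128.0, 32.0, 8.0)
NEGATIVE_MEAN = 2.0


@dataclass
class CohortConfig:
    """Configuration for one compartment's synthetic nCounter cohort.

    ``background_diagnoses`` maps ordinary high-grade tumor diagnoses to
    sample counts; ``planted_entities`` maps the four new entities to their
    planted sample counts. The total cohort size is the sum of both. One
    planted sample per entity is tagged as that entity's reference sample
    (a tumor with a prior methylation diagnosis); references are drawn from
    the same distribution as the other planted samples.

    ``marker_fold_range`` bounds the expected reference fold of each planted
    marker probe. Diagnoses listed in ``glioma_high_diagnoses`` express the
    glioma panel (GFAP/OLIG2/PMP2); ``dual_glioma_entities`` marks how many
    planted samples of an entity additionally express the glioma panel.
    ``background_probe_folds`` elevates single probes in background
    diagnoses (e.g. EMX1/PRDM6 in posterior fossa ependymomas).
    """

    compartment: str
    background_diagnoses: dict[str, int]
    planted_entities: dict[str, int]
    reference_samples: dict[str, str] | None = None
    marker_fold_range: tuple[float, float] = (3.9, 92.7)
    nb_dispersion: float = 0.005
    hk_mean_counts: float = 1200.0
    baseline_marker_counts: float = 40.0
    lane_efficiency_sd: float = 0.15
    rna_content_sd: float = 0.25
    glioma_high_diagnoses: tuple[str, ...] = ("HGG", "GBM")
    glioma_fold_range: tuple[float, float] = (4.0, 16.0)
    dual_glioma_entities: dict[str, int] = field(default_factory=dict)
    background_probe_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.background_diagnoses.values()) + sum(
            self.planted_entities.values()
        )

    def validate(self, codeset: CodeSet | None = None) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        low, high = self.marker_fold_range
        if low < 1 or low > high:
            raise ConfigurationError(
                "marker_fold_range must satisfy 1 <= low <= high"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        for name, n in {**self.background_diagnoses, **self.planted_entities}.items():
            if n < 0:
                raise ConfigurationError(f"negative sample count for {name!r}")
        for entity, k in self.dual_glioma_entities.items():
            if k > self.planted_entities.get(entity, 0):
                raise ConfigurationError(
                    f"dual_glioma_entities[{entity!r}] exceeds planted count"
                )
        if codeset is not None:
            for entity, n in self.planted_entities.items():
                if n >= 1 and not codeset.markers_for(entity, self.compartment):
                    raise ConfigurationError(
                        f"entity {entity!r} has no marker probes in the "
                        f"{self.compartment} CodeSet"
                    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draw parameterized by mean and dispersion.

    var = mu + dispersion * mu^2, i.e. NB(r, p) with r = 1/dispersion and
    p = r / (r + mu).
    """
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def _elevation_for_target_fold(fold: float, n_entity: int, n_total: int) -> float:
    """Per-probe mean multiplier giving an expected reference fold of ``fold``.

    With ``n_entity`` planted samples sharing the multiplier m (baseline 1)
    in a cohort of ``n_total``, the expected reference fold is
    F = m (N-1) / ((n_e - 1) m + N - n_e); invert for m. The fold saturates
    at (N-1)/(n_e-1) as m grows, so callers must pass an attainable F.
    """
    num = fold * (n_total - n_entity)
    den = (n_total - 1) - fold * (n_entity - 1)
    if den <= 0:
        raise ConfigurationError(
            f"reference fold {fold} not attainable with {n_entity} planted "
            f"samples in a cohort of {n_total}"
        )
    return num / den


def attainable_fold_range(
    fold_range: tuple[float, float], n_entity: int, n_total: int
) -> tuple[float, float]:
    """Clip a target reference-fold range to what the cohort can express.

    When several samples share a signature, the mean of the "remaining"
    samples includes the other planted samples, so the reference fold
    saturates below (N-1)/(n_e-1); the upper bound is clipped to 95% of
    that ceiling.
    """
    low, high = fold_range
    if n_entity <= 1:
        return low, high
    cap = 0.95 * (n_total - 1) / (n_entity - 1)
    if cap <= low:
        raise ConfigurationError(
            f"fold range {fold_range} unattainable: {n_entity} planted samples "
            f"in {n_total} saturate the reference fold at {cap:.2f}"
        )
    return low, min(high, cap)


def generate_nanostring_cohort(
    config: CohortConfig, codeset: CodeSet
) -> tuple[list[RCCSample], pd.DataFrame]:
    """Simulate one compartment's lanes plus a ground-truth table.

    Returns ``(samples, truth)`` where ``truth`` has one row per sample:
    ``sample_id``, ``diagnosis`` (original histology label), ``entity``
    (planted entity or empty), ``is_reference``, ``glioma_high``.
    """
    config.validate(codeset)
    rng = np.random.default_rng(config.seed)
    n_total = config.n_samples
    prefix = "ST" if config.compartment == SUPRATENTORIAL else "IT"

    # Build the sample roster, then shuffle so entity samples are not
    # positionally clustered in lane order.
    diagnosis: list[str] = []
    entity: list[str] = []
    for diag in config.background_diagnoses:
        diagnosis += [diag] * config.background_diagnoses[diag]
        entity += [""] * config.background_diagnoses[diag]
    for ent in config.planted_entities:
        diagnosis += [ent] * config.planted_entities[ent]
        entity += [ent] * config.planted_entities[ent]
    order = rng.permutation(n_total)
    diagnosis = [diagnosis[i] for i in order]
    entity = [entity[i] for i in order]
    sample_ids = [f"{prefix}{i + 1:03d}" for i in range(n_total)]

    # Reference tagging: the first planted sample (in lane order) per entity,
    # unless explicit ids were configured.
    is_reference = [False] * n_total
    ref_ids: dict[str, str] = {}
    for ent, n in config.planted_entities.items():
        if n < 1:
            continue
        if config.reference_samples and ent in config.reference_samples:
            sid = config.reference_samples[ent]
            if sid not in sample_ids or entity[sample_ids.index(sid)] != ent:
                raise ConfigurationError(
                    f"configured reference {sid!r} is not a planted {ent!r} sample"
                )
            idx = sample_ids.index(sid)
        else:
            idx = next(i for i in range(n_total) if entity[i] == ent)
        is_reference[idx] = True
        ref_ids[ent] = sample_ids[idx]

    # Dual glioma-expressing entity samples (first k in lane order, skipping
    # none; references may be dual).
    dual = [False] * n_total
    for ent, k in config.dual_glioma_entities.items():
        picked = 0
        for i in range(n_total):
            if entity[i] == ent and picked < k:
                dual[i] = True
                picked += 1

    glioma_high = [
        diagnosis[i] in config.glioma_high_diagnoses or dual[i] for i in range(n_total)
    ]

    # Per-probe mean multipliers (probes x samples), baseline 1.
    endo = codeset.endogenous_probes()
    probe_idx = {p: i for i, p in enumerate(endo)}
    elev = np.ones((len(endo), n_total))
    ent_arr = np.asarray(entity)
    for ent, n_e in config.planted_entities.items():
        if n_e < 1:
            continue
        cols = np.flatnonzero(ent_arr == ent)
        lo, hi = attainable_fold_range(config.marker_fold_range, n_e, n_total)
        for probe in codeset.marker_union(ent):
            target_fold = rng.uniform(lo, hi)
            m = _elevation_for_target_fold(target_fold, n_e, n_total)
            elev[probe_idx[probe], cols] *= m
    g_lo, g_hi = config.glioma_fold_range
    glioma_cols = np.flatnonzero(np.asarray(glioma_high))
    for probe in codeset.glioma_panel:
        gfold = rng.uniform(g_lo, g_hi)
        elev[probe_idx[probe], glioma_cols] *= gfold
    for diag, probe_folds in config.background_probe_folds.items():
        cols = np.flatnonzero(np.asarray(diagnosis) == diag)
        for probe, fold in probe_folds.items():
            if probe in probe_idx:
                elev[probe_idx[probe], cols] *= fold

    # Per-lane factors: hybridization/degradation efficiency acts on every
    # probe (controls included); RNA content acts on endogenous and
    # housekeeping probes only.
    efficiency = np.exp(rng.normal(0.0, config.lane_efficiency_sd, n_total))
    content = np.exp(rng.normal(0.0, config.rna_content_sd, n_total))

    endo_mean = config.baseline_marker_counts * elev * (efficiency * content)
    hk_mean = np.tile(config.hk_mean_counts * efficiency * content,
                      (len(codeset.housekeeping), 1))
    pos_mean = np.outer(POSITIVE_LADDER[: len(codeset.positive_controls)], efficiency)
    neg_mean = np.tile(NEGATIVE_MEAN * efficiency,
                       (len(codeset.negative_controls), 1))

    disp = config.nb_dispersion
    endo_counts = _nb_counts(rng, endo_mean, disp)
    hk_counts = _nb_counts(rng, hk_mean, disp)
    pos_counts = _nb_counts(rng, pos_mean, disp)
    neg_counts = _nb_counts(rng, neg_mean, disp)

    samples: list[RCCSample] = []
    for j, sid in enumerate(sample_ids):
        records = []
        for block, probes in (
            (endo_counts, endo),
            (hk_counts, codeset.housekeeping),
            (pos_counts, codeset.positive_controls),
            (neg_counts, codeset.negative_controls),
        ):
            for i, probe in enumerate(probes):
                records.append(
                    RCCRecord(
                        code_class=codeset.code_class_of(probe),
                        name=probe,
                        accession=f"SYN_{probe}",
                        count=int(block[i, j]),
                    )
                )
        samples.append(
            RCCSample(
                sample_id=sid,
                sample_attributes={
                    "ID": sid,
                    "GeneRLF": codeset.name,
                    "Comments": config.compartment,
                },
                lane_attributes={
                    "ID": str(j % 12 + 1),
                    "FovCount": "555",
                    "FovCounted": "550",
                    "ScannerID": "synthetic",
                    "StagePosition": str(j % 12 + 1),
                    "BindingDensity": "0.55",
                    "CartridgeID": f"SYNTH{j // 12 + 1:02d}",
                },
                records=records,
            )
        )

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diagnosis": diagnosis,
            "entity": entity,
            "is_reference": is_reference,
            "glioma_high": glioma_high,
            "compartment": config.compartment,
        }
    )
    return samples, truth


def reference_map(truth: pd.DataFrame) -> dict[str, str]:
    """Entity -> reference sample id, extracted from a ground-truth table."""
    refs = truth[truth["is_reference"]]
    return dict(zip(refs["entity"], refs["sample_id"]))


# ---------------------------------------------------------------------------
# Default study-condition configurations
# ---------------------------------------------------------------------------


def default_supratentorial_config(seed: int = 0) -> CohortConfig:
    """92 supratentorial tumors: 80 background + 12 planted entity samples.

    Background composition mirrors the supratentorial series (HGGs, PNETs,
    ependymomas, choroid plexus carcinomas, ATRTs, ETMRs, NOS embryonal
    tumors) with the planted entities subtracted from the diagnoses they
    originally carried (1 EFT-CIC and 3 NB-FOXR2 from PNETs, 4 HGNET-MN1
    from PNET/EPN/CPC, 4 HGNET-BCOR from HGGs/PNET).
    """
    return CohortConfig(
        compartment=SUPRATENTORIAL,
        background_diagnoses={
            "HGG": 25,
            "PNET": 17,
            "EPN": 18,
            "CPC": 9,
            "ATRT": 7,
            "ETMR": 2,
            "NOS": 2,
        },
        planted_entities={
            "EFT-CIC": 1,
            "NB-FOXR2": 3,
            "HGNET-MN1": 4,
            "HGNET-BCOR": 4,
        },
        seed=seed,
    )


def default_infratentorial_config(seed: int = 0) -> CohortConfig:
    """95 infratentorial tumors: 93 background + 2 planted HGNET-BCOR.

    Background mirrors the posterior fossa series (ependymomas,
    medulloblastomas, CPCs, ATRTs). EMX1 and PRDM6 are moderately elevated
    in ependymomas/medulloblastomas — the reason those probes are excluded
    from the infratentorial HGNET-BCOR panel.
    """
    return CohortConfig(
        compartment=INFRATENTORIAL,
        background_diagnoses={"EPN": 50, "MB": 36, "CPC": 4, "ATRT": 3},
        planted_entities={"HGNET-BCOR": 2},
        background_probe_folds={
            "EPN": {"EMX1": 5.0, "PRDM6": 4.0},
            "MB": {"EMX1": 3.0, "PRDM6": 5.0},
        },
        seed=seed,
    )


def default_hgg_contrast_config(seed: int = 0) -> CohortConfig:
    """28-sample glioma-contrast cohort for the HGNET-BCOR re-analysis.

    21 glioma-panel-expressing HGGs, one non-glioma outlier (embryonal
    histology, expresses neither panel) and 6 planted HGNET-BCOR samples of
    which 2 additionally express the glioma panel (the dual-signature pair).
    """
    return CohortConfig(
        compartment=SUPRATENTORIAL,
        background_diagnoses={"HGG": 21, "PNET": 1},
        planted_entities={"HGNET-BCOR": 6},
        dual_glioma_entities={"HGNET-BCOR": 2},
        seed=seed,
    )
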