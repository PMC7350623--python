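"""One-vs-rest ROC/AUC evaluation of individual marker probes.

Each entity's samples are the positives and all other samples the
negatives; the classifier score is the probe's log2 normalized expression.
The ROC curve is a threshold sweep over the observed scores and the AUC is
the trapezoidal area, which with midranked ties equals the Mann-Whitney
U statistic divided by n_pos * n_neg (the probability that a random
positive outscores a random negative, ties counting one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigurationError
from .normalization import NormalizedMatrix
from .rcc import CodeSet


@dataclass
class ROCResult:
    probe_id: str
    target_entity: str
    points: np.ndarray  # (n, 2) columns FPR, TPR; includes (0,0) and (1,1)
    auc: float
    n_pos: int
    n_neg: int


def roc_for_probe(
    matrix: NormalizedMatrix,
    probe: str,
    positive_samples: list[str],
    target_entity: str = "",
) -> ROCResult:
    """ROC curve and AUC for one probe against one positive sample set."""
    if probe not in matrix.values.index:
        raise ConfigurationError(f"probe {probe!r} not measured")
    scores = matrix.values.loc[probe]
    labels = scores.index.isin(set(positive_samples)).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError(
            "ROC needs at least one positive and one negative sample"
        )
    y = scores.to_numpy(dtype=float)
    fpr, tpr, _ = roc_curve(labels, y, drop_intermediate=False)
    auc = float(roc_auc_score(labels, y))
    points = np.column_stack([fpr, tpr])
    if not np.allclose(points[0], (0.0, 0.0)):
        points = np.vstack([[0.0, 0.0], points])
    if not np.allclose(points[-1], (1.0, 1.0)):
        points = np.vstack([points, [1.0, 1.0]])
    return ROCResult(
        probe_id=probe,
        target_entity=target_entity,
        points=points,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_table(
    matrix: NormalizedMatrix,
    codeset: CodeSet,
    truth: pd.DataFrame,
    compartment: str,
) -> pd.DataFrame:
    """Per-entity, per-marker-probe AUC report.

    ``truth`` must carry ``sample_id`` and ``entity`` columns covering all
    samples (empty entity = background). Entities with zero positives are
    skipped with a warning — with these rare tumors an entity can easily
    have a single sample or none, and a missing class cannot be evaluated.
    Rows are sorted by entity, then AUC descending.
    """
    truth = truth.set_index("sample_id")
    missing = [s for s in matrix.samples if s not in truth.index]
    if missing:
        raise ConfigurationError(f"ground truth misses samples: {missing}")
    rows = []
    for entity in codeset.entities_in(compartment):
        positives = [
            s for s in matrix.samples if truth.loc[s, "entity"] == entity
        ]
        if not positives:
            warnings.warn(
                f"entity {entity!r} has no positive samples; skipped",
                stacklevel=2,
            )
            continue
        for probe in codeset.markers_for(entity, compartment):
            res = roc_for_probe(matrix, probe, positives, target_entity=entity)
            rows.append(
                {
                    "entity": entity,
                    "probe": probe,
                    "auc": res.auc,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                }
            )
    frame = pd.DataFrame(rows, columns=["entity", "probe", "auc", "n_pos", "n_neg"])
    if len(frame):
        frame = frame.sort_values(
            ["entity", "auc", "probe"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return frame


def panel_mean_roc(
    matrix: NormalizedMatrix,
    codeset: CodeSet,
    entity: str,
    compartment: str,
    positive_samples: list[str],
) -> ROCResult:
    """ROC on the mean expression of an entity's whole marker panel.

    Option for scoring a combined panel rather than individual probes.
    """
    probes = codeset.markers_for(entity, compartment)
    if not probes:
        raise ConfigurationError(f"no {entity!r} panel in {compartment!r}")
    sub = matrix.restrict(probes)
    mean_scores = sub.values.mean(axis=0)
    pseudo = NormalizedMatrix(
        values=mean_scores.to_frame(name=f"{entity}_panel").T,
        linear=(2.0 ** mean_scores).to_frame(name=f"{entity}_panel").T,
        tech_factors=matrix.tech_factors,
        bio_factors=matrix.bio_factors,
    )
    return roc_for_probe(
        pseudo, f"{entity}_panel", positive_samples, target_entity=entity
    )
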