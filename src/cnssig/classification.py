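"""Reference-anchored diagnosis from normalized marker expression.

Samples are clustered (average linkage / UPGMA on Euclidean distances of
their log2 marker-probe vectors, per compartment) and scored per entity.
A sample is called an entity when

* its entity signature z-score reaches the calling threshold tau
  (default 2) and is the unique arg-max over entities,
* its marker-panel expression is genuinely elevated — at least
  ``min_call_fold`` (default 2x) above the cohort median panel level, an
  effect-size guard that keeps pure z-score flukes from becoming calls —
  and
* when the entity has a reference sample (a tumor with a prior methylation
  diagnosis), the sample co-clusters with that reference when the tree is
  cut into (number of referenced entities) + 1 clusters.

Every reference sample must recover its own entity, otherwise the run is
rejected. Entities without a reference in the run are callable by score
alone but flagged lower-confidence.

The glioma-contrast re-analysis (HGNET-BCOR panel vs GFAP/OLIG2/PMP2)
labels each sample signature / glioma / dual / outlier; here "high" in a
panel is decided by a bimodal split of panel scores rather than a cohort
z-score, because the glioma-expressing group is typically the *majority*
of such a cohort and cohort standardization cannot flag a majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ClassificationIntegrityError, ConfigurationError
from .normalization import NormalizedMatrix
from .rcc import CodeSet


@dataclass
class Dendrogram:
    """Average-linkage tree over samples.

    ``merges`` holds (node_a, node_b, height, size) rows in scipy linkage
    convention: leaves are 0..n-1 (indexing ``leaf_ids``), internal node i
    is n + (merge row index).
    """

    merges: np.ndarray  # (n-1, 4) linkage matrix
    leaf_ids: list[str]
    metric: str = "euclidean"
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.leaf_ids[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Cluster membership (1..k) when the tree is cut into k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ConfigurationError(f"cannot cut {self.n_leaves} leaves into {k}")
        flat = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.leaf_ids, name="cluster")

    def leaf_merge_heights(self) -> pd.Series:
        """Height at which each sample first merges with anything.

        A sample whose first merge happens far above the rest of the cohort
        sits alone in expression space — the outlier signal.
        """
        n = self.n_leaves
        first = np.full(n, np.nan)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for row_idx, (a, b, h, _size) in enumerate(self.merges):
            merged = members.pop(int(a)) + members.pop(int(b))
            for leaf in merged:
                if np.isnan(first[leaf]):
                    first[leaf] = h
            members[n + row_idx] = merged
        return pd.Series(first, index=self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n_leaves
        height_of: dict[int, float] = {i: 0.0 for i in range(n)}
        for row_idx, row in enumerate(self.merges):
            height_of[n + row_idx] = float(row[2])

        def _render(node: int, parent_height: float) -> str:
            length = parent_height - height_of[node]
            if node < n:
                return f"{self.leaf_ids[node]}:{length:.10g}"
            a, b, h, _ = self.merges[node - n]
            inner = f"({_render(int(a), h)},{_render(int(b), h)})"
            return f"{inner}:{length:.10g}"

        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[-1]
        return f"({_render(int(a), h)},{_render(int(b), h)});" if root >= n else ";"


@dataclass
class GroupCall:
    """Per-sample diagnosis with its supporting evidence."""

    sample_id: str
    called_entity: str | None
    signature_scores: dict[str, float]
    co_clusters_with_reference: dict[str, bool] = field(default_factory=dict)
    dual_signature: bool = False
    outlier: bool = False
    flags: list[str] = field(default_factory=list)


def hierarchical_cluster(
    matrix: NormalizedMatrix,
    sample_subset: list[str] | None = None,
) -> Dendrogram:
    """Average-linkage tree on Euclidean distances of sample log2 vectors.

    The caller restricts the matrix to the probes under study (entity
    marker panels plus the glioma panel for the compartment). Tie-breaking
    among equidistant merges follows the deterministic nearest-neighbor
    chain order of the underlying implementation.
    """
    values = matrix.values
    if sample_subset is not None:
        values = values[list(sample_subset)]
    if values.shape[1] < 2:
        raise ConfigurationError("clustering needs >= 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x probes
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    return Dendrogram(merges=Z, leaf_ids=list(values.columns))


def signature_score(matrix: NormalizedMatrix, marker_probes: list[str]) -> pd.Series:
    """Cohort-standardized per-sample signature score for one marker panel.

    The raw score is the mean log2 normalized value over the panel's
    probes; it is z-standardized across the cohort. A zero-variance cohort
    yields all-zero scores.
    """
    if not marker_probes:
        raise ConfigurationError("entity has no marker probes with data")
    sub = matrix.restrict(marker_probes)
    s = sub.values.mean(axis=0)
    sd = s.std(ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=s.index)
    return (s - s.mean()) / sd


def panel_fold_over_cohort(
    matrix: NormalizedMatrix, marker_probes: list[str]
) -> pd.Series:
    """Linear fold of each sample's panel mean over the cohort median.

    Measures absolute elevation (in folds) rather than standardized
    distance; used as the effect-size guard for calling.
    """
    sub = matrix.restrict(marker_probes)
    s = sub.values.mean(axis=0)
    return 2.0 ** (s - s.median())


def call_groups(
    matrix: NormalizedMatrix,
    codeset: CodeSet,
    compartment: str,
    references: dict[str, str],
    tau: float = 2.0,
    min_call_fold: float = 2.0,
    dendrogram: Dendrogram | None = None,
) -> list[GroupCall]:
    """Assign at most one entity diagnosis per sample.

    ``references`` maps entity -> reference sample id for the entities with
    a molecularly pre-diagnosed anchor in this run. Raises
    :class:`ClassificationIntegrityError` if any reference sample fails to
    recover its own entity.
    """
    entities = codeset.entities_in(compartment)
    for entity in references:
        if entity not in entities:
            raise ConfigurationError(
                f"entity {entity!r} is not callable in the {compartment} "
                "compartment but has a reference sample"
            )
    if not entities:
        raise ConfigurationError(f"no callable entities in {compartment!r}")

    scores = {
        e: signature_score(matrix, codeset.markers_for(e, compartment))
        for e in entities
    }
    folds = {
        e: panel_fold_over_cohort(matrix, codeset.markers_for(e, compartment))
        for e in entities
    }
    if dendrogram is None:
        dendrogram = hierarchical_cluster(
            matrix.restrict(codeset.analysis_probes(compartment))
        )
    ref_entities = [e for e in entities if e in references]
    k = len(ref_entities) + 1
    clusters = dendrogram.cut(min(k, dendrogram.n_leaves))

    calls: list[GroupCall] = []
    for sample in matrix.samples:
        zs = {e: float(scores[e][sample]) for e in entities}
        above = [e for e in entities if zs[e] >= tau]
        flags: list[str] = []
        called: str | None = None
        co_cluster = {
            e: bool(clusters[sample] == clusters[references[e]])
            for e in ref_entities
        }
        if above:
            best = max(zs[e] for e in above)
            top = [e for e in above if zs[e] == best]
            if len(top) > 1:
                flags.append("ambiguous")
            else:
                candidate = top[0]
                if float(folds[candidate][sample]) < min_call_fold:
                    flags.append("weak-elevation")
                elif candidate in references:
                    if co_cluster[candidate]:
                        called = candidate
                    else:
                        flags.append("no-reference-co-cluster")
                else:
                    called = candidate
                    flags.append("low-confidence-no-reference")
        calls.append(
            GroupCall(
                sample_id=sample,
                called_entity=called,
                signature_scores=zs,
                co_clusters_with_reference=co_cluster,
                dual_signature=len(above) > 1,
                flags=flags,
            )
        )

    by_id = {c.sample_id: c for c in calls}
    for entity, ref in references.items():
        if ref not in by_id:
            raise ConfigurationError(f"reference sample {ref!r} not in cohort")
        if by_id[ref].called_entity != entity:
            raise ClassificationIntegrityError(
                f"reference sample {ref!r} was called "
                f"{by_id[ref].called_entity!r}, expected {entity!r}"
            )
    return calls


def calls_to_frame(calls: list[GroupCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "called_entity": c.called_entity or "",
            "dual_signature": c.dual_signature,
            "outlier": c.outlier,
            "flags": ";".join(c.flags),
        }
        row.update({f"z_{e}": z for e, z in c.signature_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def split_high_low(scores: pd.Series, min_separation: float = 1.0) -> pd.Series:
    """Bimodal high/low split of panel scores via the largest gap.

    Sorts the scores and splits at the largest adjacent gap; if that gap is
    below ``min_separation`` (log2 units, default one two-fold step) the
    panel is considered unexpressed and everything is labeled low. Works
    whether the high group is a minority or a majority.
    """
    s = scores.sort_values()
    if len(s) < 2:
        return pd.Series(False, index=scores.index)
    gaps = s.to_numpy()[1:] - s.to_numpy()[:-1]
    i = int(np.argmax(gaps))
    if gaps[i] < min_separation:
        return pd.Series(False, index=scores.index)
    threshold = (s.iloc[i] + s.iloc[i + 1]) / 2.0
    return scores > threshold


def glioma_contrast(
    matrix: NormalizedMatrix,
    codeset: CodeSet,
    compartment: str = "supratentorial",
    entity: str = "HGNET-BCOR",
    min_separation: float = 1.0,
    outlier_height_quantile: float = 0.95,
) -> pd.Series:
    """Contrast an entity signature against the glioma panel (per sample).

    Returns labels in {"signature", "glioma", "dual", "outlier", "none"}:
    ``dual`` expresses both panels, ``signature``/``glioma`` exactly one,
    and a sample expressing neither is an ``outlier`` when it additionally
    sits apart in the tree — its first merge height exceeds the cohort's
    ``outlier_height_quantile`` of first-merge heights — else ``none``.
    """
    entity_probes = codeset.markers_for(entity, compartment)
    if not entity_probes:
        raise ConfigurationError(f"no {entity!r} panel in {compartment!r}")
    if not codeset.glioma_panel:
        raise ConfigurationError("CodeSet has no glioma panel")
    try:
        sub = matrix.restrict(entity_probes + codeset.glioma_panel)
    except ConfigurationError as err:
        raise ConfigurationError(f"missing panel probes: {err}") from None

    s_entity = sub.restrict(entity_probes).values.mean(axis=0)
    s_glioma = sub.restrict(codeset.glioma_panel).values.mean(axis=0)
    high_entity = split_high_low(s_entity, min_separation)
    high_glioma = split_high_low(s_glioma, min_separation)

    tree = hierarchical_cluster(sub)
    first_heights = tree.leaf_merge_heights()
    cutoff = float(first_heights.quantile(outlier_height_quantile))

    labels = {}
    for sample in sub.samples:
        he, hg = bool(high_entity[sample]), bool(high_glioma[sample])
        if he and hg:
            labels[sample] = "dual"
        elif he:
            labels[sample] = "signature"
        elif hg:
            labels[sample] = "glioma"
        elif float(first_heights[sample]) > cutoff:
            labels[sample] = "outlier"
        else:
            labels[sample] = "none"
    return pd.Series(labels, name="contrast_label")


def ordered_matrix(matrix: NormalizedMatrix, dendrogram: Dendrogram) -> pd.DataFrame:
    """Heatmap-ready matrix with samples in dendrogram leaf order."""
    return matrix.values[dendrogram.leaf_order()]
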