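"""In-silico marker-gene discovery from expression matrices.

The discovery statistic is a resampled, balanced two-sample comparison:
the target class (one tumor entity, n samples) is compared repeatedly
(default 100 draws; 200 for classes with few clean up-regulated markers)
against an equally sized subset drawn without replacement from all other
tumors. Each draw contributes a per-probe two-sided Student t-test p-value
and a log2 mean difference; the per-probe means of both over the draws
measure marker quality. Repeating the test against random balanced
subsets makes the selection robust to the composition of the much larger
"everything else" pool.

Upstream of the statistic: quantile normalization across samples (run per
brain compartment), log2 transform, and removal of near-constant probes
(log2-scale variance below 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .matrix import LINEAR, LOG2, ExpressionMatrix


@dataclass
class DiscoveryParams:
    """Tunable parameters of the marker-discovery stage.

    variance_threshold : probes with log2-scale variance strictly below this
        are filtered out (default 0.25).
    n_reps : number of balanced resampling draws (default 100).
    fold_threshold : minimum mean linear fold for a candidate (default 10).
    top_n : panel size cap after ranking (default 100).
    welch : use Welch's unequal-variance t-test instead of the pooled
        Student test (default False).
    """

    variance_threshold: float = 0.25
    n_reps: int = 100
    fold_threshold: float = 10.0
    top_n: int = 100
    welch: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.variance_threshold < 0:
            raise ConfigurationError("variance_threshold must be >= 0")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.fold_threshold < 1:
            raise ConfigurationError("fold_threshold must be >= 1")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")


@dataclass
class MarkerStat:
    """Per-probe resampling summary for one target class."""

    probe_id: str
    target_class: str
    mean_p: float
    mean_log2fc: float
    rank: int = 0

    @property
    def mean_linear_fold(self) -> float:
        return float(2.0 ** self.mean_log2fc)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile distribution.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample ranks are
    preserved. Ties receive the mean of the reference values at the tied
    ranks (equal inputs map to equal outputs). On tie-free data —
    the generic case for continuous intensities — the operation is
    exactly idempotent.
    """
    if matrix.n_samples < 2:
        raise ConfigurationError("quantile normalization needs >= 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    n_probes = X.shape[0]
    sorted_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n_probes + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        # integer ranks index directly; midranks (ties) interpolate, i.e.
        # average the reference values of the tied positions
        out[:, j] = np.interp(ranks, positions, sorted_means)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(
        values=values,
        scale=matrix.scale,
        labels=matrix.labels,
        compartment=matrix.compartment,
    )


def log2_and_variance_filter(
    matrix: ExpressionMatrix, params: DiscoveryParams | None = None
) -> ExpressionMatrix:
    """log2-transform and drop probes with across-sample variance < threshold.

    The removal rule is strict (< threshold), so a probe whose log2
    variance equals the threshold exactly is retained. Probe order is
    preserved. Input must be strictly positive linear-scale intensities.
    """
    params = params or DiscoveryParams()
    params.validate()
    if matrix.scale != LINEAR:
        raise ConfigurationError("expected a linear-scale matrix")
    X = matrix.values
    if (X.to_numpy() <= 0).any():
        bad = X.stack()
        bad = bad[bad <= 0]
        probe, sample = bad.index[0]
        raise ConfigurationError(
            f"non-positive intensity at probe {probe!r}, sample {sample!r}"
        )
    log2 = np.log2(X)
    variances = log2.var(axis=1, ddof=1)
    keep = variances >= params.variance_threshold
    return ExpressionMatrix(
        values=log2.loc[keep],
        scale=LOG2,
        labels=matrix.labels,
        compartment=matrix.compartment,
    )


def _t_pvalues(a: np.ndarray, b: np.ndarray, welch: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with a zero-variance convention.

    Probes that are constant within both groups would yield 0/0; they are
    assigned p = 0 when the group means differ and p = 1 when they are
    equal, so degenerate probes never propagate NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    nan = ~np.isfinite(p)
    if nan.any():
        diff = a[nan].mean(axis=1) != b[nan].mean(axis=1)
        p[nan] = np.where(diff, 0.0, 1.0)
    return p


def resampled_marker_stats(
    matrix: ExpressionMatrix,
    target_class: str,
    params: DiscoveryParams | None = None,
    labels: pd.Series | None = None,
) -> list[MarkerStat]:
    """Mean p-value and mean log2 fold over balanced resampled t-tests.

    For each of ``params.n_reps`` repetitions a subset of the non-target
    pool of size min(n_target, pool) is drawn without replacement (seeded);
    per probe, a two-sided t-test and the log2 mean difference
    (target minus subset) are computed. The returned statistics are the
    arithmetic means over repetitions. Identical inputs and seed give
    identical output.
    """
    params = params or DiscoveryParams()
    params.validate()
    if matrix.scale != LOG2:
        raise ConfigurationError("resampled stats expect a log2-scale matrix")
    labels = labels if labels is not None else matrix.labels
    if labels is None:
        raise ConfigurationError("no class labels available")
    labels = labels.reindex(matrix.samples)

    target_ids = matrix.samples[labels == target_class]
    pool_ids = matrix.samples[labels != target_class]
    if len(target_ids) < 2:
        raise ConfigurationError(
            f"target class {target_class!r} has {len(target_ids)} samples; need >= 2"
        )
    if len(pool_ids) < 2:
        raise ConfigurationError("non-target pool has fewer than 2 samples")

    X = matrix.values
    target = X[target_ids].to_numpy(dtype=float)
    pool = X[pool_ids].to_numpy(dtype=float)
    n_t = target.shape[1]
    draw_size = min(n_t, pool.shape[1])
    if draw_size < n_t:
        warnings.warn(
            f"non-target pool ({pool.shape[1]}) smaller than target class "
            f"({n_t}); using the whole pool in every repetition",
            stacklevel=2,
        )

    rng = np.random.default_rng(params.seed)
    target_mean = target.mean(axis=1)
    p_sum = np.zeros(X.shape[0])
    fc_sum = np.zeros(X.shape[0])
    for _ in range(params.n_reps):
        cols = rng.choice(pool.shape[1], size=draw_size, replace=False)
        subset = pool[:, cols]
        p_sum += _t_pvalues(target, subset, params.welch)
        fc_sum += target_mean - subset.mean(axis=1)

    mean_p = p_sum / params.n_reps
    mean_fc = fc_sum / params.n_reps
    return [
        MarkerStat(
            probe_id=probe,
            target_class=target_class,
            mean_p=float(mean_p[i]),
            mean_log2fc=float(mean_fc[i]),
        )
        for i, probe in enumerate(X.index)
    ]


def rank_and_select(
    stats_list: list[MarkerStat], params: DiscoveryParams | None = None
) -> list[MarkerStat]:
    """Rank candidates and return the fold-filtered top panel.

    Sorting is by ascending mean p-value, ties broken by descending mean
    log2 fold change, then lexicographic probe id (fully deterministic).
    Every input stat receives its rank (a permutation of 1..n_tested); the
    returned panel keeps only probes whose mean linear fold reaches
    ``fold_threshold``, truncated to ``top_n``.
    """
    params = params or DiscoveryParams()
    params.validate()
    ordered = sorted(
        stats_list, key=lambda s: (s.mean_p, -s.mean_log2fc, s.probe_id)
    )
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    panel = [s for s in ordered if s.mean_linear_fold >= params.fold_threshold]
    return panel[: params.top_n]


@dataclass
class MarkerCandidate:
    """A final candidate probe with provenance across two ranked lists."""

    probe_id: str
    internal_rank: int | None
    external_rank: int | None
    provenance: str  # "both" | "external-only" | "forced"


def intersect_with_reference_list(
    panel: list[MarkerStat],
    external_top_list: list[str],
    forced: list[str] = (),
) -> list[MarkerCandidate]:
    """Intersect an internal panel with an external ranked probe list.

    Probes present in both lists are returned with their rank in each.
    ``forced`` probes are always included: if absent from the internal
    panel they are flagged ``external-only`` (probes mandated from outside
    evidence despite not ranking internally).
    """
    internal_ranks = {s.probe_id: s.rank for s in panel}
    external_ranks = {p: i + 1 for i, p in enumerate(external_top_list)}
    out: list[MarkerCandidate] = []
    for probe in external_top_list:
        if probe in internal_ranks:
            out.append(
                MarkerCandidate(
                    probe_id=probe,
                    internal_rank=internal_ranks[probe],
                    external_rank=external_ranks[probe],
                    provenance="both",
                )
            )
    for probe in forced:
        if any(c.probe_id == probe for c in out):
            continue
        out.append(
            MarkerCandidate(
                probe_id=probe,
                internal_rank=internal_ranks.get(probe),
                external_rank=external_ranks.get(probe),
                provenance="external-only" if probe not in internal_ranks else "forced",
            )
        )
    return out


def stats_to_frame(stats_list: list[MarkerStat]) -> pd.DataFrame:
    """Tabular view of marker statistics (for TSV export)."""
    return pd.DataFrame(
        {
            "probe_id": [s.probe_id for s in stats_list],
            "target_class": [s.target_class for s in stats_list],
            "mean_p": [s.mean_p for s in stats_list],
            "mean_log2fc": [s.mean_log2fc for s in stats_list],
            "mean_linear_fold": [s.mean_linear_fold for s in stats_list],
            "rank": [s.rank for s in stats_list],
        }
    )
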