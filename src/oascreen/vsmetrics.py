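"""Virtual-screening performance metrics on ranked, labeled results.

Covers the ROC curve and its area (AUC), the early-recognition BEDROC
score (Truchon-Bailey rescaled RIE with exponential rank weighting,
default alpha = 53.6, which places 80% of the weight mass on the top 3%
of the ranked list), the ROC enrichment ROCE_x% (sensitivity at the rank
cutoff containing the top x% of true decoys, divided by the realized
false positive rate), its arithmetically weighted variant awROCE_x%
(each active weighted inversely to its chemotype-cluster size), and the
chemotype discovery curve.

Tie policy: AUC uses the average-rank (Mann-Whitney) convention, so tied
active/decoy pairs count one half.  The cutoff metrics and BEDROC use a
canonical pessimistic ordering: descending score, decoys before actives
at equal score, then id.  All metrics are therefore invariant to
permuting tied entries in the input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankedList",
    "MetricReport",
    "roc_curve",
    "auc",
    "bedroc",
    "bedroc_weight_fraction",
    "roce",
    "awroce",
    "chemotype_discovery_curve",
    "compute_report",
]

TIE_POLICY = "score-desc, decoy-first on ties"


@dataclass
class RankedList:
    """Scored screening results, canonically sorted (see module docstring)."""

    ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray  # bool, True = active
    clusters: np.ndarray | None = None  # object array, None entries allowed
    tie_policy: str = TIE_POLICY

    @classmethod
    def from_records(cls, ids, scores, labels, clusters=None) -> "RankedList":
        ids = np.asarray(ids, dtype=object)
        scores = np.asarray(scores, dtype=float)
        if isinstance(labels, np.ndarray) and labels.dtype == bool:
            active = labels
        else:
            active = np.array(
                [l if isinstance(l, (bool, np.bool_)) else str(l).lower() == "active" for l in labels],
                dtype=bool)
        if clusters is not None:
            clusters = np.asarray(clusters, dtype=object)
        n = len(ids)
        if not (len(scores) == len(active) == n) or (clusters is not None and len(clusters) != n):
            raise ValueError("ids, scores, labels (and clusters) must have equal length")
        # decoys (label False) before actives at equal score
        order = sorted(range(n), key=lambda k: (-scores[k], active[k], str(ids[k])))
        order = np.array(order, dtype=np.intp)
        return cls(ids=ids[order], scores=scores[order], labels=active[order],
                   clusters=None if clusters is None else clusters[order])

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoys(self) -> int:
        return len(self) - self.n_actives

    def _require_both_labels(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ValueError("metrics require at least one active and one decoy")

    def _require_clusters(self) -> None:
        if self.clusters is None:
            raise ValueError("metric requires chemotype cluster annotations")
        for idx in np.flatnonzero(self.labels):
            if self.clusters[idx] is None:
                raise ValueError(f"active {self.ids[idx]!r} has no cluster id")


def roc_curve(r: RankedList) -> np.ndarray:
    """Stepwise ROC curve over all score thresholds, (FPR, TPR) pairs.

    Tied scores are grouped into a single threshold, so a tied block
    appears as one diagonal segment.  Starts at (0, 0), ends at (1, 1).
    """
    r._require_both_labels()
    points = [(0.0, 0.0)]
    tp = fp = 0
    i, n = 0, len(r)
    while i < n:
        j = i
        while j < n and r.scores[j] == r.scores[i]:
            j += 1
        tp += int(r.labels[i:j].sum())
        fp += (j - i) - int(r.labels[i:j].sum())
        points.append((fp / r.n_decoys, tp / r.n_actives))
        i = j
    return np.array(points)


def auc(r: RankedList) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    Equals the fraction of (active, decoy) pairs in which the active
    outscores the decoy, ties counted one half; identical to the
    trapezoidal area under the tie-grouped ROC curve.
    """
    r._require_both_labels()
    from scipy.stats import rankdata

    ranks = rankdata(r.scores)  # average ranks, ascending
    n_act, n_dec = r.n_actives, r.n_decoys
    u = ranks[r.labels].sum() - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_dec))


def bedroc_weight_fraction(alpha: float, top_fraction: float) -> float:
    """Fraction of the exponential weight mass in the top ``top_fraction``.

    The BEDROC rank weight is w(x) = alpha e^{-alpha x} on x in [0, 1];
    the mass above a relative rank x0 is (1 - e^{-alpha x0}) / (1 - e^{-alpha}).
    """
    if alpha <= 0 or not (0 < top_fraction <= 1):
        raise ValueError("alpha > 0 and 0 < top_fraction <= 1 required")
    return (1.0 - math.exp(-alpha * top_fraction)) / (1.0 - math.exp(-alpha))


def bedroc(r: RankedList, alpha: float = 53.6) -> float:
    """Truchon-Bailey BEDROC: exponentially rank-weighted, rescaled to [0, 1].

    The robust initial enhancement RIE is computed from the active ranks
    (1-based, canonical pessimistic order) and min-max rescaled using its
    exact attainable extremes, so a perfect ranking scores 1 and an
    anti-perfect ranking scores 0.
    """
    r._require_both_labels()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n = len(r)
    n_act = r.n_actives
    ra = n_act / n
    ranks = np.flatnonzero(r.labels) + 1  # 1-based ranks of actives
    rie = float(np.exp(-alpha * ranks / n).sum())
    rie /= n_act * (1.0 - math.exp(-alpha)) / (n * math.expm1(alpha / n))
    factor = ra * math.sinh(alpha / 2.0) / (math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    return float(rie * factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra))))


def _decoy_cutoff(r: RankedList, x_percent: float) -> tuple[int, int]:
    """Position (0-based, inclusive) of the k-th decoy and k = ceil(x% N_dec)."""
    if not 0 < x_percent < 100:
        raise ValueError("x_percent must lie in (0, 100)")
    k = math.ceil(x_percent / 100.0 * r.n_decoys)
    if k == 0:
        raise ValueError(f"cutoff {x_percent}% yields zero decoys")
    decoy_positions = np.flatnonzero(~r.labels)
    return int(decoy_positions[k - 1]), k


def roce(r: RankedList, x_percent: float) -> float:
    """ROC enrichment: sensitivity at the top-x%-of-decoys cutoff over FPR.

    ROCE_x% = (N_actives^x% / N_actives) / (N_decoys^x% / N_decoys) with
    N_actives^x% the actives found along with the top k = ceil(x% N_decoys)
    true decoys.
    """
    r._require_both_labels()
    boundary, k = _decoy_cutoff(r, x_percent)
    found = int(r.labels[:boundary].sum())
    se = found / r.n_actives
    fpr = k / r.n_decoys
    return float(se / fpr)


def awroce(r: RankedList, x_percent: float) -> float:
    """Arithmetically weighted ROCE: actives weighted by 1/cluster size.

    SE^aw_x% = sum_j sum_i alpha_ij^x% (1/N_j) / N_clusters, divided by the
    realized FPR; rewards retrieving many distinct chemotypes early.
    """
    r._require_both_labels()
    r._require_clusters()
    boundary, k = _decoy_cutoff(r, x_percent)
    active_idx = np.flatnonzero(r.labels)
    cluster_sizes: dict[str, int] = {}
    for idx in active_idx:
        cluster_sizes[r.clusters[idx]] = cluster_sizes.get(r.clusters[idx], 0) + 1
    n_clusters = len(cluster_sizes)
    se_aw = sum(
        1.0 / cluster_sizes[r.clusters[idx]]
        for idx in active_idx if idx < boundary
    ) / n_clusters
    fpr = k / r.n_decoys
    return float(se_aw / fpr)


def chemotype_discovery_curve(r: RankedList) -> np.ndarray:
    """Step curve: fraction of clusters first discovered vs decoy fraction."""
    r._require_both_labels()
    r._require_clusters()
    all_clusters = {r.clusters[i] for i in np.flatnonzero(r.labels)}
    n_clusters = len(all_clusters)
    seen: set = set()
    decoys_seen = 0
    points = []
    for i in range(len(r)):
        if not r.labels[i]:
            decoys_seen += 1
        else:
            c = r.clusters[i]
            if c not in seen:
                seen.add(c)
                points.append((decoys_seen / r.n_decoys, len(seen) / n_clusters))
    return np.array(points)


@dataclass
class MetricReport:
    """Bundle of VS metrics for one ranked list."""

    auc: float
    bedroc: float
    alpha: float
    roce: dict[float, float] = field(default_factory=dict)
    awroce: dict[float, float] | None = None

    def to_json(self) -> str:
        payload = {
            "auc": self.auc,
            "bedroc": self.bedroc,
            "alpha": self.alpha,
            "roce": {str(k): v for k, v in self.roce.items()},
        }
        if self.awroce is not None:
            payload["awroce"] = {str(k): v for k, v in self.awroce.items()}
        return json.dumps(payload, indent=1)

    def table(self) -> str:
        lines = [f"AUC      {self.auc:8.4f}",
                 f"BEDROC   {self.bedroc:8.4f}  (alpha={self.alpha})"]
        for x, v in sorted(self.roce.items()):
            lines.append(f"ROCE_{x:g}%   {v:8.3f}")
        if self.awroce is not None:
            for x, v in sorted(self.awroce.items()):
                lines.append(f"awROCE_{x:g}% {v:8.3f}")
        return "\n".join(lines)


def compute_report(r: RankedList, alpha: float = 53.6,
                   roce_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0)) -> MetricReport:
    """AUC, BEDROC and (aw)ROCE at the requested decoy fractions."""
    levels = [x for x in roce_levels if math.ceil(x / 100 * r.n_decoys) >= 1]
    report = MetricReport(
        auc=auc(r), bedroc=bedroc(r, alpha), alpha=alpha,
        roce={x: roce(r, x) for x in levels},
    )
    if r.clusters is not None and all(
            r.clusters[i] is not None for i in np.flatnonzero(r.labels)):
        report.awroce = {x: awroce(r, x) for x in levels}
    return report
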