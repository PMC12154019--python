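"""Chemotype classification from THC/CBD quantitation.

Cannabis sativa samples fall into three chemical phenotypes defined by the
ratio of the two major cannabinoids: chemotype I (drug type, THC >> CBD),
chemotype II (intermediate, THC ~ CBD) and chemotype III (fiber type,
CBD >> THC).  The working statistic is ``log10(%THC / %CBD)`` on percent
dry-weight contents; published survey work separates the three classes with
fixed cutoffs at 0.0 (I vs II) and -1.0 (II vs III).

Two classification routes are provided:

* :func:`classify_fixed` -- the fixed-cutoff rule (default, exact);
* :func:`cluster_samples` -- agglomerative complete-linkage Euclidean
  clustering of the log10-transformed (%THC, %CBD) points, mirroring the
  heatmap-based grouping route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CannabinoidRecord",
    "ChemotypeCall",
    "ClusteringResult",
    "DEFAULT_FLOOR",
    "DEFAULT_LOWER_CUT",
    "DEFAULT_UPPER_CUT",
    "compute_log_ratio",
    "classify_fixed",
    "classify_records",
    "cluster_samples",
    "derive_cluster_ranges",
    "round_half_away",
    "read_cannabinoid_csv",
    "calls_to_frame",
]

#: Quantitation floor in percent w/w; the smallest content reported by the
#: UPLC assay this statistic was designed around.
DEFAULT_FLOOR = 0.001
DEFAULT_UPPER_CUT = 0.0
DEFAULT_LOWER_CUT = -1.0


@dataclass(frozen=True)
class CannabinoidRecord:
    """One sample's THC and CBD contents in percent w/w."""

    sample_id: str
    pct_thc: float
    pct_cbd: float

    def __post_init__(self) -> None:
        if self.pct_thc < 0 or self.pct_cbd < 0:
            raise ValueError(
                f"{self.sample_id}: cannabinoid contents must be >= 0"
            )


@dataclass(frozen=True)
class ChemotypeCall:
    sample_id: str
    log_ratio: float
    chemotype: str  # "I" | "II" | "III"
    method: str  # "fixed_cutoff" | "cluster"
    flags: tuple[str, ...] = ()


@dataclass
class ClusteringResult:
    """Full merge history plus a k-cluster cut.

    ``dendrogram`` is the scipy linkage matrix (merge history with heights);
    ``labels`` maps sample_id -> cluster label (1..k) for the requested k.
    """

    sample_ids: list[str]
    dendrogram: np.ndarray
    k: int
    labels: dict[str, int] = field(default_factory=dict)

    def partition_at_k(self, k: int) -> dict[str, int]:
        lab = fcluster(self.dendrogram, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in lab)))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so -1.085 -> -1.09), unlike banker's round."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def compute_log_ratio(
    record: CannabinoidRecord, floor: float = DEFAULT_FLOOR
) -> tuple[float, tuple[str, ...]]:
    """log10 of the THC:CBD content ratio, with below-floor values clamped.

    Returns ``(log_ratio, flags)``; a ``floored_thc`` / ``floored_cbd`` flag
    records that the corresponding content was below ``floor`` (e.g. CBD
    below the detection limit in drug-type samples).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    flags = []
    thc, cbd = record.pct_thc, record.pct_cbd
    if thc < floor:
        flags.append("floored_thc")
        thc = floor
    if cbd < floor:
        flags.append("floored_cbd")
        cbd = floor
    return math.log10(thc / cbd), tuple(flags)


def classify_fixed(
    log_ratio: float,
    upper_cut: float = DEFAULT_UPPER_CUT,
    lower_cut: float = DEFAULT_LOWER_CUT,
) -> str:
    """Chemotype from fixed log-ratio cutoffs.

    I if log_ratio > upper_cut, II if lower_cut < log_ratio <= upper_cut,
    III if log_ratio <= lower_cut.
    """
    if not math.isfinite(log_ratio):
        raise ValueError(f"log_ratio must be finite, got {log_ratio!r}")
    if not lower_cut < upper_cut:
        raise ValueError("require lower_cut < upper_cut")
    if log_ratio > upper_cut:
        return "I"
    if log_ratio > lower_cut:
        return "II"
    return "III"


def classify_records(
    records: list[CannabinoidRecord],
    floor: float = DEFAULT_FLOOR,
    upper_cut: float = DEFAULT_UPPER_CUT,
    lower_cut: float = DEFAULT_LOWER_CUT,
) -> list[ChemotypeCall]:
    """Fixed-cutoff classification of a whole cannabinoid table."""
    _check_unique_ids(records)
    calls = []
    for rec in records:
        lr, flags = compute_log_ratio(rec, floor=floor)
        calls.append(
            ChemotypeCall(
                sample_id=rec.sample_id,
                log_ratio=lr,
                chemotype=classify_fixed(lr, upper_cut, lower_cut),
                method="fixed_cutoff",
                flags=flags,
            )
        )
    return calls


def _check_unique_ids(records) -> None:
    ids = [r.sample_id for r in records]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample_ids: {sorted(dup)}")


def cluster_samples(
    records: list[CannabinoidRecord],
    k: int = 3,
    floor: float = DEFAULT_FLOOR,
) -> ClusteringResult:
    """Complete-linkage Euclidean clustering of log10 (%THC, %CBD) points.

    Each sample is a 2-D point (log10 %THC, log10 %CBD) after flooring at
    ``floor``; agglomeration uses the complete (farthest-neighbour) method,
    so merge heights are non-decreasing.  Deterministic for a given input
    order (ties, which cannot occur for generic real-valued inputs, are
    resolved by the stable order of the condensed distance matrix).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    _check_unique_ids(records)
    pts = np.log10(
        np.maximum(
            np.array([[r.pct_thc, r.pct_cbd] for r in records], dtype=float),
            floor,
        )
    )
    ids = [r.sample_id for r in records]
    if len(records) == 1:
        return ClusteringResult(ids, np.empty((0, 4)), k=1, labels={ids[0]: 1})
    Z = linkage(pdist(pts, metric="euclidean"), method="complete")
    res = ClusteringResult(ids, Z, k=k)
    res.labels = res.partition_at_k(k)
    return res


def derive_cluster_ranges(
    partition: dict[str, int],
    log_ratios: dict[str, float],
    ndigits: int = 2,
) -> dict[int, tuple[float, float]]:
    """Per-cluster (min, max) log-ratio, rounded half away from zero.

    ``partition`` maps sample_id -> cluster label; ``log_ratios`` maps
    sample_id -> log10(%THC/%CBD).  Every sample in the partition must have
    a log ratio.
    """
    missing = set(partition) - set(log_ratios)
    if missing:
        raise ValueError(f"no log_ratio for samples: {sorted(missing)}")
    ranges: dict[int, tuple[float, float]] = {}
    for label in sorted(set(partition.values())):
        vals = [log_ratios[s] for s, c in partition.items() if c == label]
        ranges[label] = (
            round_half_away(min(vals), ndigits),
            round_half_away(max(vals), ndigits),
        )
    return ranges


def read_cannabinoid_csv(path) -> list[CannabinoidRecord]:
    """Read a ``sample_id,pct_thc,pct_cbd`` CSV into records."""
    df = pd.read_csv(path)
    required = {"sample_id", "pct_thc", "pct_cbd"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"cannabinoid CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"cannabinoid CSV {path} contains no rows")
    return [
        CannabinoidRecord(str(r.sample_id), float(r.pct_thc), float(r.pct_cbd))
        for r in df.itertuples(index=False)
    ]


def calls_to_frame(calls: list[ChemotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "log_ratio": [c.log_ratio for c in calls],
            "chemotype": [c.chemotype for c in calls],
            "method": [c.method for c in calls],
            "flags": [";".join(c.flags) for c in calls],
        }
    )
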