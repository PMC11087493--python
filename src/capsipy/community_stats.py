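"""Point-pattern statistics of viral particle picks.

Virions observed in micrographs cluster into spatial "communities".  Given
2D pick coordinates (nm) this module computes nearest-neighbor distances,
single-linkage community partitions at a user-chosen cutoff, box-plot
statistics matching the 1.5·IQR whisker convention, and the genome
packaging efficiency from full/empty capsid counts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "ParticlePick",
    "CommunitySummary",
    "BoxStats",
    "nearest_neighbor_distances",
    "cluster_communities",
    "box_stats",
    "packaging_efficiency",
    "read_picks",
    "write_picks",
]


@dataclasses.dataclass
class ParticlePick:
    particle_id: int
    x: float  # nm
    y: float  # nm
    diameter: float | None = None  # nm
    state: str = "unknown"  # full | empty | pleomorphic | unknown

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"particle {self.particle_id}: non-finite coordinates")
        if self.diameter is not None and self.diameter <= 0:
            raise ValueError(f"particle {self.particle_id}: diameter must be positive")


@dataclasses.dataclass
class CommunitySummary:
    n_communities: int
    sizes: list[int]
    mean_size: float
    sd_size: float
    n_singletons: int
    labels: dict[int, int]  # particle_id -> community label (0 = singleton)


@dataclasses.dataclass
class BoxStats:
    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def _xy(picks: Sequence[ParticlePick]) -> np.ndarray:
    return np.array([[p.x, p.y] for p in picks])


def nearest_neighbor_distances(
    picks: Sequence[ParticlePick], edge_to_edge: bool = False
) -> list[tuple[tuple[int, int], float]]:
    """Each particle's nearest neighbor, mutual pairs reported once.

    Distances are center-to-center by default; with ``edge_to_edge`` the
    two radii are subtracted (requires diameters), clipped at zero.
    Returned pairs are (particle_id, nearest particle_id) de-duplicated so
    a mutual nearest pair contributes one unique entry.
    """
    if len(picks) < 2:
        raise ValueError("need at least 2 picks for neighbor distances")
    xy = _xy(picks)
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=2)
    out: dict[tuple[int, int], float] = {}
    for i, p in enumerate(picks):
        # with coincident points the self-match may land in either column
        col = 1 if int(idx[i, 1]) != i else 0
        j = int(idx[i, col])
        d = float(dist[i, col])
        if edge_to_edge:
            if p.diameter is None or picks[j].diameter is None:
                raise ValueError("edge-to-edge distances require diameters")
            d = max(0.0, d - (p.diameter + picks[j].diameter) / 2.0)
        key = tuple(sorted((p.particle_id, picks[j].particle_id)))
        out.setdefault(key, d)
    return sorted(out.items())


def cluster_communities(
    picks: Sequence[ParticlePick],
    linkage_cutoff: float,
    include_singletons: bool = False,
) -> CommunitySummary:
    """Single-linkage communities at a distance cutoff (nm).

    Two particles join a community when connected by a chain of links each
    ≤ cutoff.  Size-1 groups are counted as singletons and excluded from
    the size statistics unless requested.
    """
    if linkage_cutoff <= 0:
        raise ValueError("linkage_cutoff must be positive")
    if len(picks) == 0:
        return CommunitySummary(0, [], float("nan"), float("nan"), 0, {})
    if len(picks) == 1:
        return CommunitySummary(0, [], float("nan"), float("nan"), 1,
                                {picks[0].particle_id: 0})
    xy = _xy(picks)
    labels = fcluster(linkage(pdist(xy), method="single"),
                      t=linkage_cutoff, criterion="distance")
    sizes_by_label: dict[int, int] = {}
    for lab in labels:
        sizes_by_label[lab] = sizes_by_label.get(lab, 0) + 1
    community_labels = {lab for lab, n in sizes_by_label.items()
                        if n > 1 or include_singletons}
    # relabel communities 1..k by first appearance; singletons get 0
    relabel: dict[int, int] = {}
    out_labels: dict[int, int] = {}
    for p, lab in zip(picks, labels):
        if lab in community_labels:
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
            out_labels[p.particle_id] = relabel[lab]
        else:
            out_labels[p.particle_id] = 0
    sizes = [sizes_by_label[lab] for lab in relabel]
    n_singletons = sum(1 for lab, n in sizes_by_label.items() if n == 1)
    if include_singletons:
        n_singletons = 0
    mean = float(np.mean(sizes)) if sizes else float("nan")
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0 if sizes else float("nan")
    return CommunitySummary(len(sizes), sizes, mean, sd, n_singletons, out_labels)


def box_stats(values: Sequence[float]) -> BoxStats:
    """Box-plot statistics with Tukey 1.5·IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the extreme data inside [q25 − 1.5·IQR, q75 + 1.5·IQR] and
    points beyond are outliers.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 4:
        raise ValueError("box statistics need at least 4 values")
    q25, median, q75 = np.percentile(vals, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return BoxStats(
        q25=float(q25),
        median=float(median),
        q75=float(q75),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
    )


def packaging_efficiency(n_full: int, n_empty: int) -> tuple[float, int]:
    """Genome packaging efficiency: full / (full + empty) mature capsids.

    Returns (raw percentage, percentage rounded to the nearest ten).
    """
    if n_full < 0 or n_empty < 0:
        raise ValueError("counts must be non-negative")
    total = n_full + n_empty
    if total == 0:
        raise ValueError("at least one capsid must be counted")
    raw = 100.0 * n_full / total
    return raw, int(round(raw / 10.0) * 10)


# ---------------------------------------------------------------------------
# pick table I/O

PICK_COLUMNS = ["particle_id", "x_nm", "y_nm", "diameter_nm", "state"]


def read_picks(path: str | Path) -> list[ParticlePick]:
    df = pd.read_csv(path, sep="\t")
    picks = []
    for row in df.itertuples(index=False):
        d = getattr(row, "diameter_nm", None)
        picks.append(
            ParticlePick(
                particle_id=int(row.particle_id),
                x=float(row.x_nm),
                y=float(row.y_nm),
                diameter=None if d is None or pd.isna(d) else float(d),
                state=str(getattr(row, "state", "unknown")),
            )
        )
    return picks


def write_picks(picks: Sequence[ParticlePick], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "particle_id": p.particle_id,
                "x_nm": p.x,
                "y_nm": p.y,
                "diameter_nm": p.diameter,
                "state": p.state,
            }
            for p in picks
        ],
        columns=PICK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
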