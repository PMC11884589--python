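"""Structural- and reaction-diversity analytics for generated datasets.

Pairwise-distance histograms expose dissociative structures (mass beyond
5 Å), bonded-angle and dihedral histograms expose conformational coverage,
and activation-energy summaries grouped by the number of bond changes
characterize reaction diversity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Geometry, MolecularGraph, graph_diff, perceive_bonds
from .database import ReactionRecord
from .gsm import ReactionTriad

__all__ = [
    "HistogramSummary",
    "pairwise_distance_histogram",
    "internal_angle_histograms",
    "activation_energy_summary",
    "export_histogram_csv",
]


@dataclass(frozen=True)
class HistogramSummary:
    """Binned counts with an explicit overflow bin as the final count."""

    edges: np.ndarray  # strictly increasing, len = n_bins + 1
    counts: np.ndarray  # len = n_bins (+1 if overflow enabled)
    total: int
    overflow: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.total:
            raise ValueError("counts must sum to total")

    @property
    def densities(self) -> np.ndarray:
        """Counts normalized to unit total (overflow bin included)."""
        return self.counts / max(self.total, 1)

    def mass_above(self, x: float) -> int:
        """Observations in bins entirely above x (overflow included)."""
        body = self.counts[:-1] if self.overflow else self.counts
        idx = np.searchsorted(self.edges, x, side="left")
        out = int(body[idx:].sum())
        if self.overflow:
            out += int(self.counts[-1])
        return out


def _iter_structures(records: Iterable[ReactionRecord | Geometry]) -> Iterable[Geometry]:
    for item in records:
        if isinstance(item, Geometry):
            yield item
        else:
            yield from item.structures


def pairwise_distance_histogram(
    records: Sequence[ReactionRecord | Geometry],
    bin_width: float = 0.1,
    max_range: float = 8.0,
) -> HistogramSummary:
    """Histogram of all unordered atom-pair distances across all structures.

    Distances beyond ``max_range`` land in a trailing overflow bin.
    """
    structures = list(_iter_structures(records))
    if not structures:
        raise ValueError("empty dataset")
    n_bins = int(round(max_range / bin_width))
    edges = np.linspace(0.0, max_range, n_bins + 1)
    counts = np.zeros(n_bins + 1, dtype=np.int64)
    total = 0
    for g in structures:
        n = g.n_atoms
        if n < 2:
            continue
        iu = np.triu_indices(n, k=1)
        diff = g.positions[:, None, :] - g.positions[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))[iu]
        total += d.size
        over = d >= max_range
        counts[-1] += int(over.sum())
        idx = np.minimum((d[~over] / bin_width).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1)
    return HistogramSummary(edges=edges, counts=counts, total=total, overflow=True)


def _bonded_triplets(graph: MolecularGraph) -> list[tuple[int, int, int]]:
    out = []
    for j in range(graph.n_atoms):
        nbrs = sorted(graph.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((nbrs[a], j, nbrs[b]))
    return out


def _bonded_quartets(graph: MolecularGraph) -> list[tuple[int, int, int, int]]:
    out = []
    for j, k in sorted(graph.bonds):
        for i in sorted(graph.neighbors(j) - {k}):
            for l in sorted(graph.neighbors(k) - {j, i}):
                out.append((i, j, k, l))
    return out


def _angle(p0, p1, p2) -> float:
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def internal_angle_histograms(
    records: Sequence[ReactionRecord | Geometry],
    bin_width: float = 5.0,
    perception_scale: float = 1.2,
) -> tuple[HistogramSummary, HistogramSummary]:
    """(bonded triplet angle, bonded quartet dihedral) histograms in degrees.

    Connectivity is perceived per structure; angles lie in [0, 180],
    dihedrals in (−180, 180].
    """
    n_ang = int(round(180.0 / bin_width))
    ang_edges = np.linspace(0.0, 180.0, n_ang + 1)
    dih_edges = np.linspace(-180.0, 180.0, 2 * n_ang + 1)
    ang_counts = np.zeros(n_ang, dtype=np.int64)
    dih_counts = np.zeros(2 * n_ang, dtype=np.int64)
    ang_total = dih_total = 0
    for g in _iter_structures(records):
        if g.n_atoms < 3:
            continue
        graph = perceive_bonds(g, scale=perception_scale)
        for i, j, k in _bonded_triplets(graph):
            a = _angle(g.positions[i], g.positions[j], g.positions[k])
            ang_counts[min(int(a / bin_width), n_ang - 1)] += 1
            ang_total += 1
        for i, j, k, l in _bonded_quartets(graph):
            d = _dihedral(g.positions[i], g.positions[j], g.positions[k], g.positions[l])
            # half-open (−180, 180]: put the value in the bin left of its edge
            idx = int(np.ceil((d + 180.0) / bin_width)) - 1
            dih_counts[int(np.clip(idx, 0, 2 * n_ang - 1))] += 1
            dih_total += 1
    return (
        HistogramSummary(edges=ang_edges, counts=ang_counts, total=ang_total),
        HistogramSummary(edges=dih_edges, counts=dih_counts, total=dih_total),
    )


def activation_energy_summary(
    triads: Sequence[ReactionTriad],
    perception_scale: float = 1.2,
) -> dict[int, dict[str, float]]:
    """Median/quartile activation energies grouped by bond-change count.

    The grouping key is |added| + |removed| between the perceived reactant
    and product graphs of each triad.
    """
    groups: dict[int, list[float]] = {}
    for t in triads:
        rg = perceive_bonds(t.reactant, scale=perception_scale)
        pg = perceive_bonds(t.product, scale=perception_scale)
        added, removed = graph_diff(rg, pg)
        key = len(added) + len(removed)
        groups.setdefault(key, []).append(t.barrier)
    out: dict[int, dict[str, float]] = {}
    for key in sorted(groups):
        arr = np.asarray(groups[key])
        out[key] = {
            "count": int(arr.size),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return out


def plot_distance_contrast(
    hist_rps: HistogramSummary,
    hist_nms: HistogramSummary | None = None,
    path=None,
):
    """Pairwise-distance density plot contrasting RPS and NMS datasets.

    Requires matplotlib (optional dependency); returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (hist_rps.edges[:-1] + hist_rps.edges[1:])
    body = hist_rps.densities[:-1] if hist_rps.overflow else hist_rps.densities
    ax.fill_between(centers, body, step="mid", alpha=0.6,
                    color="gold", label="RPS")
    if hist_nms is not None:
        body_n = hist_nms.densities[:-1] if hist_nms.overflow else hist_nms.densities
        ax.fill_between(centers, body_n, step="mid", alpha=0.6,
                        color="darkorange", label="NMS")
    ax.axvline(5.0, ls="--", color="gray", lw=1)
    ax.set_xlabel("pairwise distance (Å)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_activation_energies(summary: dict[int, dict[str, float]], path=None):
    """Box-style activation-energy plot per bond-change count (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
    keys = sorted(summary)
    for k in keys:
        s = summary[k]
        ax1.errorbar(
            [k], [s["median"]],
            yerr=[[s["median"] - s["q1"]], [s["q3"] - s["median"]]],
            fmt="o", color="goldenrod", capsize=4,
        )
    ax1.set_xlabel("bond changes")
    ax1.set_ylabel("activation energy (eV)")
    ax2.bar(keys, [summary[k]["count"] for k in keys], color="goldenrod")
    ax2.set_xlabel("bond changes")
    ax2.set_ylabel("reactions")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def export_histogram_csv(hist: HistogramSummary, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "count", "density"])
        dens = hist.densities
        n_body = len(hist.counts) - (1 if hist.overflow else 0)
        for i in range(n_body):
            writer.writerow([hist.edges[i], hist.edges[i + 1], int(hist.counts[i]), dens[i]])
        if hist.overflow:
            writer.writerow([hist.edges[-1], "inf", int(hist.counts[-1]), dens[-1]])
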