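"""Single-axon branch morphometry on SWC traces.

A sparsely labeled ORN axon enters the antennal lobe, extends a thick stem
axon, and sends collateral (primary) branches toward its partner PN's
dendrites.  From a rooted SWC trace plus region definitions this module
derives: the stem axon (thickest root-to-leaf path), the antennal-lobe
entry and end points, the developmental stage from stem length, one record
per primary branch (position on the entry=0 / end=1 stem axis, PN contact,
multifurcation, laterality), per-axon summary statistics, and group-level
statistical comparisons.

SWC convention: 1-based integer ids, parent -1 for the root, coordinates
and radii in micrometers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SWC trees


@dataclass
class NeuriteTree:
    """A rooted neurite trace: node ids, parent links, 3D positions, radii."""

    ids: np.ndarray          # (n,) int
    parents: np.ndarray      # (n,) int id of parent, -1 for root
    xyz: np.ndarray          # (n, 3) float, micrometers
    radius: np.ndarray       # (n,) float, micrometers

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        n = len(self.ids)
        if self.xyz.shape != (n, 3) or self.parents.shape != (n,) or self.radius.shape != (n,):
            raise ValueError("inconsistent array shapes")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate node ids")
        if np.any(self.radius <= 0):
            raise ValueError("radii must be positive")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self._id_to_idx = {int(i): k for k, i in enumerate(self.ids)}
        self._parent_idx = np.array(
            [-1 if p == -1 else self._id_to_idx[int(p)] for p in self.parents]
        )
        # reachability from the root guarantees connected + acyclic
        self._children: list[list[int]] = [[] for _ in range(n)]
        for k, p in enumerate(self._parent_idx):
            if p >= 0:
                self._children[p].append(k)
        self.root = int(roots[0])
        seen = np.zeros(n, bool)
        stack = [self.root]
        while stack:
            k = stack.pop()
            seen[k] = True
            stack.extend(self._children[k])
        if not seen.all():
            raise ValueError("tree is not connected to the root")

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: int) -> int:
        return self._id_to_idx[int(node_id)]

    def children(self, idx: int) -> list[int]:
        return self._children[idx]

    def parent_index(self, idx: int) -> int:
        return int(self._parent_idx[idx])

    def leaves(self) -> list[int]:
        return [k for k in range(self.n_nodes) if not self._children[k]]

    def edge_length(self, idx: int) -> float:
        """Length of the edge from node idx to its parent (0 for the root)."""
        p = self._parent_idx[idx]
        if p < 0:
            return 0.0
        return float(np.linalg.norm(self.xyz[idx] - self.xyz[p]))

    def path_to_root(self, idx: int) -> list[int]:
        """Node indices from the root down to idx."""
        path = [idx]
        while self._parent_idx[path[-1]] >= 0:
            path.append(int(self._parent_idx[path[-1]]))
        return path[::-1]

    def subtree_indices(self, idx: int) -> list[int]:
        """All node indices of the subtree rooted at idx (idx included)."""
        out, stack = [], [idx]
        while stack:
            k = stack.pop()
            out.append(k)
            stack.extend(self._children[k])
        return out

    @classmethod
    def from_swc(cls, path: str | Path) -> "NeuriteTree":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(parts)
        if not rows:
            raise ValueError(f"no nodes in SWC file {path}")
        arr = np.array(rows)
        return cls(
            ids=arr[:, 0].astype(int),
            parents=arr[:, 6].astype(int),
            xyz=arr[:, 2:5].astype(float),
            radius=arr[:, 5].astype(float),
        )

    def to_swc(self, path: str | Path, structure_type: int = 2) -> None:
        lines = []
        for k in range(self.n_nodes):
            x, y, z = self.xyz[k]
            lines.append(
                f"{self.ids[k]} {structure_type} {x:.4f} {y:.4f} {z:.4f} "
                f"{self.radius[k]:.4f} {self.parents[k]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regions


class Region(Protocol):
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (n, 3) array of micrometer points."""
        ...


@dataclass
class SphereRegion:
    center: np.ndarray
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.atleast_2d(points) - np.asarray(self.center), axis=1)
        return d <= self.radius


@dataclass
class BoxRegion:
    lo: np.ndarray  # inclusive lower corner, um
    hi: np.ndarray  # inclusive upper corner, um

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= np.asarray(self.lo)) & (p <= np.asarray(self.hi)), axis=1)


@dataclass
class PointCloudRegion:
    """A region given as sample points; membership = within eps of any point."""

    points: np.ndarray
    eps: float = 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        cloud = np.atleast_2d(self.points)
        d2 = ((p[:, None, :] - cloud[None, :, :]) ** 2).sum(axis=2)
        return d2.min(axis=1) <= self.eps**2


@dataclass
class MaskRegion:
    """A voxel mask region; a point is inside iff its voxel is set."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.origin)
        idx = np.floor(p / np.asarray(self.voxel_size)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.mask.shape)), axis=1)
        out = np.zeros(len(p), bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class MidlinePlane:
    """Plane through ``point`` with ``normal``; splits ipsi/contralateral."""

    point: np.ndarray
    normal: np.ndarray

    def signed_side(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (p - np.asarray(self.point)) @ np.asarray(self.normal)


@dataclass
class RegionSet:
    antennal_lobe: Region
    pn_region: Region
    midline: MidlinePlane | None = None


# ---------------------------------------------------------------------------
# Stem axon and stage


@dataclass
class StemAnnotation:
    stem_path: list[int]          # node indices root -> tip
    entry_node: int               # node index
    end_node: int                 # node index
    stem_length: float            # um, geodesic entry -> end
    stage: int | None = None

    def validate(self) -> None:
        if self.entry_node not in self.stem_path or self.end_node not in self.stem_path:
            raise AssertionError("entry/end must lie on the stem path")
        if self.stem_length < 0:
            raise AssertionError("stem length must be non-negative")


def _path_score(tree: NeuriteTree, path: Sequence[int]) -> tuple[float, float]:
    """(length-weighted mean radius, geodesic length) of a root-to-leaf path."""
    total_len = 0.0
    weighted = 0.0
    for a, b in zip(path[:-1], path[1:]):
        seg = float(np.linalg.norm(tree.xyz[b] - tree.xyz[a]))
        total_len += seg
        weighted += seg * 0.5 * (tree.radius[a] + tree.radius[b])
    if total_len == 0:
        return float(np.mean(tree.radius[list(path)])), 0.0
    return weighted / total_len, total_len


def identify_stem_axon(tree: NeuriteTree) -> list[int]:
    """Thickest root-to-leaf path: maximal path-length-weighted mean radius.

    Ties go to the geodesically longer path, then to the lexicographically
    smaller leaf id.
    """
    if tree.n_nodes < 2:
        raise ValueError("single-node tree has no stem axon")
    best = None
    best_key = None
    for leaf in tree.leaves():
        path = tree.path_to_root(leaf)
        mean_r, length = _path_score(tree, path)
        key = (-mean_r, -length, str(tree.ids[leaf]))
        if best_key is None or key < best_key:
            best_key = key
            best = path
    assert best is not None
    return best


def _arc_positions(tree: NeuriteTree, stem_path: Sequence[int]) -> np.ndarray:
    """Cumulative arc length (um) of each stem node from the root end."""
    s = np.zeros(len(stem_path))
    for i in range(1, len(stem_path)):
        s[i] = s[i - 1] + float(
            np.linalg.norm(tree.xyz[stem_path[i]] - tree.xyz[stem_path[i - 1]])
        )
    return s


def locate_entry_and_end(
    tree: NeuriteTree, stem_path: Sequence[int], regions: RegionSet
) -> StemAnnotation:
    """Find the antennal-lobe entry point and the stem end point.

    Entry = first stem node (in root-to-tip order) inside the antennal
    lobe; end = stem node geodesically farthest from the entry along the
    stem (the distal tip); stem_length is that geodesic distance.
    """
    inside = regions.antennal_lobe.contains(tree.xyz[list(stem_path)])
    if not inside.any():
        raise ValueError("stem axon does not intersect the antennal lobe region")
    entry_i = int(np.argmax(inside))
    s = _arc_positions(tree, stem_path)
    # farthest node distal to the entry (toward the tip); if the stem only
    # touches the region at its tip this degenerates to entry = end
    dist = np.where(np.arange(len(s)) >= entry_i, s - s[entry_i], -np.inf)
    end_i = int(np.argmax(dist))
    ann = StemAnnotation(
        stem_path=list(stem_path),
        entry_node=stem_path[entry_i],
        end_node=stem_path[end_i],
        stem_length=float(dist[end_i]),
    )
    ann.validate()
    return ann


def classify_stage(
    stem_length: float, thresholds: tuple[float, float] = (100.0, 170.0)
) -> int:
    """Developmental stage from stem length: <t1 -> 1, [t1, t2] -> 2, >t2 -> 3."""
    if stem_length < 0:
        raise ValueError("stem length must be >= 0")
    t1, t2 = thresholds
    if stem_length < t1:
        return 1
    if stem_length <= t2:
        return 2
    return 3


def annotate_stem(tree: NeuriteTree, regions: RegionSet) -> StemAnnotation:
    """Identify the stem, locate entry/end, and classify the stage."""
    ann = locate_entry_and_end(tree, identify_stem_axon(tree), regions)
    ann.stage = classify_stage(ann.stem_length)
    return ann


# ---------------------------------------------------------------------------
# Primary branches


@dataclass
class BranchRecord:
    branch_point_node: int        # node index on the stem
    branch_root_node: int         # first node of the collateral subtree
    normalized_position: float
    order: Literal["primary", "higher"] = "primary"
    contacts_pn: bool = False
    multifurcated: bool = False
    n_secondary: int = 0
    side: Literal["ipsilateral", "contralateral"] | None = None


def _count_secondary(tree: NeuriteTree, subtree: Sequence[int]) -> int:
    """Branch events inside a collateral subtree: sum of (children - 1)."""
    sub = set(subtree)
    n = 0
    for k in subtree:
        kids = [c for c in tree.children(k) if c in sub]
        if len(kids) > 1:
            n += len(kids) - 1
    return n


def extract_primary_branches(
    tree: NeuriteTree,
    annotation: StemAnnotation,
    regions: RegionSet,
) -> list[BranchRecord]:
    """One record per collateral subtree leaving the stem axon.

    Positions are normalized to the entry=0 / end=1 axis; branch points
    proximal to the entry point (or beyond the end point) are excluded and
    logged.  A branch contacts the PN dendrites iff any subtree node lies
    inside the PN region (a point-cloud region carries its own contact
    tolerance).  A branch is multifurcated iff its subtree contains at
    least one internal branch point.
    """
    if annotation.stem_length <= 0:
        raise ValueError("zero-length stem: normalized positions undefined")
    stem = annotation.stem_path
    stem_set = set(stem)
    s = _arc_positions(tree, stem)
    entry_pos = s[stem.index(annotation.entry_node)]
    end_pos = s[stem.index(annotation.end_node)]
    span = end_pos - entry_pos  # positive when the end is distal to entry

    entry_side = None
    if regions.midline is not None:
        entry_side = float(
            regions.midline.signed_side(tree.xyz[annotation.entry_node][None, :])[0]
        )

    records: list[BranchRecord] = []
    n_excluded = 0
    for i, node in enumerate(stem):
        for child in tree.children(node):
            if child in stem_set:
                continue
            u = (s[i] - entry_pos) / span
            if not (0.0 <= u <= 1.0):
                n_excluded += 1
                continue
            subtree = tree.subtree_indices(child)
            contact = bool(np.any(regions.pn_region.contains(tree.xyz[subtree])))
            n_sec = _count_secondary(tree, subtree)
            side = None
            if regions.midline is not None and entry_side is not None:
                bp_side = float(
                    regions.midline.signed_side(tree.xyz[node][None, :])[0]
                )
                side = (
                    "ipsilateral" if bp_side * entry_side >= 0 else "contralateral"
                )
            records.append(
                BranchRecord(
                    branch_point_node=node,
                    branch_root_node=child,
                    normalized_position=float(u),
                    contacts_pn=contact,
                    multifurcated=n_sec >= 1,
                    n_secondary=n_sec,
                    side=side,
                )
            )
    if n_excluded:
        logger.info(
            "excluded %d branch points outside the entry-end span", n_excluded
        )
    return records


# ---------------------------------------------------------------------------
# Summaries and group comparisons


def branch_statistics(
    records: Sequence[BranchRecord],
    annotation: StemAnnotation,
    bins: int = 20,
) -> dict:
    """Per-axon summary of the primary-branch records.

    ``branch_density`` is primaries per micrometer of stem;
    ``contacting_fraction`` is over all primaries;
    ``multifurcated_contacting_fraction`` is the PN-contacting fraction of
    multifurcated primaries; ``n_secondary_contacting`` totals secondary
    branches on PN-contacting primaries.  Fractions are NaN when their
    denominator is empty.
    """
    if annotation.stem_length <= 0:
        raise ValueError("non-degenerate stem required")
    n = len(records)
    contacting = [r for r in records if r.contacts_pn]
    multif = [r for r in records if r.multifurcated]
    hist, edges = np.histogram(
        [r.normalized_position for r in records], bins=bins, range=(0.0, 1.0)
    )
    return {
        "stem_length": annotation.stem_length,
        "stage": annotation.stage,
        "total_branches": n,
        "branch_density": n / annotation.stem_length,
        "contacting_fraction": len(contacting) / n if n else float("nan"),
        "multifurcated_contacting_fraction": (
            sum(r.contacts_pn for r in multif) / len(multif)
            if multif
            else float("nan")
        ),
        "n_secondary_contacting": int(sum(r.n_secondary for r in contacting)),
        "position_histogram": hist,
        "position_bin_edges": edges,
    }


def compare_groups(
    groups: dict[str, Sequence[float]] | dict[str, tuple[int, int]],
    test: Literal["anova_tukey", "chi2_bonferroni", "kruskal_bonferroni"],
) -> dict:
    """Multi-group comparison mirroring the study's statistical workflow.

    ``anova_tukey``: one-way ANOVA with Tukey HSD post hoc; Shapiro-Wilk
    normality and Brown-Forsythe homoscedasticity gates are reported.
    ``chi2_bonferroni``: pairwise 2x2 chi-squared (no continuity
    correction) on (count_contacting, count_total) per group, Bonferroni
    corrected.  ``kruskal_bonferroni``: Kruskal-Wallis with pairwise
    Mann-Whitney U post hoc, Bonferroni corrected.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    pairs = [
        (names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))
    ]
    n_pairs = len(pairs)
    report: dict = {"test": test, "groups": names, "pairwise": {}}

    if test == "chi2_bonferroni":
        for a, b in pairs:
            ca, na = groups[a]
            cb, nb = groups[b]
            table = np.array([[ca, na - ca], [cb, nb - cb]], dtype=float)
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            report["pairwise"][(a, b)] = {
                "chi2": float(chi2),
                "p": float(p),
                "p_corrected": min(1.0, float(p) * n_pairs),
            }
        return report

    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}

    if test == "anova_tukey":
        for k, v in data.items():
            if len(v) < 2:
                raise ValueError(f"group {k!r} has n < 2; ANOVA undefined")
        report["shapiro"] = {
            k: float(stats.shapiro(v).pvalue) if len(set(v)) > 1 else float("nan")
            for k, v in data.items()
        }
        report["brown_forsythe_p"] = float(
            stats.levene(*data.values(), center="median").pvalue
        )
        f, p = stats.f_oneway(*data.values())
        report["statistic"] = float(f)
        report["p"] = float(p)
        tukey = stats.tukey_hsd(*data.values())
        for i, j in [(names.index(a), names.index(b)) for a, b in pairs]:
            report["pairwise"][(names[i], names[j])] = {
                "p_corrected": float(tukey.pvalue[i, j])
            }
        return report

    if test == "kruskal_bonferroni":
        h, p = stats.kruskal(*data.values())
        report["statistic"] = float(h)
        report["p"] = float(p)
        for a, b in pairs:
            mw = stats.mannwhitneyu(data[a], data[b], alternative="two-sided")
            report["pairwise"][(a, b)] = {
                "p": float(mw.pvalue),
                "p_corrected": min(1.0, float(mw.pvalue) * n_pairs),
            }
        return report

    raise ValueError(f"unknown test {test!r}")


def summarize_axons(
    summaries: Iterable[dict], group_labels: Iterable[str]
) -> pd.DataFrame:
    """Tabulate per-axon summaries with their group label for export."""
    rows = []
    for summ, grp in zip(summaries, group_labels):
        row = {k: v for k, v in summ.items() if not isinstance(v, np.ndarray)}
        row["group"] = grp
        rows.append(row)
    return pd.DataFrame(rows)
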