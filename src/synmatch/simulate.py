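"""Seed-deterministic synthetic data with the statistical structure each stage assumes.

Three generators:

* :func:`gen_tmt_dataset` -- a six-plex TMT protein table with planted
  bait interactors (enriched over both the spatial reference and the
  negative control), generic membrane background (enriched over NC only),
  endogenously biotinylated contaminants (high in every group including
  NC), null proteins, and a bait row.  Ground-truth class labels ride
  along so filter recall/removal can be scored.
* :func:`gen_glomerular_volumes` -- paired axon/dendrite ellipsoid
  volumes with a programmed voxel overlap fraction, for the volumetric
  index pipeline.
* :func:`gen_axon_with_field` -- a branched SWC axon with
  stage-consistent stem length, planted branch positions/contacts/
  multifurcations, plus a co-registered F-actin-like intensity field with
  an optional intensity boost on PN-contact zones.

All randomness flows through a caller-supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .morpho import (
    BoxRegion,
    NeuriteTree,
    RegionSet,
    SphereRegion,
)
from .volumes import LabeledVolume

# ---------------------------------------------------------------------------
# TMT tables


@dataclass
class TmtSimConfig:
    """Planted-truth six-plex proteomics scenario.

    Effects are log2 fold changes on the contrast scale: an interactor has
    ``fc_nc_interactor`` over NC and ``fc_sr_interactor`` over SR; membrane
    background matches the interactors over NC but is flat over SR;
    endogenously biotinylated contaminants sit at ``endo_biotin_level`` in
    every group (zero fold change over NC).  Channel noise is i.i.d.
    Gaussian on the log2 scale.
    """

    n_proteins: int = 2000
    frac_interactor: float = 0.025        # 50 of 2000
    frac_membrane: float = 0.10           # 200 of 2000
    frac_endo_biotin: float = 0.05        # 100 of 2000
    fc_nc_interactor: float = 3.0
    fc_sr_interactor: float = 2.0
    fc_nc_membrane: float = 3.0
    endo_biotin_level: float = 2.0
    noise_sd: float = 0.25
    bait_id: str = "BAIT"
    bait_fc_nc: float = 1.5
    bait_fc_sr: float = 1.0
    peptide_poisson_mean: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.frac_interactor + self.frac_membrane + self.frac_endo_biotin > 1:
            raise ValueError("class fractions must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")


#: channel labels of the balanced 2/2/2 design, matching tmt.default_design()
TMT_CHANNELS = ("TRT_1", "TRT_2", "SR_1", "SR_2", "NC_1", "NC_2")


def _class_means(cfg: TmtSimConfig, cls: str) -> tuple[float, float, float]:
    """(TRT, SR, NC) group means of log2 ratios for a truth class."""
    if cls == "interactor":
        return cfg.fc_nc_interactor, cfg.fc_nc_interactor - cfg.fc_sr_interactor, 0.0
    if cls == "membrane":
        return cfg.fc_nc_membrane, cfg.fc_nc_membrane, 0.0
    if cls == "endo_biotin":
        return cfg.endo_biotin_level, cfg.endo_biotin_level, cfg.endo_biotin_level
    if cls == "bait":
        return cfg.bait_fc_nc, cfg.bait_fc_nc - cfg.bait_fc_sr, 0.0
    return 0.0, 0.0, 0.0  # null


def gen_tmt_dataset(cfg: TmtSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (quant table in precomputed log2-ratio mode, truth labels).

    The bait row is always present (it is not counted against
    ``n_proteins``); planted classes get unique-peptide counts >= 2 while
    null proteins may have a single peptide, so the peptide filter has
    something to remove.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    n_int = int(round(cfg.frac_interactor * n))
    n_mem = int(round(cfg.frac_membrane * n))
    n_endo = int(round(cfg.frac_endo_biotin * n))
    n_null = n - n_int - n_mem - n_endo
    classes = (
        ["interactor"] * n_int
        + ["membrane"] * n_mem
        + ["endo_biotin"] * n_endo
        + ["null"] * n_null
        + ["bait"]
    )

    rows = []
    truth = []
    for i, cls in enumerate(classes):
        trt, sr, nc = _class_means(cfg, cls)
        means = np.array([trt, trt, sr, sr, nc, nc])
        vals = means + rng.normal(0.0, cfg.noise_sd, size=6)
        if cls == "bait":
            pid = cfg.bait_id
            peptides = 2 + rng.poisson(cfg.peptide_poisson_mean)
        elif cls == "null":
            pid = f"P{i:05d}"
            peptides = 1 + rng.poisson(cfg.peptide_poisson_mean)
        else:
            pid = f"P{i:05d}"
            peptides = 2 + rng.poisson(cfg.peptide_poisson_mean)
        row = {
            "protein_id": pid,
            "gene_symbol": pid.lower(),
            "unique_peptides": int(peptides),
        }
        row.update(dict(zip(TMT_CHANNELS, vals)))
        rows.append(row)
        truth.append({"protein_id": pid, "truth_class": cls})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Glomerular volumes


@dataclass
class VolumeSimConfig:
    """Paired ellipsoid volumes with a programmed match overlap fraction."""

    shape: tuple[int, int, int] = (64, 64, 64)
    semi_axes: tuple[float, float, float] = (14.0, 10.0, 8.0)  # voxels
    overlap_fraction: float = 0.4        # target |A ∩ D| / |D|
    intensity_level: float = 200.0
    noise_sd: float = 10.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap fraction must lie in [0, 1]")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if 2 * self.semi_axes[0] >= self.shape[0]:
            raise ValueError("ellipsoid does not fit the grid along axis 0")


def _ellipsoid_mask(
    shape: Sequence[int], center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return acc <= 1.0


def gen_glomerular_volumes(
    cfg: VolumeSimConfig,
) -> tuple[LabeledVolume, LabeledVolume, dict]:
    """Generate axon/dendrite intensity volumes plus noiseless truth.

    The dendrite ellipsoid is fixed; the axon is a congruent ellipsoid
    shifted along axis 0, with the shift solved by bisection so the
    voxelized overlap fraction |A ∩ D| / |D| matches the programmed value.
    Truth indices are recorded from the noiseless masks.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    a0 = cfg.semi_axes[0]
    d_center = (0.35 * shape[0], shape[1] / 2.0, shape[2] / 2.0)
    dendrite = _ellipsoid_mask(shape, d_center, cfg.semi_axes)
    n_d = int(dendrite.sum())
    if n_d == 0:
        raise ValueError("degenerate dendrite ellipsoid")

    def overlap_frac(shift: float) -> tuple[float, np.ndarray]:
        axon = _ellipsoid_mask(
            shape, (d_center[0] + shift, d_center[1], d_center[2]), cfg.semi_axes
        )
        return float(np.count_nonzero(axon & dendrite)) / n_d, axon

    lo, hi = 0.0, 2.0 * a0 + 2.0
    f_target = cfg.overlap_fraction
    if f_target >= 1.0:
        shift = 0.0
    elif f_target <= 0.0:
        shift = hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f_mid, _ = overlap_frac(mid)
            if f_mid > f_target:
                lo = mid
            else:
                hi = mid
        shift = 0.5 * (lo + hi)
    _, axon = overlap_frac(shift)
    if not axon.any():
        raise ValueError("axon ellipsoid fell outside the grid")

    overlap = int(np.count_nonzero(axon & dendrite))
    truth = {
        "match_index": overlap / n_d,
        "mismatch_index": overlap / int(axon.sum()),
        "shift_vox": shift,
        "axon_mask": axon,
        "dendrite_mask": dendrite,
    }
    axon_vol = LabeledVolume(
        cfg.intensity_level * axon + rng.normal(0, cfg.noise_sd, shape),
        cfg.voxel_size,
        channel="axon",
    )
    dend_vol = LabeledVolume(
        cfg.intensity_level * dendrite + rng.normal(0, cfg.noise_sd, shape),
        cfg.voxel_size,
        channel="dendrite",
    )
    return axon_vol, dend_vol, truth


# ---------------------------------------------------------------------------
# Branched axon with an F-actin-like field


@dataclass
class AxonSimConfig:
    """A single developing ORN axon with planted branch structure.

    Stem lengths are drawn per developmental stage (stage 1 < 100 um,
    stage 2 in [100, 170], stage 3 > 170, matching the stage classifier's
    thresholds).  Primary branch counts follow a per-stage density,
    branch positions a per-stage distribution on the entry=0/end=1 axis
    (uniform early, PN-peaked later).  Each branch is independently
    PN-contacting with probability ``contact_probability`` and its
    geometry realizes the label: contacting branches are steered through
    the PN dendrite sphere, non-contacting ones away from it.  The
    intensity field paints every neurite as a tube at a baseline level
    with ``factin_boost`` added inside PN-contact zones, Gaussian-blurs
    the structure, and adds i.i.d. voxel noise.
    """

    stage: int = 3
    stem_length_range: tuple[float, float] | None = None  # default per stage
    pre_entry_length: float = 20.0
    node_spacing: float = 2.0
    branch_density: float | None = None     # primaries per um; default per stage
    position_beta: tuple[float, float] | None = None  # default per stage
    contact_probability: float = 0.7
    multifurcation_probability: float = 0.3
    pn_center_u: float = 0.65
    pn_offset: float = 16.0                  # um lateral offset of PN sphere
    pn_radius: float = 12.0                  # um
    contact_overshoot: float = 6.0           # um traveled past the PN boundary
    noncontact_length: tuple[float, float] = (8.0, 20.0)
    factin_boost: float = 0.3                # added inside contact zones
    baseline_intensity: float = 0.5
    field_noise_sd: float = 0.08
    field_voxel_size: float = 1.0            # um, isotropic
    blur_sigma_vox: float = 0.3
    tip_overpaint: float = 4.0               # um painted past every tip
    seed: int = 0

    _STAGE_LENGTHS = {1: (40.0, 95.0), 2: (105.0, 165.0), 3: (180.0, 240.0)}
    _STAGE_DENSITY = {1: 0.12, 2: 0.08, 3: 0.05}
    _STAGE_BETA = {1: (1.0, 1.0), 2: (2.5, 1.8), 3: (5.0, 2.5)}

    def validate(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        for p in (self.contact_probability, self.multifurcation_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.stem_length_range or self._STAGE_LENGTHS[self.stage]
        t1, t2 = 100.0, 170.0
        ok = (
            (self.stage == 1 and hi < t1)
            or (self.stage == 2 and lo >= t1 and hi <= t2)
            or (self.stage == 3 and lo > t2)
        )
        if not ok:
            raise ValueError("stem length range inconsistent with the stage")

    @property
    def resolved_length_range(self) -> tuple[float, float]:
        return self.stem_length_range or self._STAGE_LENGTHS[self.stage]

    @property
    def resolved_density(self) -> float:
        return self.branch_density if self.branch_density is not None else self._STAGE_DENSITY[self.stage]

    @property
    def resolved_beta(self) -> tuple[float, float]:
        return self.position_beta or self._STAGE_BETA[self.stage]


@dataclass
class SimulatedAxon:
    tree: NeuriteTree
    regions: RegionSet
    field: LabeledVolume
    field_origin: tuple[float, float, float]
    truth: dict
    truth_branches: pd.DataFrame = dc_field(default_factory=pd.DataFrame)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction")
    return v / n


class _TreeBuilder:
    """Incremental SWC tree assembly with 1-based ids."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.parents: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.radius: list[float] = []

    def add(self, pos: np.ndarray, radius: float, parent_id: int) -> int:
        nid = len(self.ids) + 1
        self.ids.append(nid)
        self.parents.append(parent_id)
        self.xyz.append(np.asarray(pos, dtype=float))
        self.radius.append(radius)
        return nid

    def build(self) -> NeuriteTree:
        return NeuriteTree(
            ids=np.array(self.ids),
            parents=np.array(self.parents),
            xyz=np.vstack(self.xyz),
            radius=np.array(self.radius),
        )


def gen_axon_with_field(cfg: AxonSimConfig) -> SimulatedAxon:
    """Generate a branched axon, its regions, an intensity field, and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ds = cfg.node_spacing

    lo, hi = cfg.resolved_length_range
    n_post = max(2, int(round(rng.uniform(lo, hi) / ds)))
    stem_length = n_post * ds  # entry -> tip arc length, exact by construction
    n_pre = max(1, int(round(cfg.pre_entry_length / ds)))

    b = _TreeBuilder()
    # pre-entry straight run along +x, root outside the antennal lobe
    pos = np.array([0.0, 0.0, 0.0])
    parent = b.add(pos, 1.0, -1)
    for _ in range(n_pre):
        pos = pos + np.array([ds, 0.0, 0.0])
        parent = b.add(pos, 1.0 + rng.normal(0, 0.03), parent)
    entry_id = parent
    entry_x = pos[0]

    # post-entry stem: +x with a smooth small-amplitude y wiggle, steps
    # renormalized so consecutive nodes are exactly ds apart in arc length
    stem_ids = [entry_id]
    phase = rng.uniform(0, 2 * np.pi)
    for i in range(n_post):
        tilt = 0.05 * np.sin(2 * np.pi * (i / n_post) * 1.5 + phase)
        step = _unit(np.array([1.0, tilt, 0.0])) * ds
        pos = pos + step
        parent = b.add(pos, 1.0 + rng.normal(0, 0.03), parent)
        stem_ids.append(parent)
    stem_xyz = np.array([b.xyz[i - 1] for i in stem_ids])

    # PN dendrite region: sphere near pn_center_u, offset laterally in +y
    pn_anchor = stem_xyz[int(round(cfg.pn_center_u * n_post))]
    pn_center = pn_anchor + np.array([0.0, cfg.pn_offset, 0.0])
    pn_region = SphereRegion(center=pn_center, radius=cfg.pn_radius)

    n_branches = rng.poisson(cfg.resolved_density * stem_length)
    a_beta, b_beta = cfg.resolved_beta
    branch_truth = []
    contact_edges: list[tuple[int, int]] = []  # ids; used for field painting
    tip_extensions: list[tuple[np.ndarray, np.ndarray]] = []  # (tip pos, dir)

    for j in range(n_branches):
        u = float(rng.beta(a_beta, b_beta))
        # keep the stem tip branch-free so it stays a leaf of the tree
        k = min(n_post - 1, max(1, int(round(u * n_post))))
        u_snap = k / n_post
        origin_id = stem_ids[k]
        origin = stem_xyz[k]
        contacting = bool(rng.random() < cfg.contact_probability)
        r_branch = 0.3 + rng.normal(0, 0.02)

        if contacting:
            # steer at a random interior point of the PN sphere rather than
            # its center, so contacting branches do not converge on one spot
            while True:
                jitter = rng.uniform(-1, 1, 3)
                if np.linalg.norm(jitter) <= 1:
                    break
            target = pn_center + 0.6 * cfg.pn_radius * jitter
            to_target = target - origin
            dist = np.linalg.norm(to_target)
            direction = _unit(to_target)
            # run through the target and slightly beyond; the target sits at
            # least 0.4 * pn_radius inside the sphere, so contact is realized
            length = dist + ds
        else:
            away = np.array([0.0, -1.0, 0.0]) + rng.normal(0, 0.15, 3)
            away[1] = min(away[1], -0.5)
            direction = _unit(away)
            length = rng.uniform(*cfg.noncontact_length)

        n_seg = max(1, int(round(length / ds)))
        bp = origin
        bparent = origin_id
        branch_node_ids = []
        for _ in range(n_seg):
            bp = bp + direction * ds
            bparent = b.add(bp, max(0.05, r_branch), bparent)
            branch_node_ids.append(bparent)
        tip_extensions.append((bp, direction))

        multif = bool(rng.random() < cfg.multifurcation_probability) and n_seg >= 2
        if multif:
            # attach to a non-terminal branch node so the split is internal
            mid = branch_node_ids[min(n_seg // 2, n_seg - 2)]
            mid_pos = b.xyz[mid - 1]
            zdir = np.array([0.0, 0.0, rng.choice([-1.0, 1.0])])
            sp = mid_pos
            sparent = mid
            for _ in range(3):
                sp = sp + zdir * ds
                sparent = b.add(sp, 0.2, sparent)
            tip_extensions.append((sp, zdir))

        branch_truth.append(
            {
                "branch_index": j,
                "normalized_position": u_snap,
                "contacting": contacting,
                "multifurcated": multif,
                "n_secondary": 1 if multif else 0,
                "branch_root_id": branch_node_ids[0],
            }
        )

    tree = b.build()
    antennal_lobe = BoxRegion(
        lo=np.array([entry_x - 1e-6, -1e6, -1e6]), hi=np.array([1e6, 1e6, 1e6])
    )
    regions = RegionSet(antennal_lobe=antennal_lobe, pn_region=pn_region)

    field, origin_um = _paint_field(tree, pn_region, tip_extensions, cfg, rng)
    truth = {
        "stage": cfg.stage,
        "stem_length": stem_length,
        "entry_id": int(entry_id),
        "end_id": int(stem_ids[-1]),
        "stem_ids": [int(i) for i in stem_ids],
        "n_branches": n_branches,
    }
    return SimulatedAxon(
        tree=tree,
        regions=regions,
        field=field,
        field_origin=origin_um,
        truth=truth,
        truth_branches=pd.DataFrame(branch_truth),
    )


def _paint_field(
    tree: NeuriteTree,
    pn_region: SphereRegion,
    tip_extensions: list[tuple[np.ndarray, np.ndarray]],
    cfg: AxonSimConfig,
    rng: np.random.Generator,
) -> tuple[LabeledVolume, tuple[float, float, float]]:
    """Rasterize the neurite as a tube, boost contact zones, blur, add noise.

    Painting extends a short distance past every tip so that sampled trace
    nodes always sit in a locally tube-like neighborhood (the trace ends
    where tracing stopped, not where the neurite does); without this, blur
    would systematically dim terminal nodes.
    """
    vs = cfg.field_voxel_size
    margin = 8.0
    lo = tree.xyz.min(axis=0) - margin
    hi = tree.xyz.max(axis=0) + margin
    shape = tuple(np.ceil((hi - lo) / vs).astype(int) + 1)
    vol = np.zeros(shape, dtype=np.float32)

    # collect paint points: dense samples along every edge + tip overhangs
    pts = []
    vals = []
    step = vs / 2.0
    for k in range(tree.n_nodes):
        p = tree.parent_index(k)
        if p < 0:
            continue
        a, c = tree.xyz[p], tree.xyz[k]
        seg = np.linalg.norm(c - a)
        n = max(2, int(np.ceil(seg / step)) + 1)
        for t in np.linspace(0.0, 1.0, n):
            pts.append(a + t * (c - a))
    for tip, direction in tip_extensions:
        n = max(2, int(np.ceil(cfg.tip_overpaint / step)) + 1)
        for t in np.linspace(0.0, 1.0, n):
            pts.append(tip + t * cfg.tip_overpaint * direction)
    pts_arr = np.array(pts)
    in_zone = pn_region.contains(pts_arr) if cfg.factin_boost != 0 else np.zeros(len(pts), bool)
    vals = cfg.baseline_intensity + cfg.factin_boost * in_zone

    idx = np.floor((pts_arr - lo) / vs).astype(int)
    offs = np.array(
        [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for off in offs:
        q = idx + off
        ok = np.all((q >= 0) & (q < np.array(shape)), axis=1)
        qq = q[ok]
        np.maximum.at(vol, (qq[:, 0], qq[:, 1], qq[:, 2]), vals[ok].astype(np.float32))

    if cfg.blur_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, cfg.blur_sigma_vox)
    vol = vol + rng.normal(0.0, cfg.field_noise_sd, shape).astype(np.float32)
    field = LabeledVolume(vol, (vs, vs, vs), channel="factin")
    return field, tuple(lo)
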