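"""Peptide-lipid contact statistics from coarse membrane trajectories.

The quantities computed here characterise how a membrane-binding peptide
engages a phospholipid leaflet, frame by frame:

* ``contact_matrix`` -- which residues are within a cutoff (default 0.7 nm)
  of which lipid molecules, under minimum-image periodicity in the membrane
  plane (x, y); the membrane normal z is not periodic (slab geometry).
* ``occupancy`` -- O_ij, the fraction of frames in which residue j touches
  any lipid of class i (DOPC or DOPA), and the class-averaged <O>_j.
* ``delta_occupancy`` -- the monolayer-minus-bilayer difference d<O>_j in
  percent, with the convention that residues are reported only when their
  occupancy exceeds 5% in at least one system.
* ``lipid_fraction`` -- L_f = L_n / N per frame, where N residues of a group
  contact L_n distinct lipids (DOPC, DOPA or TG), and its distribution
  P(L_f).
* ``area_per_lipid`` / ``membrane_thickness`` -- leaflet packing metrics.
* ``backbone_rmsd`` -- least-squares (Kabsch) superposed RMSD series.
* ``ss_content`` -- per-class secondary-structure fractions from consumed
  per-frame assignments.

Contacts never distinguish headgroup from tail sites: every site of a lipid
molecule counts toward that molecule's contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryFrame",
    "OccupancyTable",
    "LipidFractionSeries",
    "contact_matrix",
    "contact_pairs_bruteforce",
    "occupancy",
    "delta_occupancy",
    "lipid_fraction",
    "area_per_lipid",
    "membrane_thickness",
    "backbone_rmsd",
    "kabsch",
    "ss_content",
]

PHOSPHOLIPID_CLASSES = ("DOPC", "DOPA")
LIPID_KINDS = ("lipid", "tg")


@dataclass
class TrajectoryFrame:
    """One frame: per-particle kind/index/class/leaflet labels + positions (nm)."""

    index: int
    box: tuple[float, float, float]
    kind: np.ndarray  # 'residue' | 'lipid' | 'tg'
    label: np.ndarray  # residue index j or lipid molecule index i (per kind)
    klass: np.ndarray  # 'PEP' | 'DOPC' | 'DOPA' | 'TG'
    leaflet: np.ndarray  # 'upper' | 'lower' | 'na'
    xyz: np.ndarray  # (n, 3)

    def __post_init__(self):
        if any(b <= 0 for b in self.box):
            raise ValueError(f"box lengths must be positive, got {self.box}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("positions must be finite")

    def residues(self):
        """(sorted residue labels, positions) of peptide sites."""
        m = self.kind == "residue"
        return self._grouped(self.label[m], self.xyz[m])

    def lipids(self, classes: tuple[str, ...] | None = None):
        """(molecule keys, site positions, class per molecule) of lipid sites.

        Molecule identity is (kind, index): indices are unique within a kind.
        """
        m = np.isin(self.kind, LIPID_KINDS)
        if classes is not None:
            m &= np.isin(self.klass, classes)
        keys = list(zip(self.kind[m], self.label[m]))
        return keys, self.xyz[m], self.klass[m]

    @staticmethod
    def _grouped(labels, xyz):
        order = np.argsort(labels, kind="stable")
        return labels[order], xyz[order]


@dataclass
class OccupancyTable:
    """Per-residue occupancies for one system (monolayer or bilayer)."""

    system: str
    cutoff: float
    table: pd.DataFrame  # residue, O_DOPC, O_DOPA, O_mean, O_any (fractions)


@dataclass
class LipidFractionSeries:
    group: tuple[int, ...]
    cutoff: float
    per_frame: pd.DataFrame  # frame, N, L_n, L_f (NaN when N == 0)
    bin_edges: np.ndarray
    probability: np.ndarray  # sums to 1 over defined frames


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------


def _min_image_d2(dx, dy, dz, Lx, Ly):
    dx = dx - Lx * np.round(dx / Lx)
    dy = dy - Ly * np.round(dy / Ly)
    return dx * dx + dy * dy + dz * dz


def contact_pairs_bruteforce(frame: TrajectoryFrame, cutoff: float) -> set:
    """All-pairs reference: {(residue j, (kind, lipid index))} within cutoff.

    Quadratic in particle count; used as the independent check on the
    binned implementation.
    """
    Lx, Ly, _ = frame.box
    res_lab, res_xyz = frame.residues()
    keys, lip_xyz, _ = frame.lipids()
    pairs = set()
    c2 = cutoff * cutoff
    for j, rp in zip(res_lab, res_xyz):
        d2 = _min_image_d2(
            lip_xyz[:, 0] - rp[0], lip_xyz[:, 1] - rp[1], lip_xyz[:, 2] - rp[2],
            Lx, Ly,
        )
        for k in np.flatnonzero(d2 <= c2):
            pairs.add((int(j), keys[k]))
    return pairs


def contact_matrix(
    frame: TrajectoryFrame, cutoff: float = 0.7
) -> tuple[np.ndarray, list, np.ndarray]:
    """Boolean residue x lipid contact matrix via spatial binning.

    Entry (j, i) is true iff the minimum-image distance (periodic in x and y
    only) between any site of residue j and any site of lipid molecule i is
    at most ``cutoff``. Returns ``(residue_labels, lipid_keys, matrix)``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    Lx, Ly, _ = frame.box
    res_lab, res_xyz = frame.residues()
    keys, lip_xyz, _ = frame.lipids()
    res_ids = np.unique(res_lab)
    uniq_keys = sorted(set(keys))
    mat = np.zeros((len(res_ids), len(uniq_keys)), dtype=bool)
    if len(res_ids) == 0 or len(uniq_keys) == 0:
        return res_ids, uniq_keys, mat

    ridx = {int(j): a for a, j in enumerate(res_ids)}
    kidx = {k: a for a, k in enumerate(uniq_keys)}

    # cell lists: in-plane cells of edge >= cutoff (wrapped), z binned freely
    nx = max(1, int(Lx // cutoff))
    ny = max(1, int(Ly // cutoff))
    z0 = min(lip_xyz[:, 2].min(), res_xyz[:, 2].min())
    lx, ly = Lx / nx, Ly / ny

    def cell_of(p):
        return (
            int(p[0] % Lx // lx) % nx,
            int(p[1] % Ly // ly) % ny,
            int((p[2] - z0) // cutoff),
        )

    bins: dict[tuple[int, int, int], list[int]] = {}
    for k, p in enumerate(lip_xyz):
        bins.setdefault(cell_of(p), []).append(k)

    c2 = cutoff * cutoff
    for j, rp in zip(res_lab, res_xyz):
        cx, cy, cz = cell_of(rp)
        cand = []
        for ddx in (-1, 0, 1):
            for ddy in (-1, 0, 1):
                for ddz in (-1, 0, 1):
                    cand.extend(bins.get(((cx + ddx) % nx, (cy + ddy) % ny, cz + ddz), ()))
        if not cand:
            continue
        q = lip_xyz[cand]
        d2 = _min_image_d2(q[:, 0] - rp[0], q[:, 1] - rp[1], q[:, 2] - rp[2], Lx, Ly)
        for k in np.asarray(cand)[d2 <= c2]:
            mat[ridx[int(j)], kidx[keys[k]]] = True
    return res_ids, uniq_keys, mat


# ---------------------------------------------------------------------------
# occupancy statistics
# ---------------------------------------------------------------------------


def occupancy(
    frames: list[TrajectoryFrame], cutoff: float = 0.7, system: str = "system"
) -> OccupancyTable:
    """Time-fraction occupancy of each residue by each phospholipid class.

    O_ij counts a frame when any lipid of class i has any site within the
    cutoff of residue j; frames are weighted equally. <O>_j is the
    unweighted mean of the DOPC and DOPA occupancies; O_any is the fraction
    of frames with a contact to either class (used for parameter recovery
    against generator truth).
    """
    if not frames:
        raise ValueError("occupancy requires at least one frame")
    counts: dict[str, np.ndarray] = {}
    any_count = None
    res_ids = None
    for fr in frames:
        rl, keys, mat = contact_matrix(fr, cutoff)
        if res_ids is None:
            res_ids = rl
            counts = {c: np.zeros(len(rl)) for c in PHOSPHOLIPID_CLASSES}
            any_count = np.zeros(len(rl))
        elif not np.array_equal(res_ids, rl):
            raise ValueError("residue indexing differs between frames")
        cls_by_col = _classes_for_keys(fr, keys)
        any_pl = np.zeros(len(rl), dtype=bool)
        for c in PHOSPHOLIPID_CLASSES:
            cols = cls_by_col == c
            hit = mat[:, cols].any(axis=1)
            counts[c] += hit
            any_pl |= hit
        any_count += any_pl
    n = len(frames)
    o_pc = counts["DOPC"] / n
    o_pa = counts["DOPA"] / n
    table = pd.DataFrame(
        dict(
            residue=res_ids,
            O_DOPC=o_pc,
            O_DOPA=o_pa,
            O_mean=(o_pc + o_pa) / 2.0,
            O_any=any_count / n,
        )
    )
    return OccupancyTable(system=system, cutoff=cutoff, table=table)


def _classes_for_keys(frame: TrajectoryFrame, keys: list) -> np.ndarray:
    all_keys, _, all_cls = frame.lipids()
    lookup = dict(zip(all_keys, all_cls))
    return np.array([lookup[k] for k in keys], dtype=object)


def delta_occupancy(
    mono: OccupancyTable, bi: OccupancyTable, report_threshold: float = 5.0
) -> pd.DataFrame:
    """Monolayer-minus-bilayer occupancy difference per residue, in percent.

    Positive values favour the monolayer. ``reported`` is true only when the
    residue's class-averaged occupancy exceeds ``report_threshold`` percent
    in at least one of the two systems. The returned frame carries summary
    means over reported monolayer-favouring (delta > 0) and
    bilayer-favouring (delta < 0) residues in ``attrs``.
    """
    mt, bt = mono.table, bi.table
    if not np.array_equal(mt["residue"].to_numpy(), bt["residue"].to_numpy()):
        only_m = sorted(set(mt["residue"]) - set(bt["residue"]))
        only_b = sorted(set(bt["residue"]) - set(mt["residue"]))
        raise ValueError(
            f"residue sets disagree: only in monolayer {only_m}, only in bilayer {only_b}"
        )
    delta_pct = 100.0 * (mt["O_mean"].to_numpy() - bt["O_mean"].to_numpy())
    max_pct = 100.0 * np.maximum(mt["O_mean"].to_numpy(), bt["O_mean"].to_numpy())
    out = pd.DataFrame(
        dict(residue=mt["residue"], delta_pct=delta_pct,
             reported=max_pct > report_threshold)
    )
    rep = out[out["reported"]]
    fav_mono = rep.loc[rep["delta_pct"] > 0, "delta_pct"]
    fav_bi = rep.loc[rep["delta_pct"] < 0, "delta_pct"]
    out.attrs["mean_monolayer_favoring_pct"] = (
        float(fav_mono.mean()) if len(fav_mono) else np.nan
    )
    out.attrs["mean_bilayer_favoring_pct"] = (
        float(-fav_bi.mean()) if len(fav_bi) else np.nan
    )
    return out


def lipid_fraction(
    frames: list[TrajectoryFrame],
    group: set[int] | list[int],
    cutoff: float = 0.7,
    classes: tuple[str, ...] = ("DOPC", "DOPA", "TG"),
    fixed_group_size: bool = False,
    bins: int = 20,
) -> LipidFractionSeries:
    """Distinct lipids per contacting residue of a residue group, per frame.

    N is the number of group residues with at least one lipid contact that
    frame (or the full group size when ``fixed_group_size``); L_n the number
    of distinct lipid molecules (of the included classes) contacted by the
    group. Frames with N = 0 are undefined and excluded from P(L_f).
    """
    group = sorted(set(int(j) for j in group))
    if not group:
        raise ValueError("residue group must be nonempty")
    rows = []
    for fr in frames:
        rl, keys, mat = contact_matrix(fr, cutoff)
        cls = _classes_for_keys(fr, keys)
        keep_cols = np.isin(cls, classes)
        sel = np.isin(rl, group)
        sub = mat[np.ix_(sel, keep_cols)]
        contacting = sub.any(axis=1)
        n_res = len(group) if fixed_group_size else int(contacting.sum())
        l_n = int(sub.any(axis=0).sum())
        lf = l_n / n_res if n_res > 0 else np.nan
        rows.append(dict(frame=fr.index, N=n_res, L_n=l_n, L_f=lf))
    per_frame = pd.DataFrame(rows)
    defined = per_frame["L_f"].dropna().to_numpy()
    if defined.size == 0:
        warnings.warn("no frame had a contacting group residue; P(L_f) is empty",
                      stacklevel=2)
        edges = np.linspace(0, 1, bins + 1)
        prob = np.zeros(bins)
    else:
        hi = max(1.0, float(defined.max()))
        edges = np.linspace(0.0, hi, bins + 1)
        hist, edges = np.histogram(defined, bins=edges)
        prob = hist / hist.sum()
    return LipidFractionSeries(
        group=tuple(group), cutoff=cutoff, per_frame=per_frame,
        bin_edges=edges, probability=prob,
    )


# ---------------------------------------------------------------------------
# membrane metrics
# ---------------------------------------------------------------------------


def area_per_lipid(frame: TrajectoryFrame, leaflet: str = "upper") -> float:
    """In-plane box area divided by the leaflet's phospholipid count (nm^2)."""
    m = (
        (frame.kind == "lipid")
        & (frame.leaflet == leaflet)
        & np.isin(frame.klass, PHOSPHOLIPID_CLASSES)
    )
    n = int(m.sum())
    if n == 0:
        raise ValueError(f"leaflet {leaflet!r} contains no phospholipids")
    return frame.box[0] * frame.box[1] / n


def membrane_thickness(frame: TrajectoryFrame) -> float:
    """Mean z of upper-leaflet reference sites minus mean z of lower (nm)."""
    pl = (frame.kind == "lipid") & np.isin(frame.klass, PHOSPHOLIPID_CLASSES)
    up = pl & (frame.leaflet == "upper")
    lo = pl & (frame.leaflet == "lower")
    if not up.any() or not lo.any():
        missing = "upper" if not up.any() else "lower"
        raise ValueError(f"missing {missing} leaflet reference sites")
    return float(frame.xyz[up, 2].mean() - frame.xyz[lo, 2].mean())


def metrics_series(frames: list[TrajectoryFrame], leaflet: str = "upper") -> pd.DataFrame:
    """Per-frame APL and thickness, for mean +/- SD summaries."""
    return pd.DataFrame(
        dict(
            frame=[f.index for f in frames],
            apl=[area_per_lipid(f, leaflet) for f in frames],
            thickness=[membrane_thickness(f) for f in frames],
        )
    )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates. Standard SVD solution with
    the determinant correction that excludes reflections.
    """
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    H = mc.T @ tc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return mc @ R.T + target.mean(axis=0)


def _residue_coords(frame: TrajectoryFrame) -> tuple[np.ndarray, np.ndarray]:
    lab, xyz = frame.residues()
    return lab, xyz


def backbone_rmsd(
    frames: list[TrajectoryFrame],
    reference: TrajectoryFrame | None = None,
    fit: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD (nm) of peptide sites against a reference frame.

    With ``fit`` the optimal rotation+translation is removed first, so rigid
    motion yields zero. The reference defaults to the first frame.
    """
    if not frames:
        raise ValueError("backbone_rmsd requires at least one frame")
    ref = frames[0] if reference is None else reference
    ref_lab, ref_xyz = _residue_coords(ref)
    if fit and len(ref_lab) < 3:
        raise ValueError("superposition needs at least 3 residues")
    rows = []
    for fr in frames:
        lab, xyz = _residue_coords(fr)
        if not np.array_equal(lab, ref_lab):
            raise ValueError(
                f"frame {fr.index} residues do not match the reference"
            )
        coords = kabsch(xyz, ref_xyz) if fit else xyz
        rmsd = float(np.sqrt(np.mean(np.sum((coords - ref_xyz) ** 2, axis=1))))
        rows.append(dict(frame=fr.index, rmsd=rmsd))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# secondary structure bookkeeping
# ---------------------------------------------------------------------------

SS_CLASSES = ("helix", "sheet", "turn", "coil")


def ss_content(assignments) -> pd.DataFrame:
    """Mean per-class fraction from per-frame, per-residue labels.

    ``assignments`` is any rectangular (n_frames, n_residues) array of labels
    drawn from helix/sheet/turn/coil. Fractions sum to 1 per frame and on
    average. Assignments are consumed, never computed, here.
    """
    arr = np.asarray(assignments, dtype=object)
    if arr.ndim != 2:
        raise ValueError("assignments must be rectangular (frames x residues)")
    unknown = set(arr.ravel()) - set(SS_CLASSES)
    if unknown:
        raise ValueError(f"unknown secondary-structure label(s): {sorted(unknown)}")
    n_frames, n_res = arr.shape
    rows = {c: (arr == c).sum(axis=1) / n_res for c in SS_CLASSES}
    per_frame = pd.DataFrame(rows)
    out = per_frame.mean().to_frame(name="fraction").reset_index(names="ss_class")
    out.attrs["per_frame"] = per_frame
    return out
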