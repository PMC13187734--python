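"""Synthetic fixtures with recorded ground truth.

Every generator in this module is a pure function of its parameter block and
the seed it carries: the same parameters produce bit-identical images, frames
and tables. Each generator returns, alongside the raw data, a ground-truth
object sufficient to score the downstream measurement without re-deriving any
geometry.

The four generators emulate the four experimental data classes the suite
quantifies:

* ``gen_cell_scene``  -- multichannel fields of hepatoma-like cells with
  nuclei and lipid droplets placed at a controlled radial dispersal.
* ``gen_bead_scene``  -- before/after fluorescence fields of bead-supported
  lipid monolayers/bilayers (rings), encoding a known retention ratio.
* ``gen_trajectory`` -- coarse single-bead frames of a membrane-bound peptide
  over a 95:5 DOPC:DOPA leaflet (optionally with a triglyceride slab), with
  per-residue contact probabilities as ground truth.
* ``gen_tracks``     -- correlated-random-walk larval swim tracks with stop
  events, confined to a circular arena.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CellSceneParams",
    "BeadSceneParams",
    "TrajectoryParams",
    "TrackParams",
    "CellScene",
    "BeadScene",
    "gen_cell_scene",
    "gen_bead_scene",
    "gen_trajectory",
    "gen_tracks",
    "write_cell_scene",
    "write_bead_scene",
]

# Physical floor for leaflet packing: a phospholipid cannot occupy less
# in-plane area than roughly 0.55 nm^2 in a fluid membrane.
_MIN_AREA_PER_LIPID = 0.55


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSceneParams:
    """Controls for the multichannel cell/droplet image generator."""

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 3
    cell_radius: float = 70.0
    nucleus_radius: float = 22.0
    n_droplets_per_cell: int = 30
    dispersal_target: float = 0.8
    droplet_radius: float = 3.0
    channel_noise_sd: float = 0.0
    elongation: float = 1.0  # axis ratio; 1.0 keeps cells circular
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.dispersal_target <= 1.0):
            raise ValueError(
                f"dispersal_target must lie in [0, 1], got {self.dispersal_target}"
            )
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError(
                "nucleus_radius must be smaller than cell_radius "
                f"({self.nucleus_radius} >= {self.cell_radius})"
            )
        gap = self.cell_radius - self.nucleus_radius
        if gap < 2 * self.droplet_radius:
            raise ValueError(
                "droplet_radius too large: a droplet of radius "
                f"{self.droplet_radius} px cannot fit between the nucleus "
                f"(r={self.nucleus_radius}) and the cell boundary "
                f"(R={self.cell_radius})"
            )
        if self.n_cells < 1 or self.n_droplets_per_cell < 0:
            raise ValueError("n_cells must be >= 1 and n_droplets_per_cell >= 0")


@dataclass(frozen=True)
class BeadSceneParams:
    """Controls for the bead-supported-membrane ring image generator."""

    n_beads: int = 20
    image_size: tuple[int, int] = (512, 512)
    bead_radius_px: float = 15.0
    ring_width: float = 3.0
    bilayer_intensity: float = 200.0
    monolayer_intensity: float = 100.0  # one leaflet: half the bilayer signal
    membrane_kind: str = "monolayer"  # which intensity the scene uses
    retention_true: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.retention_true <= 1.0):
            raise ValueError(
                f"retention_true must lie in (0, 1], got {self.retention_true}"
            )
        if self.membrane_kind not in ("monolayer", "bilayer"):
            raise ValueError(f"unknown membrane_kind {self.membrane_kind!r}")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")

    @property
    def ring_intensity(self) -> float:
        if self.membrane_kind == "monolayer":
            return self.monolayer_intensity
        return self.bilayer_intensity


@dataclass(frozen=True)
class TrajectoryParams:
    """Controls for the coarse peptide/leaflet trajectory generator.

    Residues and lipids are single interaction sites. The peptide hovers one
    nanometre above the upper leaflet; when residue ``j`` draws a contact for
    a frame (Bernoulli with ``contact_prob[j]``), its designated partner
    phospholipid is moved to within the 0.7 nm contact shell of that residue.
    """

    n_frames: int = 200
    n_residues: int = 110  # tail-domain peptide span, aa 854-963
    n_lipids_per_leaflet: int = 200
    pc_fraction: float = 0.95
    pa_fraction: float = 0.05
    tg_slab_thickness: float = 3.0  # nm; used only when monolayer=True
    monolayer: bool = False
    monolayer_apl_factor: float = 1.08  # looser packing from TG interdigitation
    n_tg: int = 60
    box: tuple[float, float, float] = (18.0, 18.0, 12.0)
    contact_prob: np.ndarray | None = None  # length n_residues, in [0, 1]
    contact_offset: float = 0.5  # nm below a residue when in contact
    seed: int = 0

    def resolved_contact_prob(self) -> np.ndarray:
        if self.contact_prob is None:
            return np.zeros(self.n_residues)
        p = np.asarray(self.contact_prob, dtype=float)
        if p.shape != (self.n_residues,):
            raise ValueError(
                f"contact_prob must have length n_residues={self.n_residues}, "
                f"got shape {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("contact_prob entries must lie in [0, 1]")
        return p

    def validate(self) -> None:
        if not np.isclose(self.pc_fraction + self.pa_fraction, 1.0):
            raise ValueError(
                "pc_fraction + pa_fraction must equal 1 for the phospholipids"
            )
        area = self.box[0] * self.box[1]
        if area / max(self.n_lipids_per_leaflet, 1) < _MIN_AREA_PER_LIPID:
            raise ValueError(
                f"box {self.box[0]}x{self.box[1]} nm cannot hold "
                f"{self.n_lipids_per_leaflet} lipids per leaflet at a physical "
                f"area per lipid (>= {_MIN_AREA_PER_LIPID} nm^2)"
            )
        if self.n_lipids_per_leaflet < self.n_residues:
            raise ValueError(
                "need at least one partner lipid per residue: "
                f"n_lipids_per_leaflet={self.n_lipids_per_leaflet} < "
                f"n_residues={self.n_residues}"
            )
        self.resolved_contact_prob()


@dataclass(frozen=True)
class TrackParams:
    """Controls for the larval swim-track generator."""

    n_larvae: int = 10
    dt: float = 0.2  # s
    duration: float = 360.0  # s; motion tracked over 6 min
    speed_mean: float = 10.0  # px/s
    turn_sd: float = 0.3  # rad per step
    stop_prob: float = 0.01  # per-step probability of entering a stop
    stop_duration: float = 1.0  # s spent immobile per stop event
    arena_radius: float = 400.0  # px
    straight: bool = False  # disable turning and stops (analytic truth)
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.arena_radius <= 0:
            raise ValueError("arena_radius must be positive")
        if self.duration <= 0 or self.n_larvae < 1:
            raise ValueError("duration must be positive and n_larvae >= 1")


# ---------------------------------------------------------------------------
# cell scenes
# ---------------------------------------------------------------------------

@dataclass
class CellScene:
    """A generated multichannel field plus its ground truth."""

    image: np.ndarray  # (3, H, W): nucleus, cell, droplet channels
    channel_roles: dict[str, int]
    cell_labels: np.ndarray  # (H, W) int; 0 = background
    nucleus_labels: np.ndarray
    cells: pd.DataFrame  # cell_id, row, col, cell_radius_row/col, nucleus_radius
    droplets: pd.DataFrame  # droplet_id, cell_id, row, col, radius, d_f_true
    params: CellSceneParams = field(repr=False, default=None)


def _sample_fractions(rng: np.random.Generator, target: float, n: int) -> np.ndarray:
    """Radial fractions with mean exactly ``target``.

    A Beta(nu*t, nu*(1-t)) draw keeps the mean on target with realistic
    cell-to-cell spread; the extremes 0 and 1 are returned exactly.
    """
    if target <= 0.0:
        return np.zeros(n)
    if target >= 1.0:
        return np.ones(n)
    nu = 40.0
    return rng.beta(nu * target, nu * (1.0 - target), size=n)


def _disk_mask(shape, center, r_row, r_col=None) -> np.ndarray:
    r_col = r_row if r_col is None else r_col
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / r_row) ** 2 + ((cc - center[1]) / r_col) ** 2 <= 1.0


def gen_cell_scene(params: CellSceneParams) -> CellScene:
    """Render cells with nuclei and droplets at a controlled dispersal.

    Droplet centroids are placed at radius ``r_n + f (R - r_n)`` from the cell
    centre, where ``f`` is the sampled radial fraction recorded as the true
    per-droplet dispersal value. The drawn droplet disk is clipped to the
    cell mask, so a fraction of 1 paints a droplet centred on the boundary.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.image_size
    R = params.cell_radius
    r_n = params.nucleus_radius

    # non-overlapping cell centres by rejection sampling
    centers: list[tuple[float, float]] = []
    margin = R * max(params.elongation, 1.0) + 2
    if 2 * margin >= min(H, W):
        raise ValueError("image_size too small for cell_radius")
    attempts = 0
    while len(centers) < params.n_cells:
        cand = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2.05 * margin for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place n_cells={params.n_cells} non-overlapping cells "
                "in image_size; enlarge the field or reduce cell_radius"
            )

    nucleus_ch = np.zeros((H, W), dtype=float)
    cell_ch = np.zeros((H, W), dtype=float)
    droplet_ch = np.zeros((H, W), dtype=float)
    cell_labels = np.zeros((H, W), dtype=np.int32)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)

    elong = params.elongation
    cell_rows, droplet_rows = [], []
    droplet_id = 0
    for cid, (cy, cx) in enumerate(centers, start=1):
        cmask = _disk_mask((H, W), (cy, cx), R, R * elong)
        nmask = _disk_mask((H, W), (cy, cx), r_n, r_n * elong)
        cell_ch[cmask] = 120.0
        nucleus_ch[nmask] = 200.0
        cell_labels[cmask] = cid
        nucleus_labels[nmask] = cid
        cell_rows.append(
            dict(cell_id=cid, row=cy, col=cx, cell_radius_row=R,
                 cell_radius_col=R * elong, nucleus_radius=r_n)
        )

        fracs = _sample_fractions(rng, params.dispersal_target, params.n_droplets_per_cell)
        thetas = rng.uniform(0, 2 * np.pi, size=params.n_droplets_per_cell)
        for f, th in zip(fracs, thetas):
            droplet_id += 1
            rho = r_n + f * (R - r_n)
            dy = cy + rho * np.sin(th)
            dx = cx + rho * np.cos(th) * elong
            dmask = _disk_mask((H, W), (dy, dx), params.droplet_radius) & cmask
            droplet_ch[dmask] = np.maximum(droplet_ch[dmask], 255.0)
            droplet_rows.append(
                dict(droplet_id=droplet_id, cell_id=cid, row=dy, col=dx,
                     radius=params.droplet_radius, d_f_true=float(f))
            )

    image = np.stack([nucleus_ch, cell_ch, droplet_ch])
    if params.channel_noise_sd > 0:
        image = image + rng.normal(0.0, params.channel_noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)

    return CellScene(
        image=image,
        channel_roles={"nucleus": 0, "cell": 1, "droplet": 2},
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        cells=pd.DataFrame(cell_rows),
        droplets=pd.DataFrame(droplet_rows),
        params=params,
    )


def write_cell_scene(scene: CellScene, outdir: str | Path) -> None:
    """Multi-page TIFF (one page per channel) + JSON channel map + truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "scene.tif", scene.image.astype(np.float32))
    (outdir / "channels.json").write_text(json.dumps(scene.channel_roles, indent=1))
    scene.cells.to_csv(outdir / "truth_cells.csv", index=False)
    scene.droplets.to_csv(outdir / "truth_droplets.csv", index=False)


# ---------------------------------------------------------------------------
# bead scenes
# ---------------------------------------------------------------------------

@dataclass
class BeadScene:
    before: np.ndarray
    after: np.ndarray
    truth: pd.DataFrame  # bead_id, row, col, radius, ring_before, ring_after
    params: BeadSceneParams = field(repr=False, default=None)


def _paint_rings(shape, truth: pd.DataFrame, column: str) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    rr, cc = np.indices(shape)
    for rec in truth.itertuples():
        d = np.hypot(rr - rec.row, cc - rec.col)
        ring = np.abs(d - rec.radius) <= rec.halfwidth
        img[ring] = getattr(rec, column)
    return img


def gen_bead_scene(params: BeadSceneParams) -> BeadScene:
    """Paired before/after fields of fluorescent membrane rings.

    The after-ring intensity is ``retention_true`` times the before-ring
    intensity for every bead, mirroring motor retention after peptide
    treatment; independent truncated-Gaussian noise is added to each field.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.image_size
    r = params.bead_radius_px
    halfwidth = params.ring_width / 2.0
    margin = r + params.ring_width + 4

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_beads:
        cand = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2 * margin + 2 for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place n_beads={params.n_beads} non-overlapping beads; "
                "enlarge image_size or reduce bead_radius_px"
            )

    base = params.ring_intensity
    truth = pd.DataFrame(
        dict(
            bead_id=np.arange(1, params.n_beads + 1),
            row=[c[0] for c in centers],
            col=[c[1] for c in centers],
            radius=r,
            halfwidth=halfwidth,
            ring_before=base,
            ring_after=base * params.retention_true,
        )
    )
    before = _paint_rings((H, W), truth, "ring_before")
    after = _paint_rings((H, W), truth, "ring_after")
    if params.noise_sd > 0:
        before = np.clip(before + rng.normal(0, params.noise_sd, before.shape), 0, None)
        after = np.clip(after + rng.normal(0, params.noise_sd, after.shape), 0, None)
    return BeadScene(before=before, after=after, truth=truth, params=params)


def write_bead_scene(scene: BeadScene, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "before.tif", scene.before.astype(np.float32))
    tifffile.imwrite(outdir / "after.tif", scene.after.astype(np.float32))
    scene.truth.to_csv(outdir / "truth_beads.csv", index=False)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _leaflet_grid(n: int, Lx: float, Ly: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular in-plane lipid packing with small positional jitter."""
    ncols = int(np.ceil(np.sqrt(n * Lx / Ly)))
    nrows = int(np.ceil(n / ncols))
    xs = (np.arange(ncols) + 0.5) * (Lx / ncols)
    ys = (np.arange(nrows) + 0.5) * (Ly / nrows)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    jitter_scale = 0.05 * min(Lx / ncols, Ly / nrows)
    pts = pts + rng.normal(0, jitter_scale, pts.shape)
    pts[:, 0] %= Lx
    pts[:, 1] %= Ly
    return pts


def gen_trajectory(params: TrajectoryParams):
    """Generate frames plus the true per-frame contact indicator matrix.

    Returns ``(frames, contacts_true)`` where ``frames`` is a list of
    :class:`ldquant.contacts.TrajectoryFrame` and ``contacts_true`` is a
    boolean array of shape ``(n_frames, n_residues)`` recording which
    residues were placed in lipid contact in each frame.
    """
    from .contacts import TrajectoryFrame  # local import to avoid a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    Lx, Ly, Lz = params.box
    p_contact = params.resolved_contact_prob()
    n_res = params.n_residues
    n_lip = params.n_lipids_per_leaflet
    if params.monolayer:
        # TG interdigitation loosens monolayer packing: fewer lipids per
        # leaflet at the same box, i.e. a higher area per lipid
        n_lip = max(n_res, int(round(n_lip / params.monolayer_apl_factor)))

    # residue rest positions: grid 1.0 nm above the upper leaflet plane,
    # spaced so that contact shells of neighbouring residues never overlap
    spacing = 1.5
    ncols = max(1, int(Lx // spacing))
    res_rest = np.zeros((n_res, 3))
    for j in range(n_res):
        res_rest[j, 0] = (j % ncols + 0.5) * spacing % Lx
        res_rest[j, 1] = ((j // ncols + 0.5) * spacing) % Ly
        res_rest[j, 2] = 1.0
    if (n_res - 1) // ncols >= max(1, int(Ly // spacing)):
        raise ValueError("box too small to lay out residues at safe spacing")

    # phospholipid classes at the PC:PA ratio, drawn per molecule
    def classes(n):
        return np.where(rng.random(n) < params.pc_fraction, "DOPC", "DOPA")

    upper_cls = classes(n_lip)
    lower_cls = classes(n_lip)
    upper_rest = _leaflet_grid(n_lip, Lx, Ly, rng)
    lower_rest = _leaflet_grid(n_lip, Lx, Ly, rng)

    # leaflet planes: upper at z=0; lower offset by the TG slab (monolayer
    # model sandwiches a triglyceride core) or a 3.8 nm bilayer spacing
    if params.monolayer:
        # TG core plus two headgroup offsets separates the leaflets
        lower_z = -(params.tg_slab_thickness + 1.0)
        n_tg = params.n_tg
    else:
        lower_z = -3.7  # typical phosphate-to-phosphate distance for DOPC
        n_tg = 0

    frames = []
    contacts_true = np.zeros((params.n_frames, n_res), dtype=bool)
    wobble = 0.05  # nm of thermal z-noise on leaflet sites

    kind = np.array(
        ["residue"] * n_res + ["lipid"] * (2 * n_lip) + ["tg"] * n_tg, dtype=object
    )
    index = np.concatenate(
        [np.arange(n_res), np.arange(2 * n_lip), np.arange(n_tg)]
    )
    klass = np.concatenate(
        [np.array(["PEP"] * n_res, dtype=object), upper_cls, lower_cls,
         np.array(["TG"] * n_tg, dtype=object)]
    )
    leaflet = np.array(
        ["na"] * n_res + ["upper"] * n_lip + ["lower"] * n_lip + ["na"] * n_tg,
        dtype=object,
    )

    for t in range(params.n_frames):
        hit = rng.random(n_res) < p_contact
        contacts_true[t] = hit

        res = res_rest + rng.normal(0, 0.02, res_rest.shape)
        res[:, 2] = np.maximum(res[:, 2], 0.95)  # stay outside contact range
        upper = np.column_stack(
            [upper_rest, np.zeros(n_lip)]
        ) + rng.normal(0, wobble, (n_lip, 3))
        lower = np.column_stack(
            [lower_rest, np.full(n_lip, lower_z)]
        ) + rng.normal(0, wobble, (n_lip, 3))

        # partner lipid j snaps into the contact shell below residue j
        for j in np.flatnonzero(hit):
            upper[j] = res[j] + np.array([0.0, 0.0, -params.contact_offset])

        if n_tg:
            tg = np.column_stack(
                [
                    rng.uniform(0, Lx, n_tg),
                    rng.uniform(0, Ly, n_tg),
                    rng.uniform(lower_z + 0.4, -0.4, n_tg),
                ]
            )
            xyz = np.vstack([res, upper, lower, tg])
        else:
            xyz = np.vstack([res, upper, lower])

        frames.append(
            TrajectoryFrame(
                index=t, box=(Lx, Ly, Lz), kind=kind.copy(), label=index.copy(),
                klass=klass.copy(), leaflet=leaflet.copy(), xyz=xyz,
            )
        )
    return frames, contacts_true


# ---------------------------------------------------------------------------
# larval tracks
# ---------------------------------------------------------------------------

def gen_tracks(params: TrackParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlated random walks in a circular arena.

    Returns ``(tracks, truth)``: a long-format table with columns
    ``larva_id, t, x, y`` and a truth table with the total distance actually
    travelled and the number of stop events per larva.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.dt))
    stop_steps = max(1, int(round(params.stop_duration / params.dt)))

    rows, truth_rows = [], []
    for lid in range(1, params.n_larvae + 1):
        x = y = 0.0
        heading = 0.0 if params.straight else rng.uniform(-np.pi, np.pi)
        remaining_stop = 0
        dist = 0.0
        n_stops = 0
        rows.append((lid, 0.0, x, y))
        for k in range(1, n_steps + 1):
            if not params.straight:
                if remaining_stop == 0 and rng.random() < params.stop_prob:
                    remaining_stop = stop_steps
                    n_stops += 1
            if remaining_stop > 0:
                remaining_stop -= 1
                step = 0.0
            else:
                if not params.straight:
                    heading += rng.normal(0.0, params.turn_sd)
                step = params.speed_mean * params.dt
            nx = x + step * np.cos(heading)
            ny = y + step * np.sin(heading)
            # reflect off the arena wall, preserving step length
            rr = np.hypot(nx, ny)
            if rr > params.arena_radius:
                heading += np.pi / 2 + rng.uniform(0, np.pi) * (not params.straight)
                nx = x + step * np.cos(heading)
                ny = y + step * np.sin(heading)
                if np.hypot(nx, ny) > params.arena_radius:
                    nx, ny = x, y  # stay put rather than escape
                    step = 0.0
            dist += np.hypot(nx - x, ny - y)
            x, y = nx, ny
            rows.append((lid, k * params.dt, x, y))
        truth_rows.append(dict(larva_id=lid, total_distance=dist, n_stops=n_stops))

    tracks = pd.DataFrame(rows, columns=["larva_id", "t", "x", "y"])
    return tracks, pd.DataFrame(truth_rows)
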