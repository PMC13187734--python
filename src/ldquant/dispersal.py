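"""Radial dispersal of lipid droplets and peripheral organelle intensity.

The central quantity is the fractional-distance statistic ``D_F`` of a
droplet inside its cell: the Euclidean distance-transform distance of the
droplet centroid from the nucleus, divided by the sum of its distances from
the nucleus and from the cell boundary,

    D_F = d_nucleus / (d_nucleus + d_boundary).

``D_F = 0`` on the nucleus edge (perinuclear droplets) and ``D_F = 1`` on the
cell boundary (peripheral droplets). In a concentric circular cell of outer
radius R and nucleus radius r the statistic reduces to the radial fraction
(rho - r) / (R - r). The definition uses distance transforms of the actual
masks, so it is meaningful for arbitrary (non-convex, elongated) cell shapes.

A companion readout quantifies a second organelle channel (e.g. lysosomes) as
the ratio of intensity inside a peripheral band to whole-cell intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

__all__ = [
    "SegmentedCell",
    "DropletRecord",
    "PeripheralRatio",
    "segment_scene",
    "compute_df",
    "df_summary",
    "peripheral_intensity_ratio",
]


@dataclass
class SegmentedCell:
    """One segmented cell with the distance geometry needed for D_F.

    ``dt_nucleus`` is the distance (px) to the nearest nucleus pixel, zero on
    and inside the nucleus. ``dt_boundary`` is the distance to the nearest
    cell-boundary pixel, zero on the outermost pixels of the cell mask.
    """

    cell_id: int
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    dt_nucleus: np.ndarray = field(default=None, repr=False)
    dt_boundary: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not np.all(self.cell_mask[self.nucleus_mask]):
            raise ValueError("nucleus_mask must be contained in cell_mask")
        if self.dt_nucleus is None or self.dt_boundary is None:
            self._compute_transforms()

    def _compute_transforms(self) -> None:
        # distance to nucleus: EDT of the complement of the nucleus mask
        self.dt_nucleus = ndimage.distance_transform_edt(~self.nucleus_mask)
        # boundary pixels: cell pixels lost under erosion
        interior = ndimage.binary_erosion(self.cell_mask, border_value=0)
        boundary = self.cell_mask & ~interior
        self.dt_boundary = ndimage.distance_transform_edt(~boundary)

    @property
    def boundary(self) -> np.ndarray:
        interior = ndimage.binary_erosion(self.cell_mask, border_value=0)
        return self.cell_mask & ~interior

    @property
    def area(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.area / np.pi))


@dataclass
class DropletRecord:
    droplet_id: int
    centroid: tuple[float, float]  # (row, col)
    area: float
    cell_id: int  # 0 = unassigned
    d_f: float = np.nan
    flagged: bool = False


@dataclass
class PeripheralRatio:
    cell_id: int
    band_fraction: float
    ratio: float


# ---------------------------------------------------------------------------


def _sample_map(grid: np.ndarray, point) -> float:
    """Bilinear sample of a per-pixel map at a (row, col) point."""
    return float(
        ndimage.map_coordinates(grid, [[point[0]], [point[1]]], order=1,
                                mode="nearest")[0]
    )


def compute_df(cell: SegmentedCell, centroid) -> float:
    """Fractional distance of a droplet centroid between nucleus and boundary.

    Returns 0.0 (flagged via warning) for centroids inside the nucleus and
    raises for centroids outside the cell mask.
    """
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= r < cell.cell_mask.shape[0] and 0 <= c < cell.cell_mask.shape[1]):
        raise ValueError(f"centroid {centroid} lies outside the image")
    if not cell.cell_mask[r, c]:
        raise ValueError(f"centroid {centroid} lies outside cell {cell.cell_id}")
    if cell.nucleus_mask[r, c]:
        interior = ndimage.binary_erosion(cell.nucleus_mask, border_value=0)
        if interior[r, c]:
            warnings.warn(
                f"droplet centroid {centroid} lies inside the nucleus; D_F set to 0",
                stacklevel=2,
            )
        return 0.0
    dn = _sample_map(cell.dt_nucleus, centroid)
    db = _sample_map(cell.dt_boundary, centroid)
    if dn + db == 0.0:
        return 0.0
    return float(np.clip(dn / (dn + db), 0.0, 1.0))


def df_summary(
    droplets: list[DropletRecord] | pd.DataFrame,
    group_by: str = "cell_id",
    population_sd: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SD of D_F per group plus the per-droplet table.

    SD uses the sample convention (n-1 denominator) unless
    ``population_sd`` is set. Groups with no finite D_F are dropped with a
    warning. Returns ``(summary, per_droplet_table)``.
    """
    if isinstance(droplets, pd.DataFrame):
        table = droplets.copy()
    else:
        if not droplets:
            raise ValueError("droplet list is empty")
        table = pd.DataFrame(
            dict(
                droplet_id=[d.droplet_id for d in droplets],
                cell_id=[d.cell_id for d in droplets],
                row=[d.centroid[0] for d in droplets],
                col=[d.centroid[1] for d in droplets],
                area=[d.area for d in droplets],
                d_f=[d.d_f for d in droplets],
            )
        )
    if table.empty:
        raise ValueError("droplet table is empty")
    ddof = 0 if population_sd else 1
    rows = []
    for key, grp in table.groupby(group_by):
        vals = grp["d_f"].dropna()
        if vals.empty:
            warnings.warn(f"group {key!r} has no valid D_F values; omitted",
                          stacklevel=2)
            continue
        rows.append(
            {group_by: key, "n": len(vals), "mean_d_f": vals.mean(),
             "sd_d_f": vals.std(ddof=ddof) if len(vals) > ddof else 0.0}
        )
    return pd.DataFrame(rows), table


def peripheral_intensity_ratio(
    cell: SegmentedCell, intensity: np.ndarray, band_fraction: float = 0.2
) -> PeripheralRatio:
    """Fraction of a channel's whole-cell intensity inside a peripheral band.

    The band is the set of cell pixels whose distance to the cell boundary is
    at most ``band_fraction`` times the cell's equivalent radius
    (sqrt(area/pi)). For non-negative images the ratio lies in [0, 1].
    """
    if intensity.shape != cell.cell_mask.shape:
        raise ValueError("intensity grid shape does not match the masks")
    if not (0.0 < band_fraction < 1.0):
        raise ValueError(f"band_fraction must lie in (0, 1), got {band_fraction}")
    total = float(intensity[cell.cell_mask].sum())
    if total == 0.0:
        raise ValueError("whole-cell intensity sum is zero; ratio undefined")
    band = cell.cell_mask & (cell.dt_boundary <= band_fraction * cell.equivalent_radius)
    ratio = float(intensity[band].sum()) / total
    return PeripheralRatio(cell_id=cell.cell_id, band_fraction=band_fraction,
                           ratio=ratio)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_scene(
    image: np.ndarray,
    channel_roles: dict[str, int],
    nucleus_threshold: float | None = None,
    cell_threshold: float | None = None,
    droplet_threshold: float | None = None,
    min_droplet_area: int = 2,
) -> tuple[list[SegmentedCell], list[DropletRecord]]:
    """Threshold-and-watershed segmentation of a multichannel field.

    Nuclei (Otsu threshold by default) seed a watershed that splits touching
    cells; droplet blobs are assigned to the cell containing their centroid.
    Droplets whose centroid falls outside every cell are returned flagged
    with ``cell_id = 0``.
    """
    if "nucleus" not in channel_roles or "cell" not in channel_roles:
        raise ValueError("channel_roles must name 'nucleus' and 'cell' channels")
    nuc = np.asarray(image[channel_roles["nucleus"]], dtype=float)
    cel = np.asarray(image[channel_roles["cell"]], dtype=float)

    def _thr(img, given):
        if given is not None:
            return given
        if img.max() == img.min():
            return np.inf  # blank channel: nothing is foreground
        return threshold_otsu(img)

    nuc_fg = nuc > _thr(nuc, nucleus_threshold)
    cell_fg = cel > _thr(cel, cell_threshold)
    if not cell_fg.any():
        warnings.warn("no cell foreground found; returning empty result",
                      stacklevel=2)
        return [], []

    seeds = cc_label(nuc_fg)
    # nuclei must sit inside the cell foreground to seed a cell
    for sid in range(1, seeds.max() + 1):
        if not cell_fg[seeds == sid].any():
            warnings.warn(f"nucleus seed {sid} has no surrounding cell; skipped",
                          stacklevel=2)
            seeds[seeds == sid] = 0
    if seeds.max() == 0:
        warnings.warn("no nucleus seeds inside cells; returning empty result",
                      stacklevel=2)
        return [], []

    dist = ndimage.distance_transform_edt(cell_fg)
    labels = watershed(-dist, markers=seeds, mask=cell_fg)

    cells = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        cmask = labels == cid
        nmask = nuc_fg & cmask
        if not nmask.any():
            continue
        cells.append(SegmentedCell(cell_id=int(cid), cell_mask=cmask,
                                   nucleus_mask=nmask))

    droplets: list[DropletRecord] = []
    if "droplet" in channel_roles:
        dro = np.asarray(image[channel_roles["droplet"]], dtype=float)
        dro_fg = dro > _thr(dro, droplet_threshold)
        for i, prop in enumerate(regionprops(cc_label(dro_fg)), start=1):
            if prop.area < min_droplet_area:
                continue
            cy, cx = prop.centroid
            owner = int(labels[int(round(cy)), int(round(cx))])
            droplets.append(
                DropletRecord(droplet_id=i, centroid=(cy, cx), area=prop.area,
                              cell_id=owner, flagged=owner == 0)
            )
        n_unassigned = sum(d.flagged for d in droplets)
        if n_unassigned:
            warnings.warn(f"{n_unassigned} droplets not inside any cell; flagged",
                          stacklevel=2)
    return cells, droplets


def run_scene(
    image: np.ndarray,
    channel_roles: dict[str, int],
    band_fraction: float = 0.2,
    intensity_role: str | None = None,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Segment, score every droplet, and summarize; optionally write CSVs."""
    cells, droplets = segment_scene(image, channel_roles)
    by_id = {c.cell_id: c for c in cells}
    for d in droplets:
        if d.cell_id in by_id:
            d.d_f = compute_df(by_id[d.cell_id], d.centroid)
    scored = [d for d in droplets if np.isfinite(d.d_f)]
    out: dict[str, pd.DataFrame] = {}
    if scored:
        out["summary"], out["droplets"] = df_summary(scored)
    else:
        out["summary"] = pd.DataFrame()
        out["droplets"] = pd.DataFrame()
    if intensity_role is not None:
        grid = np.asarray(image[channel_roles[intensity_role]], dtype=float)
        out["peripheral"] = pd.DataFrame(
            [vars(peripheral_intensity_ratio(c, grid, band_fraction)) for c in cells]
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return out
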