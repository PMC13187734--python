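"""Reading and writing trajectory frames.

Native format: a plain CSV whose first line records the periodic box,

    #box <Lx> <Ly> <Lz>
    frame,kind,index,class,leaflet,x,y,z
    0,residue,0,PEP,na,1.2,0.8,1.0
    ...

with kind in {residue, lipid, tg}, class in {PEP, DOPC, DOPA, TG}, leaflet
in {upper, lower, na} and coordinates in nanometres. ``from_mdanalysis``
adapts standard structure/trajectory formats (PDB/GRO + XTC/DCD ...) read
through an MDAnalysis Universe into the same in-memory frames.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import TrajectoryFrame

__all__ = ["write_frames", "read_frames", "from_mdanalysis"]

_COLUMNS = ["frame", "kind", "index", "class", "leaflet", "x", "y", "z"]


def write_frames(frames: list[TrajectoryFrame], path: str | Path) -> None:
    path = Path(path)
    box = frames[0].box
    parts = []
    for fr in frames:
        if fr.box != box:
            raise ValueError("the frame CSV dialect assumes a constant box")
        parts.append(
            pd.DataFrame(
                {
                    "frame": fr.index,
                    "kind": fr.kind,
                    "index": fr.label,
                    "class": fr.klass,
                    "leaflet": fr.leaflet,
                    "x": fr.xyz[:, 0],
                    "y": fr.xyz[:, 1],
                    "z": fr.xyz[:, 2],
                }
            )
        )
    body = pd.concat(parts, ignore_index=True)
    with path.open("w") as fh:
        fh.write(f"#box {box[0]} {box[1]} {box[2]}\n")
        body.to_csv(fh, index=False)


def read_frames(path: str | Path) -> list[TrajectoryFrame]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#box"):
            raise ValueError(f"{path}: expected '#box Lx Ly Lz' header line")
        box = tuple(float(v) for v in header.split()[1:4])
        table = pd.read_csv(fh)
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frames = []
    for idx, grp in table.groupby("frame", sort=True):
        frames.append(
            TrajectoryFrame(
                index=int(idx),
                box=box,
                kind=grp["kind"].to_numpy(dtype=object),
                label=grp["index"].to_numpy(dtype=int),
                klass=grp["class"].to_numpy(dtype=object),
                leaflet=grp["leaflet"].to_numpy(dtype=object),
                xyz=grp[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return frames


def from_mdanalysis(
    universe,
    peptide_selection: str = "protein",
    lipid_classes: dict[str, str] | None = None,
    leaflet_z_split: float | None = None,
    scale: float = 0.1,
) -> list[TrajectoryFrame]:
    """Adapt an MDAnalysis Universe into the suite's frame objects.

    ``lipid_classes`` maps residue names to DOPC/DOPA/TG (defaults to the
    identity for those three names). Coordinates are multiplied by ``scale``
    (0.1 converts Angstrom to nm). Lipid leaflets are split at
    ``leaflet_z_split`` (nm, after scaling) or at the lipid median z.
    """
    lipid_classes = lipid_classes or {c: c for c in ("DOPC", "DOPA", "TG")}
    pep = universe.select_atoms(peptide_selection)
    lip = universe.select_atoms(
        " or ".join(f"resname {r}" for r in lipid_classes)
    )
    frames = []
    for ts in universe.trajectory:
        box = tuple(float(v) * scale for v in ts.dimensions[:3])
        pep_xyz = pep.positions * scale
        lip_xyz = lip.positions * scale
        split = (
            leaflet_z_split
            if leaflet_z_split is not None
            else float(np.median(lip_xyz[:, 2]))
        )
        kinds, labels, classes, leaflets, coords = [], [], [], [], []
        for a, p in zip(pep.atoms, pep_xyz):
            kinds.append("residue")
            labels.append(int(a.resid))
            classes.append("PEP")
            leaflets.append("na")
            coords.append(p)
        for a, p in zip(lip.atoms, lip_xyz):
            cls = lipid_classes[a.resname]
            kinds.append("tg" if cls == "TG" else "lipid")
            labels.append(int(a.resid))
            classes.append(cls)
            leaflets.append(
                "na" if cls == "TG" else ("upper" if p[2] >= split else "lower")
            )
            coords.append(p)
        frames.append(
            TrajectoryFrame(
                index=int(ts.frame),
                box=box,
                kind=np.array(kinds, dtype=object),
                label=np.array(labels),
                klass=np.array(classes, dtype=object),
                leaflet=np.array(leaflets, dtype=object),
                xyz=np.asarray(coords, dtype=float),
            )
        )
    return frames
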