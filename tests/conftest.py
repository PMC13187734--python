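import numpy as np
import pytest

from ldquant import dispersal as D
from ldquant import synthetic as S
from ldquant.contacts import TrajectoryFrame


@pytest.fixture(scope="session")
def concentric_cell():
    """Noiseless concentric-disk cell: R = 100 px, nucleus r = 30 px."""
    H = W = 240
    cy = cx = 120
    cmask = S._disk_mask((H, W), (cy, cx), 100)
    nmask = S._disk_mask((H, W), (cy, cx), 30)
    return D.SegmentedCell(cell_id=1, cell_mask=cmask, nucleus_mask=nmask), (cy, cx)


def make_frame(res_xyz, lip_xyz, box=(10.0, 10.0, 10.0), lip_class=None,
               lip_leaflet=None, index=0):
    """Hand-built frame: one site per residue / lipid molecule."""
    res_xyz = np.atleast_2d(np.asarray(res_xyz, dtype=float))
    lip_xyz = np.atleast_2d(np.asarray(lip_xyz, dtype=float)) if len(lip_xyz) else np.empty((0, 3))
    n_r, n_l = len(res_xyz), len(lip_xyz)
    lip_class = list(lip_class) if lip_class is not None else ["DOPC"] * n_l
    lip_leaflet = list(lip_leaflet) if lip_leaflet is not None else ["upper"] * n_l
    kind = np.array(["residue"] * n_r + ["lipid"] * n_l, dtype=object)
    for k, cls in enumerate(lip_class):
        if cls == "TG":
            kind[n_r + k] = "tg"
    return TrajectoryFrame(
        index=index,
        box=box,
        kind=kind,
        label=np.concatenate([np.arange(n_r), np.arange(n_l)]).astype(int),
        klass=np.array(["PEP"] * n_r + lip_class, dtype=object),
        leaflet=np.array(["na"] * n_r + lip_leaflet, dtype=object),
        xyz=np.vstack([res_xyz, lip_xyz]) if n_l else res_xyz.copy(),
    )


@pytest.fixture
def frame_factory():
    return make_frame


def random_frame(rng, n_res=5, n_lip=15, box=(6.0, 6.0, 6.0)):
    """Random small frame for oracle-equivalence checks."""
    res = rng.uniform(-2, 8, size=(n_res, 3))
    lip = rng.uniform(-2, 8, size=(n_lip, 3))
    classes = rng.choice(["DOPC", "DOPA", "TG"], size=n_lip).tolist()
    leaflets = ["na" if c == "TG" else "upper" for c in classes]
    return make_frame(res, lip, box=box, lip_class=classes, lip_leaflet=leaflets)
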