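"""Contact matrices, occupancies, lipid fractions, membrane metrics, RMSD."""

import numpy as np
import pandas as pd
import pytest

from ldquant import contacts as C
from ldquant import synthetic as S
from tests.conftest import make_frame, random_frame


class TestContactMatrix:
    def test_just_inside_cutoff(self, frame_factory):
        fr = frame_factory([[0, 0, 0]], [[0, 0, 0.69]])
        _, _, mat = C.contact_matrix(fr, 0.7)
        assert mat[0, 0]

    def test_just_outside_cutoff(self, frame_factory):
        fr = frame_factory([[0, 0, 0]], [[0, 0, 0.71]])
        _, _, mat = C.contact_matrix(fr, 0.7)
        assert not mat[0, 0]

    def test_minimum_image_wrap_in_x(self, frame_factory):
        # wrapped separation 0.3 nm across the x boundary of a 10 nm box
        fr = frame_factory([[0.2, 0, 0]], [[9.9, 0, 0]], box=(10.0, 10.0, 10.0))
        _, _, mat = C.contact_matrix(fr, 0.7)
        assert mat[0, 0]

    def test_z_is_not_periodic(self, frame_factory):
        fr = frame_factory([[0, 0, 0.2]], [[0, 0, 9.9]], box=(10.0, 10.0, 10.0))
        _, _, mat = C.contact_matrix(fr, 0.7)
        assert not mat[0, 0]

    def test_empty_frame_gives_empty_matrix(self, frame_factory):
        fr = frame_factory([[0, 0, 0]], [])
        rl, keys, mat = C.contact_matrix(fr, 0.7)
        assert mat.shape == (1, 0)

    def test_binning_equals_bruteforce_on_random_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            fr = random_frame(rng)
            rl, keys, mat = C.contact_matrix(fr, 0.7)
            got = {(int(rl[a]), keys[b]) for a, b in zip(*np.nonzero(mat))}
            assert got == C.contact_pairs_bruteforce(fr, 0.7)

    def test_contacts_nondecreasing_in_cutoff(self):
        rng = np.random.default_rng(7)
        fr = random_frame(rng, n_res=6, n_lip=20)
        prev = -1
        for cutoff in (0.3, 0.5, 0.7, 1.0, 1.5):
            _, _, mat = C.contact_matrix(fr, cutoff)
            assert mat.sum() >= prev
            prev = mat.sum()


class TestOccupancy:
    def test_never_in_contact_is_zero(self, frame_factory):
        frames = [frame_factory([[0, 0, 5]], [[0, 0, 0]], index=i)
                  for i in range(4)]
        occ = C.occupancy(frames)
        assert occ.table["O_DOPC"].iloc[0] == 0.0

    def test_toy_three_of_ten_frames(self, frame_factory):
        # residue touches a DOPA lipid in frames {1, 4, 7} only
        frames = []
        for i in range(10):
            z = 0.5 if i in (1, 4, 7) else 5.0
            frames.append(frame_factory([[0, 0, 0]], [[0, 0, z]],
                                        lip_class=["DOPA"], index=i))
        occ = C.occupancy(frames)
        assert occ.table["O_DOPA"].iloc[0] == pytest.approx(0.3)
        assert occ.table["O_DOPC"].iloc[0] == 0.0
        assert occ.table["O_mean"].iloc[0] == pytest.approx(0.15)

    def test_recovers_generator_contact_probability(self):
        p = np.full(5, 0.5)
        params = S.TrajectoryParams(n_frames=600, n_residues=5,
                                    n_lipids_per_leaflet=20,
                                    box=(9.0, 9.0, 8.0), contact_prob=p,
                                    seed=3)
        frames, _ = S.gen_trajectory(params)
        occ = C.occupancy(frames)
        half = 2.576 * np.sqrt(0.5 * 0.5 / 600)  # binomial 99% CI
        assert np.all(np.abs(occ.table["O_any"] - 0.5) <= half)

    def test_zero_frames_raises(self):
        with pytest.raises(ValueError):
            C.occupancy([])


class TestDeltaOccupancy:
    @staticmethod
    def _table(values, system):
        n = len(values)
        t = pd.DataFrame(dict(residue=np.arange(n), O_DOPC=values,
                              O_DOPA=values, O_mean=values, O_any=values))
        return C.OccupancyTable(system=system, cutoff=0.7, table=t)

    def test_identical_tables_all_zero_none_reported(self):
        t = self._table([0.03, 0.04], "x")
        out = C.delta_occupancy(t, self._table([0.03, 0.04], "y"))
        assert np.all(out["delta_pct"] == 0.0)
        assert not out["reported"].any()

    def test_thirty_vs_seven_percent_reported(self):
        out = C.delta_occupancy(self._table([0.30], "m"), self._table([0.07], "b"))
        assert out["delta_pct"].iloc[0] == pytest.approx(23.0)
        assert out["reported"].iloc[0]
        assert out.attrs["mean_monolayer_favoring_pct"] == pytest.approx(23.0)

    def test_below_threshold_not_reported(self):
        out = C.delta_occupancy(self._table([0.04], "m"), self._table([0.03], "b"))
        assert out["delta_pct"].iloc[0] == pytest.approx(1.0)
        assert not out["reported"].iloc[0]

    def test_antisymmetry(self):
        a = self._table([0.3, 0.1, 0.02], "m")
        b = self._table([0.07, 0.25, 0.01], "b")
        ab = C.delta_occupancy(a, b)
        ba = C.delta_occupancy(b, a)
        assert np.allclose(ab["delta_pct"], -ba["delta_pct"])
        assert (ab["reported"] == ba["reported"]).all()

    def test_residue_mismatch_lists_offenders(self):
        a = self._table([0.3, 0.1], "m")
        b = self._table([0.3], "b")
        with pytest.raises(ValueError, match="residue sets disagree"):
            C.delta_occupancy(a, b)


class TestLipidFraction:
    def test_one_residue_one_lipid(self, frame_factory):
        fr = frame_factory([[0, 0, 0]], [[0, 0, 0.5]])
        series = C.lipid_fraction([fr], group=[0])
        assert series.per_frame["L_f"].iloc[0] == 1.0

    def test_two_residues_three_lipids(self, frame_factory):
        # residues at 0 and 3 nm; three distinct lipids within the shells
        fr = frame_factory(
            [[0, 0, 0], [3, 0, 0]],
            [[0, 0, 0.5], [0.4, 0, 0], [3, 0, 0.5]],
            lip_class=["DOPC", "DOPA", "TG"],
            lip_leaflet=["upper", "upper", "na"],
        )
        series = C.lipid_fraction([fr], group=[0, 1])
        row = series.per_frame.iloc[0]
        assert row["N"] == 2 and row["L_n"] == 3
        assert row["L_f"] == pytest.approx(1.5)

    def test_no_contact_frames_excluded_and_mass_one(self, frame_factory):
        near = frame_factory([[0, 0, 0]], [[0, 0, 0.5]], index=0)
        far = frame_factory([[0, 0, 0]], [[0, 0, 5.0]], index=1)
        series = C.lipid_fraction([near, far], group=[0])
        assert np.isnan(series.per_frame["L_f"].iloc[1])
        assert series.probability.sum() == pytest.approx(1.0)

    def test_all_empty_frames_warn(self, frame_factory):
        far = frame_factory([[0, 0, 0]], [[0, 0, 5.0]])
        with pytest.warns(UserWarning, match="P\\(L_f\\) is empty"):
            series = C.lipid_fraction([far], group=[0])
        assert series.probability.sum() == 0.0

    def test_fixed_group_size_denominator(self, frame_factory):
        fr = frame_factory([[0, 0, 0], [3, 0, 0]], [[0, 0, 0.5]])
        series = C.lipid_fraction([fr], group=[0, 1], fixed_group_size=True)
        assert series.per_frame["L_f"].iloc[0] == pytest.approx(0.5)


class TestMembraneMetrics:
    def test_apl_arithmetic(self, frame_factory):
        lip = [[i * 0.1, 0, 0] for i in range(50)]
        fr = frame_factory([[0, 0, 5]], lip, box=(6.0, 6.0, 10.0))
        assert C.area_per_lipid(fr, "upper") == pytest.approx(0.72)

    def test_halving_lipids_doubles_apl(self, frame_factory):
        lip = [[i * 0.1, 0, 0] for i in range(50)]
        fr_full = frame_factory([[0, 0, 5]], lip, box=(6.0, 6.0, 10.0))
        fr_half = frame_factory([[0, 0, 5]], lip[:25], box=(6.0, 6.0, 10.0))
        assert C.area_per_lipid(fr_half) == pytest.approx(
            2 * C.area_per_lipid(fr_full))

    def test_generator_apl(self):
        params = S.TrajectoryParams(n_frames=1, n_residues=5,
                                    n_lipids_per_leaflet=64,
                                    box=(6.4, 6.4, 8.0), seed=0)
        frames, _ = S.gen_trajectory(params)
        assert C.area_per_lipid(frames[0], "upper") == pytest.approx(0.64)

    def test_empty_leaflet_raises(self, frame_factory):
        fr = frame_factory([[0, 0, 5]], [[0, 0, 0]], lip_leaflet=["upper"])
        with pytest.raises(ValueError, match="no phospholipids"):
            C.area_per_lipid(fr, "lower")

    def test_flat_leaflet_thickness(self, frame_factory):
        fr = frame_factory(
            [[0, 0, 5]],
            [[0, 0, 2.0], [1, 0, 2.0], [0, 0, -2.0], [1, 0, -2.0]],
            lip_leaflet=["upper", "upper", "lower", "lower"],
        )
        assert C.membrane_thickness(fr) == pytest.approx(4.0)

    def test_symmetric_noise_preserves_mean_thickness(self, frame_factory):
        rng = np.random.default_rng(5)
        n = 60
        vals = []
        for i in range(200):
            z_up = 2.0 + rng.normal(0, 0.3, n)
            z_lo = -2.0 + rng.normal(0, 0.3, n)
            lip = [[k * 0.1, 0, z] for k, z in enumerate(z_up)] + [
                [k * 0.1, 0, z] for k, z in enumerate(z_lo)]
            fr = frame_factory([[0, 0, 5]], lip, box=(8.0, 8.0, 10.0),
                               lip_leaflet=["upper"] * n + ["lower"] * n,
                               index=i)
            vals.append(C.membrane_thickness(fr))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 4.0) <= 3 * se

    def test_monolayer_thicker_than_matched_bilayer(self):
        common = dict(n_frames=1, n_residues=5, n_lipids_per_leaflet=40,
                      box=(9.0, 9.0, 12.0), seed=1)
        mono, _ = S.gen_trajectory(S.TrajectoryParams(monolayer=True, **common))
        bi, _ = S.gen_trajectory(S.TrajectoryParams(monolayer=False, **common))
        assert C.membrane_thickness(mono[0]) > C.membrane_thickness(bi[0])

    def test_missing_leaflet_raises(self, frame_factory):
        fr = frame_factory([[0, 0, 5]], [[0, 0, 2.0]], lip_leaflet=["upper"])
        with pytest.raises(ValueError, match="lower"):
            C.membrane_thickness(fr)


class TestRMSD:
    @staticmethod
    def _peptide_frames():
        rng = np.random.default_rng(0)
        ref_xyz = rng.uniform(0, 3, size=(6, 3))
        return ref_xyz

    def test_reference_against_itself_is_zero(self, frame_factory):
        xyz = self._peptide_frames()
        fr = frame_factory(xyz, [])
        out = C.backbone_rmsd([fr], fit=True)
        assert out["rmsd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance_with_fit(self, frame_factory):
        xyz = self._peptide_frames()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        moved = xyz @ R.T + np.array([1.0, -2.0, 0.5])
        ref = frame_factory(xyz, [])
        fr = frame_factory(moved, [], index=1)
        out = C.backbone_rmsd([fr], reference=ref, fit=True)
        assert out["rmsd"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_three_site_closed_form_without_fit(self, frame_factory):
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        moved = base.copy()
        moved[0, 2] += 0.3
        ref = frame_factory(base, [])
        fr = frame_factory(moved, [], index=1)
        out = C.backbone_rmsd([fr], reference=ref, fit=False)
        assert out["rmsd"].iloc[0] == pytest.approx(np.sqrt(0.09 / 3), abs=1e-12)

    def test_matches_mdanalysis_superposition(self, frame_factory):
        # independent cross-check of the Kabsch fit
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 4, size=(8, 3))
        b = a + rng.normal(0, 0.2, size=a.shape)
        ours = C.backbone_rmsd(
            [frame_factory(b, [], index=1)],
            reference=frame_factory(a, []), fit=True,
        )["rmsd"].iloc[0]
        theirs = mda_rms.rmsd(b, a, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_too_few_residues_for_fit(self, frame_factory):
        fr = frame_factory([[0, 0, 0], [1, 0, 0]], [])
        with pytest.raises(ValueError, match="at least 3"):
            C.backbone_rmsd([fr], fit=True)


class TestSSContent:
    def test_all_helix(self):
        out = C.ss_content([["helix"] * 4] * 3)
        frac = dict(zip(out["ss_class"], out["fraction"]))
        assert frac["helix"] == 1.0 and frac["coil"] == 0.0

    def test_half_and_half(self):
        out = C.ss_content([["helix", "helix", "coil", "coil"]])
        frac = dict(zip(out["ss_class"], out["fraction"]))
        assert frac["helix"] == 0.5 and frac["coil"] == 0.5

    def test_random_labels_match_counts(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(C.SS_CLASSES, size=(20, 15))
        out = C.ss_content(labels)
        for cls, frac in zip(out["ss_class"], out["fraction"]):
            assert frac == pytest.approx((labels == cls).mean())
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="310-helix"):
            C.ss_content([["helix", "310-helix"]])
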