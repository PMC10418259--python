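"""Contact criteria: salt bridges, hydrophobic pairs, hydrogen bonds."""
import numpy as np
import pytest

from conftest import brute_force_contacts, random_contact_structure
from dynmech.chemistry import InteractionCriteria
from dynmech.geometry import (
    MissingAtomError,
    contact_frequency,
    detect_contacts,
    distance_series,
)
from dynmech.structure import StructureModel, TrajectoryFrames
from dynmech.synthetic import TrajectorySimParams, generate_trajectory


def pair_structure(atoms):
    """Build a tiny structure from (chain, resid, resname, atom, element, xyz)."""
    chain, resid, resname, name, elem, pos = zip(*atoms)
    return StructureModel(
        chain=np.array(chain, dtype=object),
        resid=np.array(resid),
        resname=np.array(resname, dtype=object),
        atom_name=np.array(name, dtype=object),
        element=np.array(elem, dtype=object),
        coords=np.array(pos, dtype=float),
    )


CRIT = InteractionCriteria()


class TestSaltBridge:
    def lys_glu(self, d):
        return pair_structure([
            ("mtbd", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("mtbd", 1, "LYS", "CA", "C", (1.5, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", (d, 0.0, 0.0)),
        ])

    def test_inside_cutoff_detected(self):
        contacts = detect_contacts(self.lys_glu(3.9), None, CRIT, "salt_bridge")
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.9)

    def test_outside_cutoff_rejected(self):
        assert detect_contacts(self.lys_glu(4.1), None, CRIT, "salt_bridge") == []

    def test_cutoff_monotone(self):
        rng = np.random.default_rng(0)
        s = random_contact_structure(rng, n_residues=10)
        small = {
            (c.a, c.b)
            for c in detect_contacts(s, None, InteractionCriteria(salt_bridge_cutoff=3.0), "salt_bridge")
        }
        large = {
            (c.a, c.b)
            for c in detect_contacts(s, None, InteractionCriteria(salt_bridge_cutoff=5.0), "salt_bridge")
        }
        assert small <= large


class TestHbond:
    def dha(self, d_da, bend_deg):
        """Donor at origin with H along +x; acceptor at distance d_da,
        rotated bend_deg away from the D->H direction."""
        theta = np.deg2rad(bend_deg)
        acceptor = (d_da * np.cos(theta), d_da * np.sin(theta), 0.0)
        return pair_structure([
            ("mtbd", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("mtbd", 1, "SER", "HG", "H", (1.0, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", acceptor),
        ])

    def test_collinear_detected(self):
        assert len(detect_contacts(self.dha(3.0, 0.0), None, CRIT, "hbond")) == 1

    def test_bent_rejected(self):
        assert detect_contacts(self.dha(3.0, 45.0), None, CRIT, "hbond") == []

    def test_without_hydrogens_errors(self):
        s = pair_structure([
            ("mtbd", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", (3.0, 0.0, 0.0)),
        ])
        with pytest.raises(MissingAtomError, match="hydrogen"):
            detect_contacts(s, None, CRIT, "hbond")
        # explicit fallback allows heavy-atom-only detection
        assert len(detect_contacts(s, None, CRIT, "hbond", heavy_atom_fallback=True)) == 1

    def test_fallback_uses_antecedent_angle(self):
        # antecedent CB collinear beyond the donor: antecedent-D-A angle
        # 180 deg -> accepted; antecedent between donor and acceptor:
        # angle 0 deg -> rejected
        accept = pair_structure([
            ("mtbd", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("mtbd", 1, "SER", "CB", "C", (-1.4, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", (3.0, 0.0, 0.0)),
        ])
        reject = pair_structure([
            ("mtbd", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("mtbd", 1, "SER", "CB", "C", (1.4, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", (3.0, 0.0, 0.0)),
        ])
        assert len(detect_contacts(accept, None, CRIT, "hbond", heavy_atom_fallback=True)) == 1
        assert detect_contacts(reject, None, CRIT, "hbond", heavy_atom_fallback=True) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", ["salt_bridge", "hydrophobic", "hbond"])
    def test_matches_brute_force(self, kind):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = random_contact_structure(rng)
            expected = brute_force_contacts(s, CRIT, kind)
            try:
                got = {(c.a, c.b) for c in detect_contacts(s, None, CRIT, kind)}
            except MissingAtomError:
                assert expected == set()  # structure happened to have no hydrogens
                continue
            assert got == expected


class TestFrequencyAndDistance:
    PAIR = (("mtbd", 3306), ("alpha_tubulin", 402))

    def test_always_present_is_100(self, toy):
        params = TrajectorySimParams(n_frames=50, contact_schedule={self.PAIR: 1.0}, seed=0)
        traj = generate_trajectory(toy, params)
        assert contact_frequency(traj, toy, self.PAIR).frequency == 100.0

    def test_absent_is_0(self, toy):
        traj = generate_trajectory(toy, TrajectorySimParams(n_frames=50, seed=0))
        assert contact_frequency(traj, toy, self.PAIR).frequency == 0.0

    def test_scheduled_fraction_exact(self, toy):
        params = TrajectorySimParams(
            n_frames=1000, contact_schedule={self.PAIR: 0.624}, seed=5
        )
        traj = generate_trajectory(toy, params)
        record = contact_frequency(traj, toy, self.PAIR)
        assert record.per_frame.sum() == 624
        assert record.frequency == pytest.approx(62.4)
        assert traj.realized_contacts[self.PAIR] == pytest.approx(0.624)

    def test_static_frames_single_valued_distance(self, toy):
        traj = TrajectoryFrames(coords=np.repeat(toy.coords[None], 5, axis=0))
        series = distance_series(traj, toy, self.PAIR)
        assert np.ptp(series.distances) == pytest.approx(0.0)

    def test_linear_separation_uniform_histogram(self):
        n = 2000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = np.linspace(2.0, 10.0, n)  # move apart linearly
        s = pair_structure([
            ("mtbd", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("alpha_tubulin", 2, "GLU", "OE1", "O", (2.0, 0.0, 0.0)),
        ])
        traj = TrajectoryFrames(coords=coords)
        series = distance_series(traj, s, (("mtbd", 1), ("alpha_tubulin", 2)), bins=8)
        assert np.allclose(series.density, series.density[0], rtol=0.05)

    def test_indicator_matches_salt_bridge_series(self, toy):
        params = TrajectorySimParams(
            n_frames=200, contact_schedule={self.PAIR: 0.35}, seed=9
        )
        traj = generate_trajectory(toy, params)
        series = distance_series(traj, toy, self.PAIR)
        record = contact_frequency(traj, toy, self.PAIR)
        assert np.array_equal(series.indicator(4.0), record.per_frame)
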