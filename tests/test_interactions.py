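import numpy as np
import pytest

from gshrad import interactions
from gshrad.template import reference_coordinates
from gshrad.topology import build_gsh_oh_topology, select
from gshrad.trajio import Trajectory

from oracles import brute_detect


def _frame_with_guest(topology, og, hg):
    c = reference_coordinates().copy()
    c[topology.index_of("HOR.O_g")] = og
    c[topology.index_of("HOR.H_g")] = hg
    return c


def _linear_contact(topology, token, d):
    """Guest O-H pointing straight at the target atom (alpha = 180)."""
    ref = reference_coordinates()
    site = ref[topology.index_of(token)]
    direction = np.array([0.0, 0.0, 1.0])
    og = site + d * direction
    hg = og - 0.98 * direction  # H between O_g and the site
    return _frame_with_guest(topology, og, hg)


class TestDetect:
    def test_clear_pass(self, topology):
        c = _linear_contact(topology, "GLY.OT1", 2.8)
        events = interactions.detect_interactions(c, topology)
        guest_events = [e for e in events if e.acceptor == "GLY.OT1"]
        assert len(guest_events) == 1
        ev = guest_events[0]
        assert ev.direction == "guest_donates"
        assert ev.d_AD == pytest.approx(2.8)
        assert ev.alpha_AHD == pytest.approx(180.0)

    def test_distance_fail(self, topology):
        c = _linear_contact(topology, "GLY.OT1", 3.6)
        events = interactions.detect_interactions(c, topology)
        assert not [e for e in events if e.acceptor == "GLY.OT1"]

    def test_angle_fail(self, topology):
        ref = reference_coordinates()
        site = ref[topology.index_of("GLY.OT1")]
        og = site + np.array([0.0, 0.0, 2.8])
        hg = og + np.array([0.0, 0.0, 0.98])  # H pointing away: alpha = 0
        c = _frame_with_guest(topology, og, hg)
        events = interactions.detect_interactions(c, topology)
        assert not [e for e in events if e.acceptor == "GLY.OT1"]

    def test_strict_thresholds(self, topology):
        """d exactly 3.5 or alpha exactly 100 deg do not pass."""
        c = _linear_contact(topology, "GLY.OT1", 3.5)
        assert not [e for e in interactions.detect_interactions(c, topology)
                    if e.acceptor == "GLY.OT1"]

    def test_matches_brute_force(self, contact_rich_traj):
        top = contact_rich_traj.topology
        targets = select(top, "attack_points")
        for f in range(12):
            events = interactions.detect_interactions(
                contact_rich_traj.coords[f], top, frame=f)
            got = {(e.donor, e.hydrogen, e.acceptor) for e in events}
            expected = brute_detect(contact_rich_traj.coords[f], top, targets)
            assert got == expected

    def test_host_donates_direction(self, topology):
        """Guest oxygen parked along a thiol S-H: the host donates."""
        ref = reference_coordinates()
        sg = topology.index_of("CYS.SG")
        hg_thiol = topology.index_of("CYS.HG")
        u = ref[hg_thiol] - ref[sg]
        u /= np.linalg.norm(u)
        og = ref[sg] + 3.0 * u
        c = _frame_with_guest(topology, og, og + [0.0, 0.0, 0.98])
        events = interactions.detect_interactions(c, topology)
        host_ev = [e for e in events if e.direction == "host_donates"]
        assert any(e.donor == "CYS.SG" and e.hydrogen == "CYS.HG"
                   for e in host_ev)

    def test_host_only_topology_no_events(self, host_traj):
        assert interactions.detect_interactions(
            host_traj.coords[0], host_traj.topology) == []


class TestClassify:
    def _events(self, tokens, frame=0):
        return [interactions.InteractionEvent(
            frame=frame, donor="HOR.O_g", hydrogen="HOR.H_g", acceptor=t,
            d_AD=2.8, alpha_AHD=150.0, direction="guest_donates")
            for t in tokens]

    def test_zwitterionic(self):
        pat = interactions.classify_frame(
            self._events(["GGL.N", "GLY.OT1", "GLY.OT2"]))
        assert pat.motif == "zwitterionic"
        assert pat.n_contacts == 3

    def test_anionic(self):
        pat = interactions.classify_frame(self._events(["GLY.OT1", "CYS.SG"]))
        assert pat.motif == "anionic"

    def test_other_and_none(self):
        assert interactions.classify_frame(self._events(["CYS.CB"])).motif \
            == "other"
        assert interactions.classify_frame([]).motif == "none"
        assert interactions.classify_frame([]).n_contacts == 0

    def test_mixed_frames_error(self):
        events = self._events(["GLY.OT1"], frame=0) \
            + self._events(["GLY.OT2"], frame=1)
        with pytest.raises(ValueError):
            interactions.classify_frame(events)

    def test_motif_partition_is_total(self, contact_rich_traj):
        pats = interactions.frame_patterns(contact_rich_traj)
        for p in pats:
            assert p.motif in ("zwitterionic", "anionic", "other", "none")
            assert (p.motif == "none") == (len(p.contact_set) == 0)

    def test_engineered_triple_contact(self, topology):
        """Guest over the GLY carboxylate face touches OT1, OT2 and CA."""
        ref = reference_coordinates().copy()
        pts = np.array([ref[topology.index_of(t)]
                        for t in ("GLY.OT1", "GLY.OT2", "GLY.CA")])
        u = pts[1] - pts[0]
        v = pts[2] - pts[0]
        n = np.cross(u, v)
        n /= np.linalg.norm(n)
        m = np.array([[u @ u, u @ v], [u @ v, v @ v]])
        a, b = np.linalg.solve(m, 0.5 * np.array([u @ u, v @ v]))
        center = pts[0] + a * u + b * v
        og = center + 2.6 * n
        hg = og + 0.98 * (center - og) / np.linalg.norm(center - og)
        c = _frame_with_guest(topology, og, hg)
        events = interactions.detect_interactions(c, topology)
        pat = interactions.classify_frame(events)
        assert pat.contact_set == {"GLY.OT1", "GLY.OT2", "GLY.CA"}
        assert pat.motif == "anionic"


class TestCensus:
    def _traj_from_frames(self, topology, frames):
        return Trajectory(topology=topology, coords=np.stack(frames))

    def test_hand_tabulated_fixture(self, topology):
        """Engineered frames with known contact sets tally exactly."""
        far = _frame_with_guest(topology, [200.0, 200, 200], [200.0, 200, 200.98])
        one = _linear_contact(topology, "CYS.SG", 3.0)
        carb = _linear_contact(topology, "GLY.OT1", 2.8)
        traj = self._traj_from_frames(
            topology, [far, one, carb, far, one, far])
        census = interactions.pattern_census(traj)
        assert census.n_frames_total == 6
        assert census.n_ge1 == 3
        assert census.frac_thiol == pytest.approx(2 / 3)
        assert census.frac_carboxylate >= 1 / 3  # GLY.OT1 frame at least
        assert census.n_eq3 <= census.n_ge2 <= census.n_ge1

    def test_far_guest_all_zero(self, topology):
        far = _frame_with_guest(topology, [300.0, 0, 0], [300.98, 0, 0])
        census = interactions.pattern_census(
            self._traj_from_frames(topology, [far] * 4))
        assert census.n_ge1 == 0
        assert census.frac_carboxylate == 0.0
        assert census.motif_counts == {"none": 4}

    def test_tier_monotonicity(self, contact_rich_traj):
        census = interactions.pattern_census(contact_rich_traj)
        assert census.n_eq3 <= census.n_ge2 <= census.n_ge1 \
            <= census.n_frames_total

    def test_propensity_recovery_small(self):
        """Census recovers the generator's site propensities (3 sigma)."""
        from gshrad.synthgen import GeneratorConfig, generate

        traj = generate(GeneratorConfig(seed=13, n_frames=2000,
                                        contact_probability=0.5))
        census = interactions.pattern_census(traj)
        n = census.n_ge1
        assert n > 700
        for frac, p in ((census.frac_carboxylate, 0.78),
                        (census.frac_thiol, 0.04)):
            assert abs(frac - p) < 3.5 * np.sqrt(p * (1 - p) / n)

    def test_triple_interaction_frames(self, topology):
        far = _frame_with_guest(topology, [200.0, 200, 200], [200.0, 200, 200.98])
        ref = reference_coordinates().copy()
        pts = np.array([ref[topology.index_of(t)]
                        for t in ("GLY.OT1", "GLY.OT2", "GLY.CA")])
        center = pts.mean(axis=0)
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        n /= np.linalg.norm(n)
        og = center + 2.4 * n
        hg = og + 0.98 * (center - og) / np.linalg.norm(center - og)
        triple = _frame_with_guest(topology, og, hg)
        traj = self._traj_from_frames(topology, [far, triple, far])
        pats = interactions.frame_patterns(traj)
        if pats[1].n_contacts == 3:  # geometry-dependent; assert consistency
            assert interactions.triple_interaction_frames(
                traj, patterns=pats) == [1]
        assert interactions.triple_interaction_frames(
            self._traj_from_frames(topology, [far]), topology) == []


class TestIntramolecular:
    def test_rigid_extended_template_is_zero(self, rigid_template_traj):
        assert interactions.intramolecular_hbond_census(
            rigid_template_traj) == 0.0

    def test_engineered_amine_carboxylate_counts(self, topology):
        """A GLY carboxylate oxygen moved onto an amine N-H axis is counted."""
        c = reference_coordinates().copy()
        n_i = topology.index_of("GGL.N")
        h_i = topology.index_of("GGL.HN1")
        u = c[h_i] - c[n_i]
        u /= np.linalg.norm(u)
        c[topology.index_of("GLY.OT1")] = c[n_i] + 2.9 * u
        traj = Trajectory(topology=topology, coords=c[None])
        assert interactions.intramolecular_hbond_census(traj) == 1.0

    def test_matches_hand_count(self, small_traj):
        """Fraction equals an explicit per-frame triple-loop recount."""
        import math

        top = small_traj.topology
        sub = Trajectory(topology=top, coords=small_traj.coords[:10])
        frac = interactions.intramolecular_hbond_census(sub)
        triples = interactions._intra_pairs(top)
        hits = 0
        for f in range(10):
            c = sub.coords[f]
            found = False
            for dheavy, hyd, acc in triples:
                if math.dist(c[acc], c[dheavy]) >= 3.5:
                    continue
                u = c[acc] - c[hyd]
                w = c[dheavy] - c[hyd]
                cos = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) > 100.0:
                    found = True
                    break
            hits += found
        assert frac == pytest.approx(hits / 10)
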