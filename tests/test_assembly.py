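"""Bundle construction, cross-linker/motor placement, sterics."""

import numpy as np
import pytest

from microvillus.assembly import (
    attach_light_chains,
    barber_pole_parameters,
    build_bundle,
    detect_clashes,
    enumerate_crosslink_candidates,
    place_all_crosslinkers,
    place_myosin,
    propagate_pose,
    select_crosslink,
)
from microvillus.components import fimbrin_spec, light_chain_spec, myosin_spec, villin_spec
from microvillus.errors import (
    InsufficientDataError,
    ParameterError,
    PlacementError,
)
from microvillus.helix import ACTIN_RISE, RigidTransform
from microvillus.lattice import hex_points


class TestBuildBundle:
    def test_default_dimensions(self, full_bundle):
        assert full_bundle.monomers_per_filament == 362  # floor(10000/27.57)
        assert full_bundle.n_sites == 19 * 362
        assert full_bundle.n_repeats == 27

    def test_single_monomer_bundle(self, actin_sym):
        b = build_bundle(actin_sym, hex_points(0, 120.0), ACTIN_RISE / 10.0)
        assert b.n_sites == 1
        assert b.site_transform(0, 0).is_close(RigidTransform.identity())

    def test_axial_registry(self, small_bundle):
        """Site (f, i) has the same z and azimuthal phase for every f."""
        for i in (0, 5, 20):
            transforms = [
                small_bundle.site_transform(f, i) for f in range(19)
            ]
            zs = {round(t.translation[2], 9) for t in transforms}
            assert zs == {round(i * ACTIN_RISE, 9)}
            rots = {t.rotation.tobytes() for t in transforms}
            assert len(rots) == 1

    def test_barbed_up_flips_axially(self, actin_sym, lattice19):
        b = build_bundle(actin_sym, lattice19, 75.0, polarity="barbed-up")
        assert b.site_transform(0, 5).translation[2] == pytest.approx(-5 * ACTIN_RISE)

    def test_invalid_inputs(self, actin_sym, lattice19):
        with pytest.raises(ParameterError):
            build_bundle(actin_sym, lattice19, 0.0)
        with pytest.raises(ParameterError):
            build_bundle(actin_sym, lattice19, 75.0, polarity="sideways")


class TestPropagatePose:
    def test_identity_on_origin_site(self, small_bundle):
        t = propagate_pose(RigidTransform.identity(), small_bundle, 0, 0)
        assert t.is_close(RigidTransform.identity())

    def test_full_repeat_preserves_azimuth(self, small_bundle):
        """After 13 monomers (6 turns) an offset pose returns to the same
        azimuth, translated by one repeat length."""
        ref = RigidTransform.from_translation([40.0, 0.0, 0.0])
        t0 = propagate_pose(ref, small_bundle, 0, 0)
        t13 = propagate_pose(ref, small_bundle, 0, 13)
        delta = t13.translation - t0.translation
        assert delta[2] == pytest.approx(13 * ACTIN_RISE)
        assert np.linalg.norm(delta[:2]) < 0.05  # 0.002 deg residual only

    def test_adjacent_filament_is_lattice_translation(self, small_bundle):
        ref = RigidTransform.from_translation([40.0, 0.0, 0.0])
        t0 = propagate_pose(ref, small_bundle, 0, 3)
        t1 = propagate_pose(ref, small_bundle, 1, 3)
        lattice_shift = (
            small_bundle.lattice.points[1] - small_bundle.lattice.points[0]
        )
        assert np.allclose(t1.translation[:2] - t0.translation[:2], lattice_shift)
        assert t1.translation[2] == t0.translation[2]

    def test_out_of_range_site(self, small_bundle):
        with pytest.raises(IndexError):
            small_bundle.site_transform(0, 10_000)
        with pytest.raises(IndexError):
            small_bundle.site_transform(99, 0)


class TestCrosslinkCandidates:
    def test_every_edge_and_repeat_has_candidates(self, small_bundle, edges19):
        fim = fimbrin_spec()
        for edge in edges19[:8]:
            for r in range(small_bundle.n_repeats):
                assert enumerate_crosslink_candidates(small_bundle, fim, edge, r)

    def test_rigid_crosslinker_finds_nothing(self, small_bundle, edges19):
        """A 1-degree flexibility cannot absorb the 13/6 mismatch."""
        fim = fimbrin_spec()
        for edge in edges19[:3]:
            assert (
                enumerate_crosslink_candidates(
                    small_bundle, fim, edge, 0, flexibility=1.0
                )
                == []
            )

    def test_zero_linker_reach_finds_nothing(self, small_bundle, edges19):
        from dataclasses import replace

        fim = replace(fimbrin_spec(), linker_max_separation=0.0)
        assert enumerate_crosslink_candidates(small_bundle, fim, edges19[0], 0) == []

    def test_incomplete_repeat_yields_no_candidates(self, small_bundle, edges19):
        beyond = small_bundle.n_repeats  # monomers 26.. do not complete it
        assert (
            enumerate_crosslink_candidates(
                small_bundle, fimbrin_spec(), edges19[0], beyond
            )
            == []
        )

    def test_domains_lie_between_the_filaments(self, small_bundle, edges19):
        edge = edges19[0]
        pa = small_bundle.lattice.points[edge.i]
        pb = small_bundle.lattice.points[edge.j]
        span = pb - pa
        for cand in enumerate_crosslink_candidates(
            small_bundle, fimbrin_spec(), edge, 0
        ):
            for center, _, _ in cand.world_beads():
                frac = float((center[:2] - pa) @ span) / float(span @ span)
                assert -0.05 <= frac <= 1.05


class TestSelectCrosslink:
    def test_polarity_rule_rejects_reciprocal_orientation(
        self, small_bundle, edges19
    ):
        """Of the genuine and 180-swapped candidates exactly one survives,
        with the rank-1 domain pointed-ward (higher monomer index)."""
        for spec in (fimbrin_spec(), villin_spec()):
            for edge in edges19[:5]:
                cands = enumerate_crosslink_candidates(small_bundle, spec, edge, 0)
                chosen = select_crosslink(cands, spec)
                by_rank = sorted(
                    chosen.domains, key=lambda d: d.domain.polarity_rank
                )
                assert by_rank[0].monomer > by_rank[1].monomer

    def test_selection_is_deterministic(self, small_bundle, edges19):
        fim = fimbrin_spec()
        edge = edges19[0]
        cands = enumerate_crosslink_candidates(small_bundle, fim, edge, 0)
        a = select_crosslink(cands, fim)
        b = select_crosslink(list(reversed(cands)), fim)
        assert a.bound_sites() == b.bound_sites()

    def test_empty_candidates_raise(self):
        with pytest.raises(PlacementError):
            select_crosslink([], fimbrin_spec())


@pytest.fixture(scope="module")
def placements(small_bundle, edges19):
    return place_all_crosslinkers(
        small_bundle, fimbrin_spec(), villin_spec(), edges19
    )


class TestPlaceAllCrosslinkers:
    def test_one_of_each_species_per_edge_per_repeat(self, placements, small_bundle):
        expected = 42 * small_bundle.n_repeats
        names = [p.component.name for p in placements]
        assert names.count("fimbrin") == expected
        assert names.count("villin") == expected

    def test_level_classes_map_to_direction_classes(self, placements):
        for p in placements:
            assert p.level_class == p.edge.direction_class

    def test_same_class_placements_share_z_within_one_rise(self, placements):
        for name in ("fimbrin", "villin"):
            for cls in ("d", "e", "f"):
                zs = [
                    min(dp.monomer for dp in p.domains) % 13
                    for p in placements
                    if p.component.name == name and p.level_class == cls
                ]
                assert max(zs) - min(zs) <= 1

    def test_fimbrin_and_villin_are_vertically_staggered(self, placements):
        """On any edge the two species bind distinct monomer levels."""
        by_edge = {}
        for p in placements:
            key = (p.edge.i, p.edge.j, p.repeat_index)
            by_edge.setdefault(key, {})[p.component.name] = {
                dp.monomer for dp in p.domains
            }
        for species in by_edge.values():
            assert species["fimbrin"].isdisjoint(species["villin"])

    def test_three_distinct_vertical_levels(self, placements):
        levels = {
            cls: {
                min(dp.monomer for dp in p.domains) % 13
                for p in placements
                if p.component.name == "fimbrin" and p.level_class == cls
            }
            for cls in ("d", "e", "f")
        }
        all_levels = [lv for s in levels.values() for lv in s]
        assert len(set(all_levels)) == len(all_levels)  # classes do not overlap

    def test_too_short_bundle_gives_no_placements(self, actin_sym, lattice19):
        stub = build_bundle(actin_sym, lattice19, 30.0)  # 10 monomers < 13
        assert (
            place_all_crosslinkers(stub, fimbrin_spec(), villin_spec()) == []
        )


class TestPlaceMyosin:
    def test_two_per_repeat_per_outer_filament_plus_turn_extras(self, full_build):
        motors = full_build["motors"]
        bundle = full_build["bundle"]
        base = [p for p in motors if "turn_index" not in p.extra]
        extras = [p for p in motors if "turn_index" in p.extra]
        assert len(base) == 12 * 2 * bundle.n_repeats  # 648
        assert len(extras) == bundle.monomers_per_filament // motors.turn_monomers
        assert motors.skipped == []

    def test_motors_only_on_outer_filaments_facing_outward(self, full_build):
        bundle = full_build["bundle"]
        outer = set(bundle.lattice.outer_indices())
        for p in full_build["motors"]:
            f = p.domains[0].filament
            assert f in outer
            tip = p.extra["tip"]
            anchor2d = bundle.lattice.points[f]
            assert np.linalg.norm(tip[:2]) > np.linalg.norm(anchor2d)

    def test_adjacent_outer_filament_step_is_one_long_helix_monomer(
        self, full_build
    ):
        """Moving to the next outer filament shifts the motor pattern by
        two monomer indices = one monomer along the two-start long helix."""
        motors = full_build["motors"]
        bundle = full_build["bundle"]
        outer = bundle.lattice.outer_indices()
        by_fil = {}
        for p in motors:
            if "turn_index" in p.extra:
                continue
            by_fil.setdefault(p.domains[0].filament, set()).add(p.domains[0].monomer)
        for a, b in zip(outer, outer[1:]):
            shifted = {(m + 2) % 13 for m in by_fil[a]}
            assert shifted == {m % 13 for m in by_fil[b]}

    def test_unreachable_extension_threshold_gives_no_motors(self, small_bundle):
        result = place_myosin(
            small_bundle, myosin_spec(), min_radial_extension=1e6
        )
        assert len(result) == 0

    def test_rigor_lever_is_nearly_perpendicular(self, full_build):
        """Neck direction ~80 deg from the filament (z) axis."""
        p = full_build["motors"].placements[0]
        t = p.domains[0].transform
        neck_world = t.rotation @ p.component.neck_direction
        angle = np.degrees(np.arccos(abs(neck_world[2])))
        assert angle == pytest.approx(80.0, abs=1e-6)


class TestLightChains:
    def test_three_per_motor(self, full_build):
        assert len(full_build["light_chains"]) == 3 * len(full_build["motors"])

    def test_none_without_motors(self, small_bundle):
        no_motors = place_myosin(
            small_bundle, myosin_spec(), min_radial_extension=1e6
        )
        lcs = [
            q for m in no_motors for q in attach_light_chains(m, light_chain_spec())
        ]
        assert lcs == []

    def test_centers_collinear_with_neck_axis(self, full_build):
        motor = full_build["motors"].placements[0]
        lcs = attach_light_chains(motor, light_chain_spec())
        assert len(lcs) == 3
        pts = np.array([lc.domains[0].transform.translation for lc in lcs])
        d01 = pts[1] - pts[0]
        d02 = pts[2] - pts[0]
        cross = np.linalg.norm(np.cross(d01, d02))
        assert cross < 1e-9 * np.linalg.norm(d01) * np.linalg.norm(d02) + 1e-9

    def test_light_chain_frames_require_motor(self, small_bundle, edges19):
        cands = enumerate_crosslink_candidates(
            small_bundle, fimbrin_spec(), edges19[0], 0
        )
        with pytest.raises(ParameterError):
            select_crosslink(cands, fimbrin_spec()).light_chain_frames()


class TestBarberPole:
    def test_double_helix_with_lattice_transfer_pitch(self, full_build):
        """Two strands; pitch = 12 filament steps x 2 monomers = 24 rises."""
        n, pitch, hand = barber_pole_parameters(
            full_build["motors"].placements, full_build["bundle"]
        )
        assert n == 2
        assert pitch == pytest.approx(24 * ACTIN_RISE, rel=1e-6)
        assert hand == "right"

    def test_single_motor_is_insufficient(self, full_build):
        with pytest.raises(InsufficientDataError):
            barber_pole_parameters(
                full_build["motors"].placements[:1], full_build["bundle"]
            )


def _brute_force_clashes(placements, overlap_factor):
    out = set()
    beads = []
    for idx, p in enumerate(placements):
        for c, r, lab in p.world_beads():
            beads.append((idx, c, r, lab, p))
    for x in range(len(beads)):
        for y in range(x + 1, len(beads)):
            ia, ca, ra, la, pa = beads[x]
            ib, cb, rb, lb, pb = beads[y]
            if ia == ib or pa.parent is pb or pb.parent is pa:
                continue
            if np.linalg.norm(ca - cb) < overlap_factor * (ra + rb):
                i, j = sorted((ia, ib))
                out.add((i, j))
    return out


class TestDetectClashes:
    def test_saturated_crosslinkers_do_not_clash(self, small_bundle, edges19):
        placements = place_all_crosslinkers(
            small_bundle, fimbrin_spec(), villin_spec(), edges19
        )
        assert detect_clashes(placements) == []

    def test_coincident_beads_clash(self, small_bundle, edges19):
        fim = fimbrin_spec()
        cands = enumerate_crosslink_candidates(small_bundle, fim, edges19[0], 0)
        p = select_crosslink(cands, fim)
        clashes = detect_clashes([p, p])
        assert len(clashes) >= 1
        assert clashes[0].distance == pytest.approx(0.0)

    def test_agrees_with_brute_force_oracle_on_small_bundle(self, actin_sym):
        lat = hex_points(1, 120.0)
        bundle = build_bundle(actin_sym, lat, 75.0)
        placements = place_all_crosslinkers(bundle, fimbrin_spec(), villin_spec())
        motors = place_myosin(bundle, myosin_spec(), crosslinkers=placements)
        lcs = [q for m in motors for q in attach_light_chains(m, light_chain_spec())]
        everything = placements + motors.placements + lcs
        fast = {(c.placement_a, c.placement_b) for c in detect_clashes(everything)}
        slow = _brute_force_clashes(everything, 0.9)
        assert fast == slow

    def test_result_independent_of_overlap_symmetry(self, small_bundle, edges19):
        fim = fimbrin_spec()
        a = select_crosslink(
            enumerate_crosslink_candidates(small_bundle, fim, edges19[0], 0), fim
        )
        b = select_crosslink(
            enumerate_crosslink_candidates(small_bundle, fim, edges19[0], 1), fim
        )
        assert detect_clashes([a, b]) == detect_clashes([b, a])
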