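"""Lattice neighborhood, interface detection, burial, domain assignment."""

import math

import numpy as np
import pytest

from tubmap import (
    DomainRules,
    LatticeSpec,
    Ligand,
    RigidTransform,
    StructureModel,
    assign_domains,
    build_neighborhood,
    interface_residues,
    make_toy_lattice,
    relative_exposure,
    surface_orientation,
    ToyLatticeParams,
)
from tubmap.structure import ResidueRecord


def _spec_like(toy, **overrides):
    kwargs = dict(
        axis_point=toy.spec.axis_point,
        axis_direction=toy.spec.axis_direction,
        longitudinal=toy.spec.longitudinal,
        lateral=toy.spec.lateral,
        contact_cutoff=toy.spec.contact_cutoff,
        ligand_cutoff=toy.spec.ligand_cutoff,
    )
    kwargs.update(overrides)
    return LatticeSpec(**kwargs)


class TestBuildNeighborhood:
    def test_identity_longitudinal_transform_is_degenerate(self, toy):
        bad = _spec_like(toy, longitudinal=RigidTransform.identity())
        with pytest.raises(ValueError, match="degenerate lattice"):
            build_neighborhood(toy.model, bad)

    def test_neighbor_centroids_at_planted_offsets(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        central = toy.model.all_coords().mean(axis=0)
        up, down = asm.neighbor_coords["longitudinal"]
        rise2 = 2 * toy.params.rise
        assert np.allclose(up.mean(axis=0) - central, [0, 0, rise2], atol=1e-6)
        assert np.allclose(down.mean(axis=0) - central, [0, 0, -rise2], atol=1e-6)
        for t, block in zip(toy.spec.lateral, asm.neighbor_coords["lateral"]):
            assert np.allclose(block.mean(axis=0), t.apply(central[None])[0], atol=1e-6)

    def test_translation_beyond_cutoff_gives_no_contacts(self, toy):
        far = _spec_like(
            toy,
            longitudinal=RigidTransform(np.eye(3), np.array([0.0, 0.0, 80.0])),
        )
        asm = build_neighborhood(toy.model, far)
        assert interface_residues(asm, "longitudinal", 4.5) == set()

    def test_central_coordinates_unchanged(self, toy):
        before = toy.model.all_coords().copy()
        build_neighborhood(toy.model, toy.spec)
        assert np.array_equal(before, toy.model.all_coords())


class TestInterfaceResidues:
    def test_planted_contact_sets_recovered(self, toy):
        """Geometric interface sets equal the construction-time sets."""
        asm = build_neighborhood(toy.model, toy.spec)
        p = toy.params
        expected_long = set()
        expected_intra = set()
        for row in toy.ground_truth.itertuples():
            idx = row.resnum - 1
            k = idx // (p.n_shell * p.n_theta)
            role = "alpha" if row.chain == "A" else "beta"
            long_level = 0 if role == "alpha" else p.n_z - 1
            intra_level = p.n_z - 1 if role == "alpha" else 0
            if k == long_level:
                expected_long.add((row.chain, row.resnum))
            if k == intra_level:
                expected_intra.add((row.chain, row.resnum))
        assert interface_residues(asm, "longitudinal", 4.5) == expected_long
        assert interface_residues(asm, "intradimer", 4.5) == expected_intra

    def test_tiny_cutoff_gives_empty_set(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        assert interface_residues(asm, "lateral", 0.1) == set()

    def test_nested_cutoffs_are_monotone(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        for which in ("longitudinal", "lateral", "intradimer"):
            assert interface_residues(asm, which, 4.0) <= interface_residues(
                asm, which, 5.0
            )

    def test_unknown_interface_rejected(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        with pytest.raises(ValueError, match="unknown interface"):
            interface_residues(asm, "diagonal", 4.5)


class TestSurfaceOrientation:
    def test_buried_residue_faces_neither(self, toy):
        res = toy.model.residues[0]
        assert (
            surface_orientation(toy.model, toy.spec, res, exposure=0.0) == "neither"
        )

    def test_planted_outer_probes_face_outward(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        expo = relative_exposure(asm)
        labels = toy.planted_labels()
        outer = [
            r for r in toy.model.residues
            if labels[(r.chain_id, r.residue_number)] == "MAP binding"
        ]
        assert outer
        for r in outer:
            key = (r.chain_id, r.residue_number)
            assert surface_orientation(toy.model, toy.spec, r, expo[key]) == "outer"

    def test_radial_reflection_swaps_outer_and_luminal(self, toy):
        """Mirroring radii about the chain median flips the facing label."""
        asm = build_neighborhood(toy.model, toy.spec)
        expo = relative_exposure(asm)
        chain_a = toy.model.chain("A")
        median = float(
            np.median(toy.spec.radial(np.vstack([r.centroid for r in chain_a])))
        )
        flipped = 0
        for r in chain_a:
            key = (r.chain_id, r.residue_number)
            before = surface_orientation(
                toy.model, toy.spec, r, expo[key], chain_median_radius=median
            )
            if before == "neither":
                continue
            mirrored_atoms = []
            for name, x, y, z in r.atoms:
                v = np.array([x, y, 0.0])
                rad = np.linalg.norm(v)
                v2 = v * ((2 * median - rad) / rad)
                mirrored_atoms.append((name, v2[0], v2[1], z))
            mirrored = ResidueRecord(
                r.chain_id, r.residue_number, r.amino_acid, mirrored_atoms
            )
            after = surface_orientation(
                toy.model, toy.spec, mirrored, expo[key], chain_median_radius=median
            )
            assert {before, after} == {"outer", "luminal"}
            flipped += 1
        assert flipped > 0


class TestAssignDomains:
    def test_gtp_precedence_beats_every_interface(self, toy, toy_partition):
        """Pocket residues are labeled GTP binding even at an interface."""
        pockets = {
            (row.chain, row.resnum)
            for row in toy.ground_truth.itertuples()
            if row.planted_label == "GTP binding"
        }
        assert pockets
        for key in pockets:
            assert toy_partition.label_of[key] == "GTP binding"
        # and the pocket pair of the alpha chain also touches the partner rules:
        # evidence keeps the full trace
        for key in pockets:
            assert any("nucleotide" in e for e in toy_partition.evidence_of[key])

    def test_buried_non_interface_residue_falls_through_to_other(
        self, toy, toy_partition
    ):
        others = [
            k for k, v in toy.planted_labels().items() if v == "other"
        ]
        assert others
        for key in others:
            assert toy_partition.label_of[key] == "other"
            assert toy_partition.evidence_of[key] == []

    def test_partition_is_total_and_exclusive(self, toy, toy_partition):
        assert set(toy_partition.label_of) == {
            (r.chain_id, r.residue_number) for r in toy.model.residues
        }
        assert sum(toy_partition.counts().values()) == toy.model.n_residues

    def test_rigid_motion_invariance(self, toy):
        """A global rigid motion of structure + lattice leaves labels fixed."""
        part0 = assign_domains(toy.model, toy.spec)
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        g = RigidTransform(q, rng.normal(size=3) * 20)

        def conj(t: RigidTransform) -> RigidTransform:
            gi = g.inverse()
            rot = g.rotation @ t.rotation @ gi.rotation
            trans = g.rotation @ (t.rotation @ gi.translation + t.translation) + g.translation
            return RigidTransform(rot, trans)

        moved_res = [
            ResidueRecord(
                r.chain_id, r.residue_number, r.amino_acid,
                [
                    (name, *g.apply(np.array([[x, y, z]]))[0])
                    for name, x, y, z in r.atoms
                ],
            )
            for r in toy.model.residues
        ]
        moved_ligs = [
            Ligand(
                lg.name, lg.site,
                [
                    (name, *g.apply(np.array([[x, y, z]]))[0])
                    for name, x, y, z in lg.atoms
                ],
            )
            for lg in toy.model.ligands
        ]
        moved_model = StructureModel(
            residues=moved_res, chain_roles=dict(toy.model.chain_roles),
            ligands=moved_ligs,
        )
        moved_spec = LatticeSpec(
            axis_point=g.apply(toy.spec.axis_point[None])[0],
            axis_direction=g.rotation @ toy.spec.axis_direction,
            longitudinal=conj(toy.spec.longitudinal),
            lateral=tuple(conj(t) for t in toy.spec.lateral),
            contact_cutoff=toy.spec.contact_cutoff,
            ligand_cutoff=toy.spec.ligand_cutoff,
        )
        part1 = assign_domains(moved_model, moved_spec)
        assert part1.label_of == part0.label_of

    def test_raising_cutoff_never_shrinks_interface_sets(self, toy):
        asm = build_neighborhood(toy.model, toy.spec)
        for which in ("longitudinal", "lateral", "intradimer"):
            sets = [
                interface_residues(asm, which, c) for c in (3.5, 4.5, 6.0)
            ]
            assert sets[0] <= sets[1] <= sets[2]


class TestSpecs:
    def test_lattice_spec_json_round_trip(self, toy, tmp_path):
        path = tmp_path / "spec.json"
        toy.spec.save(path)
        spec2 = LatticeSpec.load(path)
        assert np.allclose(spec2.longitudinal.translation,
                           toy.spec.longitudinal.translation)
        assert spec2.contact_cutoff == toy.spec.contact_cutoff
        assert np.allclose(spec2.lateral[0].rotation, toy.spec.lateral[0].rotation)

    def test_improper_rotation_rejected(self):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="improper"):
            RigidTransform(refl, np.zeros(3))

    def test_precedence_must_permute_the_six_labels(self):
        with pytest.raises(ValueError, match="permutation"):
            DomainRules(precedence=("GTP binding", "lateral"))
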