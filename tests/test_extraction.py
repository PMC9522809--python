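import numpy as np
import pytest

from scentmap.autoencoder import LatentMatrix
from scentmap.extraction import (
    inverse_map,
    label_lattice,
    lattice_report,
    locate_molecule,
    nearest_neuron,
    neurons_for_descriptor,
    neurons_for_descriptor_pair,
)
from scentmap.som import BMUAssignment, SOMConfig, SOMGrid
from scentmap.spectra import DescriptorTable


def _table(rows):
    """rows: {molecule: set of descriptors}"""
    names = sorted(set().union(*rows.values())) or []
    matrix = np.array(
        [[1 if d in s else 0 for d in names] for s in rows.values()], dtype=np.uint8
    ).reshape(len(rows), len(names))
    return DescriptorTable(list(rows), names, matrix)


@pytest.fixture
def toy_lattice():
    """3x2 lattice with hand-placed molecules."""
    table = _table(
        {
            "a": {"peach"},
            "b": {"coconut"},
            "c": {"spicy"},
            "d": {"warm"},
            "e": {"spicy", "warm"},
            "f": set(),
        }
    )
    asg = BMUAssignment(
        ["a", "b", "c", "d", "e", "f"],
        [(0, 0), (0, 0), (1, 0), (1, 0), (2, 1), (0, 1)],
        [0.0] * 6,
    )
    labels = label_lattice((3, 2), asg, table)
    latents = LatentMatrix(list("abcdef"), np.arange(12).reshape(6, 2) + 1.0)
    return table, asg, labels, latents


class TestLabelLattice:
    def test_same_bmu_molecules_union_their_labels(self, toy_lattice):
        _, _, labels, _ = toy_lattice
        assert labels.labels_at((0, 0)) == {"peach", "coconut"}
        assert set(labels.members_at((0, 0))) == {"a", "b"}

    def test_undescribed_molecule_is_member_without_labels(self, toy_lattice):
        _, _, labels, _ = toy_lattice
        assert labels.members_at((0, 1)) == ["f"]
        assert labels.labels_at((0, 1)) == set()

    def test_membership_conserved(self, toy_lattice):
        _, asg, labels, _ = toy_lattice
        total = sum(len(labels.members_at(c)) for c in labels.coords_row_major())
        assert total == len(asg.molecule_ids)

    def test_neuron_labels_equal_union_of_member_descriptor_sets(self, small_pipeline):
        res = small_pipeline["result"]
        for c in res.labels.coords_row_major():
            expected = set().union(
                *(res.table.descriptors_for(m) for m in res.labels.members_at(c)),
                set(),
            )
            assert res.labels.labels_at(c) == expected

    def test_excluded_descriptors_left_off_lattice(self, toy_lattice):
        table, asg, _, _ = toy_lattice
        labels = label_lattice((3, 2), asg, table, exclude={"peach"})
        assert "peach" not in labels.labels_at((0, 0))
        assert labels.labels_at((0, 0)) == {"coconut"}

    def test_out_of_bounds_assignment_rejected(self, toy_lattice):
        table, _, _, _ = toy_lattice
        bad = BMUAssignment(["a"], [(9, 9)], [0.0])
        with pytest.raises(ValueError):
            label_lattice((3, 2), bad, table)


class TestDescriptorQueries:
    def test_single_carrier_descriptor_maps_to_its_bmu(self, toy_lattice):
        _, _, labels, _ = toy_lattice
        assert neurons_for_descriptor(labels, "peach") == [(0, 0)]

    def test_unknown_descriptor_gives_empty_list(self, toy_lattice):
        _, _, labels, _ = toy_lattice
        assert neurons_for_descriptor(labels, "vanilla") == []

    def test_matches_brute_force_scan(self, small_pipeline):
        res = small_pipeline["result"]
        for d in res.table.descriptor_names:
            brute = [
                c
                for c in res.labels.coords_row_major()
                if d in res.labels.labels_at(c)
            ]
            assert neurons_for_descriptor(res.labels, d) == brute

    def test_pair_mode_distinction(self, toy_lattice):
        table, _, labels, _ = toy_lattice
        # (1,0) holds c={spicy} and d={warm} separately; (2,1) holds e with both
        on_neuron = neurons_for_descriptor_pair(labels, "spicy", "warm")
        on_molecule = neurons_for_descriptor_pair(
            labels, "spicy", "warm", table=table, mode="both_on_molecule"
        )
        assert (1, 0) in on_neuron and (2, 1) in on_neuron
        assert on_molecule == [(2, 1)]

    def test_no_cooccurrence_gives_empty(self, toy_lattice):
        _, _, labels, _ = toy_lattice
        assert neurons_for_descriptor_pair(labels, "peach", "warm") == []

    def test_molecule_mode_subset_of_neuron_mode(self, small_pipeline):
        res = small_pipeline["result"]
        names = res.table.descriptor_names
        for d1 in names[:4]:
            for d2 in names[:4]:
                if d1 == d2:
                    continue
                strict = neurons_for_descriptor_pair(
                    res.labels, d1, d2, table=res.table, mode="both_on_molecule"
                )
                loose = neurons_for_descriptor_pair(res.labels, d1, d2)
                assert set(strict) <= set(loose)


class TestLocateMolecule:
    def test_consistent_with_assignment(self, toy_lattice):
        _, asg, labels, _ = toy_lattice
        for mol, coord in zip(asg.molecule_ids, asg.bmu_coords):
            assert locate_molecule(labels, mol) == coord

    def test_unknown_id_raises_with_suggestion(self, small_pipeline):
        res = small_pipeline["result"]
        known = res.labels.bmu_of and next(iter(res.labels.bmu_of))
        with pytest.raises(KeyError, match="did you mean"):
            locate_molecule(res.labels, known.upper())

    def test_agrees_with_find_bmu_on_latents(self, small_pipeline):
        from scentmap.som import find_bmu

        res = small_pipeline["result"]
        for mol in res.latents.molecule_ids[:10]:
            assert locate_molecule(res.labels, mol) == find_bmu(
                res.grid, res.latents.row(mol)
            )


class TestInverseMap:
    def test_single_member_is_its_own_reference(self, toy_lattice):
        table, _, labels, latents = toy_lattice
        r = inverse_map(labels, latents, (2, 1), table=table, reference_id="e")
        assert r.member_ids == ["e"]
        assert r.similarity_to_reference["e"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_neuron_gives_empty_members(self, toy_lattice):
        _, _, labels, latents = toy_lattice
        r = inverse_map(labels, latents, (2, 0))
        assert r.member_ids == [] and r.member_latents.shape[0] == 0

    def test_members_equal_assignment_filter_oracle(self, small_pipeline):
        res = small_pipeline["result"]
        asg = res.assignments
        for c in [(0, 0), (3, 2), (5, 4)]:
            brute = [
                m for m, bc in zip(asg.molecule_ids, asg.bmu_coords) if bc == c
            ]
            r = inverse_map(res.labels, res.latents, c)
            assert r.member_ids == brute

    def test_extraction_closure(self, small_pipeline):
        """Every molecule is a member of its own BMU's extraction."""
        res = small_pipeline["result"]
        for mol in res.latents.molecule_ids:
            c = locate_molecule(res.labels, mol)
            assert mol in inverse_map(res.labels, res.latents, c).member_ids

    def test_raw_spectrum_representation_also_scores(self, small_pipeline):
        res = small_pipeline["result"]
        mol = res.latents.molecule_ids[0]
        c = locate_molecule(res.labels, mol)
        r = inverse_map(res.labels, res.matrix, c, reference_id=mol)
        assert r.member_latents.shape[1] == 212
        assert r.similarity_to_reference[mol] == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_neuron_rejected(self, toy_lattice):
        _, _, labels, latents = toy_lattice
        with pytest.raises(ValueError):
            inverse_map(labels, latents, (99, 0))


class TestNearestNeuron:
    def _grid(self, w=5, h=4):
        return SOMGrid(SOMConfig(width=w, height=h), np.zeros((h, w, 2)))

    def test_adjacent_satisfying_neuron_wins(self):
        g = self._grid()
        target = (3, 2)
        got = nearest_neuron(g, (2, 2), lambda c: c == target)
        assert got == target
        assert np.linalg.norm(g.planar(got) - g.planar((2, 2))) == pytest.approx(1.0)

    def test_origin_only_satisfier_raises(self):
        g = self._grid()
        with pytest.raises(ValueError):
            nearest_neuron(g, (1, 1), lambda c: c == (1, 1))

    def test_agrees_with_exhaustive_scan(self, rng):
        g = self._grid(6, 5)
        sat = {(0, 0), (5, 4), (2, 3), (4, 1)}
        for origin in [(0, 0), (3, 2), (5, 0)]:
            cand = [
                (np.linalg.norm(g.planar(c) - g.planar(origin)), v * 6 + h, (h, v))
                for (h, v) in g.coords_row_major()
                for c in [(h, v)]
                if c in sat and c != origin
            ]
            expected = min(cand, key=lambda t: (round(t[0], 9), t[1]))[2]
            assert nearest_neuron(g, origin, lambda c: c in sat) == expected


def test_lattice_report_covers_every_neuron(small_pipeline):
    res = small_pipeline["result"]
    df = lattice_report(res.labels)
    cfg = small_pipeline["config"].som
    assert len(df) == cfg.width * cfg.height
    assert df["members"].sum() == len(res.latents.molecule_ids)
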