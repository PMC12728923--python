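"""Variant triage: pathogenicity bins, ddG conventions, interface flags, networks."""

import numpy as np
import pytest

from helpers import two_group_trajectory

from bindscape import variant_interface as vi
from bindscape.contact_maps import ContactFrequencyMap
from bindscape.model_io import Particle, Topology, Trajectory


def simple_map(matrix):
    matrix = np.asarray(matrix, float)
    return ContactFrequencyMap(
        np.arange(1, matrix.shape[0] + 1),
        np.arange(1, matrix.shape[1] + 1),
        matrix,
        0.5,
        100,
        "all_frames",
    )


class TestPathogenicityBins:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.10, vi.BENIGN),
            (0.50, vi.AMBIGUOUS),
            (0.90, vi.PATHOGENIC),
            (0.33, vi.BENIGN),
            (0.34, vi.AMBIGUOUS),
            (0.564, vi.AMBIGUOUS),
            (0.565, vi.PATHOGENIC),
            (0.0, vi.BENIGN),
            (1.0, vi.PATHOGENIC),
        ],
    )
    def test_printed_bin_edges(self, score, expected):
        assert vi.classify_pathogenicity(score) == expected

    def test_micro_gap_goes_to_nearer_edge(self):
        assert vi.classify_pathogenicity(0.332) == vi.BENIGN
        assert vi.classify_pathogenicity(0.338) == vi.AMBIGUOUS
        # 3-decimal rounding closes the second micro-gap entirely
        assert vi.classify_pathogenicity(0.5646) == vi.PATHOGENIC
        assert vi.classify_pathogenicity(0.5643) == vi.AMBIGUOUS

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            vi.classify_pathogenicity(score)


class TestStabilityClasses:
    @pytest.mark.parametrize(
        "ddg,tool,expected",
        [
            (2.2, "FoldX", vi.DESTABILIZING),
            (-2.5, "DynaMut2", vi.DESTABILIZING),
            (1.0, "FoldX", vi.NEUTRAL),
            (-2.5, "DDMut-PPI", vi.DESTABILIZING),
            (3.0, "MutaBind2", vi.DESTABILIZING),
            (-3.0, "FoldX", vi.STABILIZING),
            (2.5, "DynaMut2", vi.STABILIZING),
            (2.0, "FoldX", vi.NEUTRAL),  # threshold is strict
        ],
    )
    def test_sign_unification_and_thresholds(self, ddg, tool, expected):
        assert vi.classify_stability(ddg, tool) == expected

    def test_unknown_tool_lists_conventions(self):
        with pytest.raises(ValueError, match="foldx"):
            vi.classify_stability(1.0, "mystery")


class TestInterfaceFlags:
    def variants(self, positions):
        return [vi.VariantRecord("REC", p, "A", "V", 0.5) for p in positions]

    def test_contacting_residue_flagged(self):
        cmap = simple_map([[0.5, 0.0], [0.0, 0.0]])
        out = vi.flag_interface(self.variants([1, 2]), cmap, tau=0.25)
        assert [v.interface for v in out] == [True, False]

    def test_monotone_in_tau(self, rng):
        cmap = simple_map(rng.uniform(size=(8, 5)))
        positions = list(range(1, 9))
        flagged_sets = []
        for tau in (0.1, 0.4, 0.7, 0.9):
            out = vi.flag_interface(self.variants(positions), cmap, tau)
            flagged_sets.append({v.position for v in out if v.interface})
        for small, large in zip(flagged_sets[1:], flagged_sets[:-1]):
            assert small <= large

    def test_residue_absent_from_axis_warns_not_raises(self):
        cmap = simple_map([[0.5]])
        with pytest.warns(UserWarning, match="not on"):
            out = vi.flag_interface(self.variants([99]), cmap, tau=0.1)
        assert out[0].interface is False

    def test_mixture_interface_matches_designed_residues(
        self, toy_complex, default_poses
    ):
        from bindscape import synthetic_data as sd
        from bindscape.contact_maps import contact_frequency

        spec = sd.MixtureSpec(
            poses=default_poses[:1], weights=[1.0], n_frames=500, seed=2
        )
        traj, _ = sd.sample_mixture(spec, toy_complex)
        cmap = contact_frequency(traj, "R", "L", cutoff=0.5)
        designed_rec = {r for r, _ in sd.designed_contacts(toy_complex, spec.poses[0], 0.37)}
        probes = self.variants(sorted(designed_rec) + [10, 60])
        out = vi.flag_interface(probes, cmap, tau=0.25)
        for v in out:
            if v.position in designed_rec:
                assert v.interface  # designed sticky residues are flagged
            else:
                assert not v.interface  # residues far from the interface are not


class TestVariantTable:
    def test_load_annotates_classes(self, tmp_path):
        path = tmp_path / "variants.csv"
        path.write_text(
            "protein,position,ref,alt,score,tool,ddg\n"
            "REC,61,P,S,0.62,FoldX,2.2\n"
            "LIG,90,R,S,0.20,DynaMut2,-2.5\n"
            "REC,12,G,D,0.45,,\n"
        )
        records = vi.load_variants(path)
        assert [r.pathogenicity_class for r in records] == [
            vi.PATHOGENIC,
            vi.BENIGN,
            vi.AMBIGUOUS,
        ]
        assert records[0].stability_class == vi.DESTABILIZING
        assert records[1].stability_class == vi.DESTABILIZING
        assert records[2].stability_class is None

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("protein,position\nX,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            vi.load_variants(path)


class TestResidueNetwork:
    def chain_of_residues(self, positions, resids=None):
        positions = np.asarray(positions, float)
        resids = resids or [2 * i + 1 for i in range(len(positions))]
        particles = [
            Particle(i, "BB", resids[i], "ALA", "A") for i in range(len(positions))
        ]
        return Trajectory(Topology(particles), positions[None])

    def test_three_node_path_oracle(self):
        # residues 1-3-5 in a line; only consecutive pairs within cutoff
        traj = self.chain_of_residues([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        stats = vi.residue_network(traj, cutoff=0.5)
        b = ("A", 3)
        assert stats.degree[b] == 2
        assert stats.betweenness[b] == pytest.approx(1.0)
        assert stats.closeness[b] == pytest.approx(1.0)
        assert stats.closeness[("A", 1)] == pytest.approx(2.0 / 3.0)

    def test_triangle_has_zero_betweenness(self):
        traj = self.chain_of_residues(
            [[0, 0, 0], [0.4, 0, 0], [0.2, 0.3, 0]]
        )
        stats = vi.residue_network(traj, cutoff=0.5)
        assert all(v == 0.0 for v in stats.betweenness.values())
        assert all(d == 2 for d in stats.degree.values())

    def test_isolated_residue_zero_centrality(self):
        traj = self.chain_of_residues(
            [[0, 0, 0], [0.4, 0, 0], [5.0, 5.0, 5.0]]
        )
        stats = vi.residue_network(traj, cutoff=0.5)
        far = ("A", 5)
        assert stats.degree[far] == 0
        assert stats.closeness[far] == 0.0

    def test_sequence_adjacent_residues_not_connected(self):
        traj = self.chain_of_residues(
            [[0, 0, 0], [0.3, 0, 0]], resids=[7, 8]
        )
        with pytest.warns(UserWarning, match="empty"):
            stats = vi.residue_network(traj, cutoff=0.5)
        assert stats.degree[("A", 7)] == 0
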