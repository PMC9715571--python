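import numpy as np
import pytest

from xlassemble.geometry import rotation_about_axis
from xlassemble.structio import ChainMap, ChainSpan
from xlassemble.xlinks import (classify_links, link_distances, parse_crosslinks,
                               satisfaction_fraction, write_crosslinks)
from xlassemble.synthetic import (build_chainmap, generate_assembly,
                                  simulate_crosslinks)

from conftest import ca_model


def write_csv(tmp_path, rows, header="protein1,residue1,protein2,residue2,fdr"):
    p = tmp_path / "links.csv"
    p.write_text("\n".join(["# synthetic fixture", header] + rows) + "\n")
    return p


CMAP = ChainMap([
    ChainSpan("WTAP", "A", 0, 171, 237),
    ChainSpan("WTAP", "B", 0, 171, 237),
    ChainSpan("VIRMA", "V", 0, 381, 1292),
])


class TestParse:
    def test_fdr_filter_drops_rows_above_threshold(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,192,VIRMA,500,0.01",
                                    "WTAP,155,VIRMA,600,0.08",
                                    "WTAP,200,WTAP,180,0.04"])
        cset = parse_crosslinks(path, fdr_threshold=0.05)
        assert len(cset) == 2
        assert all(ln.fdr <= 0.05 for ln in cset)

    def test_unordered_duplicates_merge(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,192,VIRMA,500,0.01,3",
                                    "VIRMA,500,WTAP,192,0.002,7"],
                         header="protein1,residue1,protein2,residue2,fdr,spectra")
        cset = parse_crosslinks(path)
        assert len(cset) == 1
        ln = cset.links[0]
        assert ln.fdr == 0.002          # min over duplicates
        assert ln.spectra_count == 7    # max over duplicates

    def test_missing_column_raises(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,192,VIRMA"],
                         header="protein1,residue1,protein2")
        with pytest.raises(ValueError, match="residue2"):
            parse_crosslinks(path)

    def test_non_integer_residue_raises(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,abc,VIRMA,500,0.01"])
        with pytest.raises(ValueError, match="residue1"):
            parse_crosslinks(path)

    def test_dedup_is_idempotent(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,192,VIRMA,500,0.01",
                                    "VIRMA,500,WTAP,192,0.01",
                                    "WTAP,180,WTAP,230,0.02"])
        once = parse_crosslinks(path)
        write_crosslinks(once, tmp_path / "again.csv")
        twice = parse_crosslinks(tmp_path / "again.csv")
        assert [ln.key for ln in once] == [ln.key for ln in twice]


class TestClassify:
    def test_kinds_and_unmapped_status(self, tmp_path):
        path = write_csv(tmp_path, ["WTAP,192,WTAP,180,0.01",
                                    "METTL3,576,VIRMA,899,0.01",
                                    "METTL3,13,WTAP,192,0.01"])
        cset = classify_links(parse_crosslinks(path), CMAP)
        by_key = {ln.key: ln for ln in cset}
        intra = by_key[(("WTAP", 180), ("WTAP", 192))]
        assert intra.kind == "intra_subunit"
        inter = by_key[(("METTL3", 576), ("VIRMA", 899))]
        assert inter.kind == "inter_subunit"
        # METTL3 is absent from the model: status unmapped, never dropped
        assert by_key[(("METTL3", 13), ("WTAP", 192))].status == "unmapped"
        counts = cset.counts()
        assert counts["total"] == 3
        assert counts["inter_subunit"] + counts["intra_subunit"] \
            + counts["ambiguous"] == counts["total"]
        assert counts["unmapped"] == 2  # both METTL3 links

    def test_conservation_on_simulated_set(self):
        model = generate_assembly(n_chains=3, seed=4, chain_length=40)
        cmap = build_chainmap(model)
        cset = simulate_crosslinks(model, n_true=15, decoy_rate=0.25, seed=4,
                                   cmap=cmap)
        out = classify_links(cset, cmap)
        counts = out.counts()
        assert counts["inter_subunit"] + counts["intra_subunit"] \
            + counts["ambiguous"] == counts["total"] == len(cset)
        assert counts["unmapped"] == 0


class TestDistances:
    def two_point_model(self, d):
        return ca_model({"A": [[0.0, 0.0, 0.0]], "V": [[0.0, 0.0, d]]},
                        start_res=190), ChainMap([
                            ChainSpan("WTAP", "A", 0, 190, 190),
                            ChainSpan("VIRMA", "V", 0, 190, 190)])

    def make_set(self, tmp_path, d):
        model, cmap = self.two_point_model(d)
        path = write_csv(tmp_path, ["WTAP,190,VIRMA,190,0.01"])
        return model, cmap, parse_crosslinks(path)

    def test_euclidean_distance(self, tmp_path):
        model, cmap, cset = self.make_set(tmp_path, 10.0)
        (ld,) = link_distances(model, cset, cmap, cutoff=30.0)
        assert ld.distance == pytest.approx(10.0)
        assert ld.satisfied

    def test_boundary_is_inclusive(self, tmp_path):
        model, cmap, cset = self.make_set(tmp_path, 30.0)
        (ld,) = link_distances(model, cset, cmap, cutoff=30.0)
        assert ld.distance == pytest.approx(30.0)
        assert ld.satisfied
        (ld,) = link_distances(model, cset, cmap, cutoff=29.999)
        assert not ld.satisfied

    def test_mapped_residue_without_ca_is_unmappable(self, tmp_path):
        model, cmap, cset = self.make_set(tmp_path, 10.0)
        no_ca = model.select(chains=["A"])  # VIRMA chain absent from model
        (ld,) = link_distances(no_ca, cset, cmap)
        assert ld.distance is None and ld.satisfied is None

    def test_homodimer_ambiguity_resolves_to_shorter_copy(self):
        model = ca_model({"A": [[0.0, 0.0, 0.0]], "B": [[50.0, 0.0, 0.0]],
                          "V": [[10.0, 0.0, 0.0]]}, start_res=192)
        cmap = ChainMap([ChainSpan("WTAP", "A", 0, 192, 192),
                         ChainSpan("WTAP", "B", 0, 192, 192),
                         ChainSpan("VIRMA", "V", 0, 192, 192)])
        from xlassemble.xlinks import Crosslink, CrosslinkSet
        cset = CrosslinkSet([Crosslink("WTAP", 192, "VIRMA", 192)])
        (ld,) = link_distances(model, cset, cmap)
        assert ld.distance == pytest.approx(10.0)
        assert ld.assignment[0][0] == "A"

    def test_full_assembly_links_all_satisfied(self):
        model = generate_assembly(seed=9, chain_length=40)
        cmap = build_chainmap(model)
        cset = simulate_crosslinks(model, n_true=12, seed=9, cmap=cmap)
        dists = link_distances(model, cset, cmap, cutoff=30.0)
        assert satisfaction_fraction(dists)["fraction"] == 1.0

    def test_invariance_under_joint_rigid_transform(self):
        model = generate_assembly(seed=9, chain_length=40)
        cmap = build_chainmap(model)
        cset = simulate_crosslinks(model, n_true=12, seed=9, cmap=cmap)
        R = rotation_about_axis([1.0, 2.0, 3.0], 1.1)
        moved = model.transformed(R, np.array([4.0, 5.0, -6.0]))
        d0 = [ld.distance for ld in link_distances(model, cset, cmap)]
        d1 = [ld.distance for ld in link_distances(moved, cset, cmap)]
        assert np.allclose(d0, d1, atol=1e-9)

    def test_single_chain_transform_changes_inter_distances(self):
        model = generate_assembly(seed=9, chain_length=40)
        cmap = build_chainmap(model)
        cset = simulate_crosslinks(model, n_true=12, seed=9, cmap=cmap)
        moved = model.transformed(np.eye(3), np.array([20.0, 0.0, 0.0]),
                                  chains=["B"])
        d0 = np.array([ld.distance for ld in link_distances(model, cset, cmap)])
        d1 = np.array([ld.distance for ld in link_distances(moved, cset, cmap)])
        assert not np.allclose(d0, d1, atol=1e-3)


class TestSatisfaction:
    def test_fraction_eight_of_ten(self):
        model = ca_model(
            {"A": [[0.0, 0.0, 0.0]],
             "B": [[0.0, 0.0, float(z)] for z in
                   [5, 10, 15, 20, 25, 28, 29, 30, 31, 45]]})
        cmap = ChainMap([ChainSpan("P1", "A", 0, 1, 1),
                         ChainSpan("P2", "B", 0, 1, 10)])
        from xlassemble.xlinks import Crosslink, CrosslinkSet
        cset = CrosslinkSet([Crosslink("P1", 1, "P2", r) for r in range(1, 11)])
        dists = link_distances(model, cset, cmap, cutoff=30.0)
        out = satisfaction_fraction(dists)
        assert out["fraction"] == pytest.approx(0.8)
        assert out["n_violated"] == 2

    def test_zero_mappable_links_raises(self):
        model = ca_model({"A": [[0.0, 0.0, 0.0]]})
        cmap = ChainMap([ChainSpan("P1", "A", 0, 1, 1)])
        from xlassemble.xlinks import Crosslink, CrosslinkSet
        cset = CrosslinkSet([Crosslink("X", 1, "Y", 2)])
        dists = link_distances(model, cset, cmap)
        with pytest.raises(ValueError):
            satisfaction_fraction(dists)

    def test_decoy_spiked_fraction_matches_design(self):
        model = generate_assembly(seed=21, chain_length=60)
        cmap = build_chainmap(model)
        cset = simulate_crosslinks(model, n_true=30, decoy_rate=0.25, seed=21,
                                   cmap=cmap)
        dists = link_distances(model, cset, cmap, cutoff=30.0)
        out = satisfaction_fraction(dists)
        assert out["n_links"] == 40  # 30 true + 10 decoys
        assert out["fraction"] == pytest.approx(0.75)
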