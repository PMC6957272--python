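import numpy as np
import pytest

from rckring import metal, structure, synthetic
from rckring.errors import UsageError
from rckring.metal import (
    DEFAULT_ION_PROFILES,
    CoordinationShell,
    Donor,
    IonProfile,
    assess_geometry,
    find_shell,
    locate_interface_site,
    score_identity,
)

from conftest import random_rotation


def _shell_from_vectors(vectors, distance, center_b=None, donor_b=50.0):
    donors = []
    for k, v in enumerate(np.asarray(vectors, dtype=float)):
        pos = distance * v / np.linalg.norm(v)
        atom = structure.AtomRecord(
            atom_name="O", element="O", residue_number=100 + k, residue_name="HOH",
            chain_id="W", position=pos, b_factor=donor_b,
        )
        donors.append(Donor(atom=atom, element="O", distance=float(np.linalg.norm(pos)),
                            b_factor=donor_b))
    return CoordinationShell(center=np.zeros(3), center_b_factor=center_b, donors=donors)


class TestFindShell:
    def test_ideal_octahedron_has_six_donors_at_the_set_distance(self):
        frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral")
        shell = find_shell(frag, "M:1:MG")
        assert shell.cn == 6
        assert [d.distance for d in shell.donors] == pytest.approx([2.07] * 6)
        assert all(d.element == "O" for d in shell.donors)

    def test_matches_brute_force_distance_filter(self, rng):
        chains = [structure.Chain(chain_id="X")]
        elements = rng.choice(["O", "N", "C", "S"], size=200)
        coords = rng.uniform(-5, 5, size=(200, 3))
        for k, (el, pos) in enumerate(zip(elements, coords)):
            res = structure.Residue(number=k + 1, name="UNK")
            res.atoms[el] = structure.AtomRecord(
                atom_name=el, element=str(el), residue_number=k + 1, residue_name="UNK",
                chain_id="X", position=pos,
            )
            chains[0].residues.append(res)
        model = structure.StructureModel(chains=chains)
        center = np.array([0.3, -0.2, 0.1])
        shell = find_shell(model, center, cutoff=3.0)
        expected = sorted(
            float(np.linalg.norm(pos - center))
            for el, pos in zip(elements, coords)
            if el in {"O", "N"} and 0.8 < np.linalg.norm(pos - center) <= 3.0
        )
        assert [d.distance for d in shell.donors] == pytest.approx(expected)

    def test_empty_shell_is_cn_zero_not_an_error(self):
        frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral")
        shell = find_shell(frag, np.array([100.0, 100.0, 100.0]))
        assert shell.cn == 0

    def test_unresolvable_selector_is_usage_error(self):
        frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral")
        with pytest.raises(UsageError):
            find_shell(frag, "Z:9:XX")


class TestGeometry:
    @pytest.mark.parametrize("name", sorted(metal.IDEAL_POLYHEDRA))
    def test_ideal_polyhedra_are_recognized_with_zero_residual(self, name):
        shell = _shell_from_vectors(metal.IDEAL_POLYHEDRA[name], 2.2)
        out = assess_geometry(shell)
        assert out.best_polyhedron == name
        assert out.angular_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rotation_invariance(self, rng):
        verts = metal.IDEAL_POLYHEDRA["octahedral"]
        jittered = verts + rng.normal(scale=0.05, size=verts.shape)
        base = assess_geometry(_shell_from_vectors(jittered, 2.07)).angular_rmsd
        rotated = (random_rotation(rng) @ jittered.T).T
        rot = assess_geometry(_shell_from_vectors(rotated, 2.07)).angular_rmsd
        assert rot == pytest.approx(base, abs=1e-6)

    def test_jittered_octahedron_residual_tracks_the_jitter(self):
        sigma = 5.0
        residuals = []
        for seed in range(40):
            frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral",
                                                 jitter_ang=sigma, seed=seed)
            shell = find_shell(frag, "M:1:MG")
            out = assess_geometry(shell)
            assert out.best_polyhedron == "octahedral"
            residuals.append(out.angular_rmsd)
        assert abs(np.mean(residuals) - sigma) < 3 * sigma / np.sqrt(40) + 1.5

    def test_low_cn_and_scrambled_shells_are_irregular(self, rng):
        assert assess_geometry(_shell_from_vectors([[1, 0, 0], [0, 1, 0]], 2.0)).best_polyhedron == "irregular"
        scrambled = rng.normal(size=(6, 3))
        out = assess_geometry(_shell_from_vectors(scrambled, 2.0))
        # random directions essentially never look octahedral within 20 deg
        assert out.best_polyhedron == "irregular"


class TestIdentityScore:
    def test_mg_like_shell_ranks_mg_first_by_direct_formula(self):
        shell = _shell_from_vectors(metal.IDEAL_POLYHEDRA["octahedral"], 2.07)
        score = score_identity(shell)
        assert score.ranking[0] == "MG"
        terms = {t["element"]: t for t in score.terms}
        # direct evaluation: Mg deviates by nothing, Ca only in distance
        assert terms["MG"]["total"] == pytest.approx(0.0, abs=1e-9)
        assert terms["CA"]["total"] == pytest.approx(abs(2.07 - 2.39), abs=1e-9)

    def test_ca_like_shell_ranks_ca_first_by_direct_formula(self):
        shell = _shell_from_vectors(metal.IDEAL_POLYHEDRA["pentagonal-bipyramidal"], 2.39)
        score = score_identity(shell)
        assert score.ranking[0] == "CA"
        terms = {t["element"]: t for t in score.terms}
        assert terms["CA"]["total"] == pytest.approx(0.0, abs=1e-9)
        # Mg: 0.32 Å distance + CN 7 not in {6} + non-octahedral geometry
        assert terms["MG"]["total"] == pytest.approx(0.32 + 0.5 + 0.5, abs=1e-9)

    def test_b_factor_ratio_flags_lighter_ion(self):
        shell = _shell_from_vectors(metal.IDEAL_POLYHEDRA["octahedral"], 2.07,
                                    center_b=150.0, donor_b=100.0)
        score = score_identity(shell)
        assert score.b_ratio == pytest.approx(1.5)
        assert score.lighter_ion_suspected

    def test_ranking_invariant_to_donor_order_and_monotone_in_distance(self, rng):
        verts = metal.IDEAL_POLYHEDRA["octahedral"]
        shell = _shell_from_vectors(verts, 2.07)
        shuffled = CoordinationShell(
            center=shell.center, center_b_factor=None,
            donors=[shell.donors[i] for i in rng.permutation(6)],
        )
        assert score_identity(shell).ranking == score_identity(shuffled).ranking
        totals = [
            {t["element"]: t["total"] for t in score_identity(
                _shell_from_vectors(verts, d)).terms}["MG"]
            for d in (2.07, 2.2, 2.4, 2.8)
        ]
        assert totals == sorted(totals)

    def test_profile_validation(self):
        with pytest.raises(UsageError):
            IonProfile("XX", -1.0, frozenset({6}), frozenset())
        with pytest.raises(UsageError):
            IonProfile("XX", 2.0, frozenset(), frozenset())
        shell = _shell_from_vectors(metal.IDEAL_POLYHEDRA["octahedral"], 2.07)
        with pytest.raises(UsageError):
            score_identity(shell, profiles=[])

    def test_jittered_replicates_rank_correctly(self):
        """Monte-Carlo identity ranking: jittered Mg-like and Ca-like sites."""
        mg_first = ca_first = 0
        n = 100
        for seed in range(n):
            frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral",
                                                 jitter_dist=0.05, jitter_ang=5.0, seed=seed)
            if score_identity(find_shell(frag, "M:1:MG")).ranking[0] == "MG":
                mg_first += 1
            frag = synthetic.make_metal_fragment("CA", 7, 2.39, "pentagonal-bipyramidal",
                                                 jitter_dist=0.05, jitter_ang=5.0, seed=seed)
            if score_identity(find_shell(frag, "M:1:CA")).ranking[0] == "CA":
                ca_first += 1
        assert mg_first >= 0.99 * n
        assert ca_first >= 0.99 * n


class TestInterfaceSite:
    def test_donors_on_a_sphere_give_equal_distances(self):
        frag = synthetic.make_metal_fragment("MG", 6, 2.3, "octahedral")
        selectors = [f"W:{101 + k}:O" for k in range(6)]
        site = locate_interface_site(frag, selectors[:2], selectors[2:])
        assert list(site.donor_distances.values()) == pytest.approx([2.3] * 6)
        assert np.linalg.norm(site.center) == pytest.approx(0.0, abs=1e-9)
        # centroid of the donor set recovers the deposited metal position
        assert np.linalg.norm(site.center - np.zeros(3)) < 1.0

    def test_missing_carboxylate_donor_is_reported(self):
        frag = synthetic.make_metal_fragment("MG", 6, 2.07, "octahedral")
        selectors = [f"W:{101 + k}:O" for k in range(6)]
        site = locate_interface_site(frag, selectors[:2], selectors[2:4] + ["W:999:O"])
        assert site.missing == ["W:999:O"]
        with pytest.raises(UsageError):
            locate_interface_site(frag, ["W:999:O"], ["W:998:O"])
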