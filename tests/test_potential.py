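import numpy as np
import pytest

from loopgrow import chemistry
from loopgrow.fixtures import FixtureSpec, make_protein
from loopgrow.potential import (
    AtomSet,
    BinSpec,
    PairCounts,
    TypingError,
    assign_atom_type,
    atom_type_scheme,
    atoms_from_residues,
    build_potential,
    count_expected,
    count_observed,
    environment_atom_set,
    fragment_energy,
    loop_atom_set,
    pair_energy,
    score_loop,
)

SPEC = BinSpec()


class TestAtomTyping:
    def test_backbone_names_map_to_backbone_ids(self):
        scheme = atom_type_scheme()
        for res in chemistry.AMINO_ACIDS:
            for name, tid in (("N", 0), ("CA", 1), ("C", 2), ("O", 3)):
                assert scheme.assign(res, name) == tid

    def test_one_sulfur_type(self):
        assert assign_atom_type("CYS", "SG") == assign_atom_type("MET", "SD")

    def test_exactly_twenty_types_all_used(self):
        scheme = atom_type_scheme()
        assert scheme.n_types == 20
        used = set()
        for res in chemistry.AMINO_ACIDS:
            used.update(scheme.assign(res, "N") for _ in [0])
            used.add(scheme.assign(res, "CA"))
            used.add(scheme.assign(res, "C"))
            used.add(scheme.assign(res, "O"))
            for atom in chemistry.sidechain_atom_names(res):
                used.add(scheme.assign(res, atom))
        assert used == set(range(20))

    def test_sidechain_class_partition(self):
        """6 carbon, 6 nitrogen, 3 oxygen, 1 sulfur side-chain classes."""
        classes = chemistry.atom_type_table()["side_chain_classes"]
        assert [len(classes[k]) for k in ("carbon", "nitrogen", "oxygen", "sulfur")] == [6, 6, 3, 1]

    def test_unknown_atom_rejected(self):
        with pytest.raises(TypingError):
            assign_atom_type("ALA", "XX9")


class TestBinSpec:
    def test_edge_cases(self):
        spec = BinSpec(r_lo=2.0, r_hi=8.0, w=0.2)
        assert spec.bin_of(0.0) == 0
        assert spec.bin_of(1.999) == 0
        assert spec.bin_of(2.0) == 1
        assert spec.bin_of(7.999) == spec.n_bins - 1
        assert spec.bin_of(8.0) is None
        assert spec.bin_of(12.0) is None
        assert spec.n_bins == 31

    def test_vectorized_matches_scalar(self, rng):
        spec = BinSpec()
        d = rng.uniform(0, 10, 500)
        mask, bins = spec.bins_of(d)
        for i, dist in enumerate(d):
            b = spec.bin_of(float(dist))
            assert mask[i] == (b is not None)
            if b is not None:
                assert bins[i] == b

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BinSpec(r_lo=8.0, r_hi=2.0)


def _tiny_structure():
    st, asn = make_protein(FixtureSpec(plan=[("H", 5), ("C", 5), ("H", 5)], seed=21))
    return st


def _brute_force_score(structure, start, end, potential):
    """Independent O(n^2) reference: every unordered heavy-atom pair with at
    least one loop atom, minus same-residue and peptide-bond 1-2/1-3 pairs."""
    chain = structure.chains[0]
    atoms = []
    for i, res in enumerate(chain.residues):
        for name, xyz in res.atoms.items():
            atoms.append((i, res.name, name, xyz))
    excluded_names = {("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")}
    total = 0.0
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            ia, ra, na, xa = atoms[a]
            ib, rb, nb, xb = atoms[b]
            in_loop_a = start <= ia <= end
            in_loop_b = start <= ib <= end
            if not (in_loop_a or in_loop_b):
                continue
            if ia == ib:
                continue
            if abs(ia - ib) == 1:
                first, second = (na, nb) if ia < ib else (nb, na)
                fkey = first if first in ("N", "CA", "C", "O") else "X"
                skey = second if second in ("N", "CA", "C", "O") else "X"
                if (fkey, skey) in excluded_names:
                    continue
            d = float(np.linalg.norm(xa - xb))
            bin_idx = potential.spec.bin_of(d)
            if bin_idx is None:
                continue
            ta = assign_atom_type(ra, na)
            tb = assign_atom_type(rb, nb)
            total += float(potential.energy[ta, tb, bin_idx])
    return total


@pytest.fixture(scope="module")
def random_potential():
    n = atom_type_scheme().n_types
    rng = np.random.default_rng(77)
    e = rng.normal(0, 1, (n, n, SPEC.n_bins))
    e = 0.5 * (e + e.transpose(1, 0, 2))
    from loopgrow.potential import PairPotential

    return PairPotential(spec=SPEC, energy=e)


class TestCountsAndEnergy:
    def test_score_matches_brute_force(self, random_potential):
        st = _tiny_structure()
        start, end = 5, 9
        loop = loop_atom_set(st, "A", start, end)
        env = environment_atom_set(st, "A", start, end)
        fast = score_loop(loop, env, random_potential)
        slow = _brute_force_score(st, start, end, random_potential)
        assert abs(fast - slow) < 1e-9

    def test_single_atom_vacuum_zero(self, random_potential):
        a = AtomSet(np.zeros((1, 3)), np.zeros(1, int), np.zeros(1, int), np.zeros(1, int))
        assert score_loop(a, AtomSet.empty(), random_potential) == 0.0

    def test_fragment_energies_telescope_to_score(self, random_potential):
        """Adding per-residue fragments in growth order reproduces the full
        loop score exactly."""
        st = _tiny_structure()
        start, end = 5, 9
        chain = st.chains[0]
        env = environment_atom_set(st, "A", start, end)
        total = 0.0
        grown = AtomSet.empty()
        for i in range(start, end + 1):
            frag = atoms_from_residues([chain.residues[i]], 0, [i])
            ctxt = AtomSet.concat([env, grown])
            total += fragment_energy(frag, ctxt, random_potential)
            grown = AtomSet.concat([grown, frag])
        full = score_loop(
            loop_atom_set(st, "A", start, end), env, random_potential
        )
        assert abs(total - full) < 1e-9

    def test_doubling_database_doubles_counts(self):
        st = _tiny_structure()
        entry = (
            loop_atom_set(st, "A", 5, 9),
            environment_atom_set(st, "A", 5, 9),
        )
        one = count_observed([entry], SPEC)
        two = count_observed([entry, entry], SPEC)
        assert np.array_equal(two.counts, 2 * one.counts)

    def test_pair_beyond_range_not_counted(self):
        pos = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        a = AtomSet(pos[:1], np.array([0]), np.array([0]), np.array([0]))
        b = AtomSet(pos[1:], np.array([1]), np.array([500]), np.array([1]))
        pc = PairCounts(SPEC)
        pc.accumulate(a, b, same_set=False)
        assert pc.counts.sum() == 0


class TestBuildPotential:
    def _counts(self, fill_obs, fill_exp):
        n_obs, n_exp = PairCounts(SPEC), PairCounts(SPEC)
        n_obs.counts[:] = fill_obs
        n_exp.counts[:] = fill_exp
        return n_obs, n_exp

    def test_equal_probabilities_give_zero(self):
        n_obs, n_exp = self._counts(4.0, 8.0)  # identical distributions
        pot = build_potential(n_obs, n_exp)
        assert np.allclose(pot.energy[:, :, 1:], 0.0)

    def test_e_fold_ratio_gives_minus_one(self):
        n_obs, n_exp = self._counts(1.0, 1.0)
        i, j, b = 2, 5, 7
        n_obs.counts[i, j, b] = n_obs.counts[j, i, b] = np.e
        pot = build_potential(n_obs, n_exp)
        # observed probability is e times expected up to the tiny shift in
        # the normalizer; verify against the exact closed form
        expected = -np.log(
            (np.e / n_obs.total) / (1.0 / n_exp.total)
        )
        assert abs(pot.energy[i, j, b] - expected) < 1e-12
        assert abs(expected + 1.0) < 0.01

    def test_subcontact_bin_is_clash_constant(self):
        n_obs, n_exp = self._counts(3.0, 3.0)
        pot = build_potential(n_obs, n_exp, clash_energy=10.0)
        assert np.all(pot.energy[:, :, 0] == 10.0)

    def test_zero_cells_capped(self):
        n_obs, n_exp = self._counts(2.0, 2.0)
        n_obs.counts[4, 4, 5] = 0.0
        pot = build_potential(n_obs, n_exp, cap=3.0)
        assert pot.energy[4, 4, 5] == 3.0

    def test_symmetry(self, bundle):
        e = bundle.potential.energy
        assert np.array_equal(e, e.transpose(1, 0, 2))

    def test_all_zero_rejected(self):
        n_obs, n_exp = self._counts(0.0, 0.0)
        with pytest.raises(ValueError):
            build_potential(n_obs, n_exp)


class TestExpectedCounts:
    def test_decoys_identical_to_native_give_equal_counts(self):
        st = _tiny_structure()
        entry = (loop_atom_set(st, "A", 5, 9), environment_atom_set(st, "A", 5, 9))
        n_obs = count_observed([entry], SPEC)
        n_exp = count_expected([[entry, entry, entry]], SPEC)
        assert np.allclose(n_obs.counts, n_exp.counts)
        pot = build_potential(n_obs, n_exp)
        nonzero = (n_obs.counts > 0) & (n_exp.counts > 0)
        nonzero[:, :, 0] = False
        assert np.allclose(pot.energy[nonzero], 0.0)

    def test_mean_over_decoys(self):
        a = AtomSet(np.zeros((1, 3)), np.array([2]), np.array([0]), np.array([2]))
        near = AtomSet(np.array([[5.0, 0, 0]]), np.array([3]), np.array([900]), np.array([3]))
        far = AtomSet(np.array([[50.0, 0, 0]]), np.array([3]), np.array([900]), np.array([3]))
        # decoy 1 has the pair in range, decoy 2 does not -> expected 0.5
        n_exp = count_expected([[(a, near), (a, far)]], SPEC)
        assert n_exp.counts.max() == 0.5
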