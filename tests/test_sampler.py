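import numpy as np
import pytest

from loopgrow.fixtures import make_loop_target, make_packed_protein
from loopgrow.loopdb_io import identify_loops
from loopgrow.potential import atoms_from_residues, environment_atom_set, score_loop
from loopgrow.redcell import InfeasibleAnchorsError
from loopgrow.sampler import (
    Ensemble,
    LoopConformation,
    LoopSpec,
    SamplerConfig,
    build_side_chains,
    rank_and_report,
    sample_ensemble,
    sample_loop,
)


@pytest.fixture(scope="module")
def target():
    """Held-out packed fixture with a coil region, plus a 4-residue excision."""
    rng = np.random.default_rng(424242)
    st, asn = make_packed_protein([("H", 6), ("C", 8), ("E", 6)], rng, redraw_plan=False)
    region = identify_loops(st, asn)[0]
    start, end = region.start + 1, region.start + 4
    trunc, spec, native = make_loop_target(st, "A", start, end)
    return st, trunc, spec, native


class TestSampleLoop:
    def test_closed_backbone_with_valid_junction(self, target, bundle):
        _, trunc, spec, native = target
        conf = sample_loop(trunc, spec, bundle, SamplerConfig(), np.random.default_rng(0))
        assert len(conf.residues) == spec.length
        for r in conf.residues:
            assert set(r.atoms) >= {"N", "CA", "C", "O"}
        assert conf.closure_residual_bond <= 1e-4
        assert conf.closure_residual_angle <= 1e-3

    def test_seeded_determinism(self, target, bundle):
        _, trunc, spec, _ = target
        a = sample_loop(trunc, spec, bundle, SamplerConfig(), np.random.default_rng(7))
        b = sample_loop(trunc, spec, bundle, SamplerConfig(), np.random.default_rng(7))
        for ra, rb in zip(a.residues, b.residues):
            for k in ra.atoms:
                assert np.array_equal(ra.atoms[k], rb.atoms[k])

    def test_infeasible_anchors_rejected_before_sampling(self, target, bundle):
        _, trunc, spec, _ = target
        far = trunc.copy()
        for res in far.chain(spec.chain_id).residues[spec.end + 1 :]:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([100.0, 0, 0])
        with pytest.raises(InfeasibleAnchorsError):
            sample_loop(far, spec, bundle, SamplerConfig(), np.random.default_rng(0))

    def test_telescoping_energy_identity(self, target, bundle):
        """Sum of per-step fragment energies equals the full backbone score
        against the Redcell environment, exactly."""
        from loopgrow.sampler import _Context

        _, trunc, spec, _ = target
        cfg = SamplerConfig()
        ctx = _Context(trunc, spec, bundle, cfg)
        for seed in range(5):
            conf = sample_loop(trunc, spec, bundle, cfg, np.random.default_rng(seed), _ctx=ctx)
            loop_atoms = atoms_from_residues(
                conf.residues, ctx.chain_index, range(spec.start, spec.end + 1)
            )
            full = score_loop(loop_atoms, ctx.env, bundle.potential)
            assert conf.backbone_energy == pytest.approx(full, abs=1e-9)


class TestSideChains:
    def test_full_atom_build_and_rescore(self, target, bundle):
        from loopgrow.sampler import _Context

        _, trunc, spec, _ = target
        cfg = SamplerConfig()
        ctx = _Context(trunc, spec, bundle, cfg)
        rng = np.random.default_rng(3)
        conf = sample_loop(trunc, spec, bundle, cfg, rng, _ctx=ctx)
        backbone_before = conf.backbone_coords()
        conf = build_side_chains(conf, trunc, bundle, cfg, rng, _ctx=ctx)
        # backbone untouched by side-chain construction / clash resolution
        assert np.array_equal(backbone_before, conf.backbone_coords())
        # energy equals an independent re-score of the full-atom loop
        loop_atoms = atoms_from_residues(
            conf.residues, ctx.chain_index, range(spec.start, spec.end + 1)
        )
        assert conf.energy == pytest.approx(
            score_loop(loop_atoms, ctx.env, bundle.potential), abs=1e-9
        )
        # every non-glycine residue has its side-chain atoms
        from loopgrow import chemistry

        for r in conf.residues:
            if r.name != "GLY":
                assert set(chemistry.sidechain_atom_names(r.name)) <= set(r.atoms)


class TestEnsemble:
    def test_singleton(self, target, bundle):
        _, trunc, spec, native = target
        ens = sample_ensemble(trunc, spec, 1, bundle, SamplerConfig(), seed=5,
                              native=native, with_side_chains=False)
        assert len(ens) == 1

    def test_same_seed_identical(self, target, bundle):
        _, trunc, spec, native = target
        a = sample_ensemble(trunc, spec, 3, bundle, SamplerConfig(), seed=9,
                            native=native, with_side_chains=False)
        b = sample_ensemble(trunc, spec, 3, bundle, SamplerConfig(), seed=9,
                            native=native, with_side_chains=False)
        assert np.array_equal(a.energies, b.energies)
        assert np.array_equal(a.rmsd4, b.rmsd4)

    def test_prefix_property(self, target, bundle):
        """Nested seeded ensembles share their prefix, so min-RMSD is
        non-increasing in n."""
        _, trunc, spec, native = target
        small = sample_ensemble(trunc, spec, 4, bundle, SamplerConfig(), seed=11,
                                native=native, with_side_chains=False)
        big = sample_ensemble(trunc, spec, 8, bundle, SamplerConfig(), seed=11,
                              native=native, with_side_chains=False)
        assert np.array_equal(big.energies[:4], small.energies)
        assert big.rmsd4.min() <= small.rmsd4.min()


class TestRankAndReport:
    def _fake_ensemble(self, energies, rmsds):
        confs = [
            LoopConformation(residues=[], start=0, end=0, chain_id="A", energy=e)
            for e in energies
        ]
        return Ensemble(
            conformations=confs,
            energies=np.asarray(energies, dtype=float),
            rmsd4=np.asarray(rmsds, dtype=float) if rmsds is not None else None,
            rmsd3=None,
        )

    def test_hand_built_statistics(self):
        ens = self._fake_ensemble([1.0, 0.0], [2.0, 3.0])
        rep = rank_and_report(ens)
        assert rep["rmsd_of_lowest_energy"] == 3.0
        assert rep["min_rmsd"] == 2.0
        assert rep["ensemble_mean_rmsd"] == 2.5

    def test_singleton_statistics_coincide(self):
        rep = rank_and_report(self._fake_ensemble([5.0], [1.25]))
        assert rep["min_rmsd"] == rep["ensemble_mean_rmsd"] == rep["rmsd_of_lowest_energy"] == 1.25

    def test_tie_broken_by_lower_index(self):
        rep = rank_and_report(self._fake_ensemble([2.0, 2.0, 3.0], [1.0, 0.5, 0.1]))
        assert rep["lowest_energy_index"] == 0

    def test_permutation_invariance(self, rng):
        e = rng.normal(0, 1, 10)
        r = rng.uniform(0, 5, 10)
        rep = rank_and_report(self._fake_ensemble(e, r))
        perm = rng.permutation(10)
        rep2 = rank_and_report(self._fake_ensemble(e[perm], r[perm]))
        for k in ("min_rmsd", "ensemble_mean_rmsd", "rmsd_of_lowest_energy"):
            assert rep[k] == pytest.approx(rep2[k])

    def test_no_native_no_rmsd_fields(self):
        rep = rank_and_report(self._fake_ensemble([1.0, 2.0], None))
        assert "min_rmsd" not in rep
        assert "ranked" in rep


class TestClashFreedom:
    def test_reported_conformations_clash_free_or_flagged(self, target, bundle):
        _, trunc, spec, native = target
        ens = sample_ensemble(trunc, spec, 5, bundle, SamplerConfig(), seed=21,
                              native=native, with_side_chains=True)
        from loopgrow import chemistry
        from loopgrow.sampler import _Context, _clash_pairs

        ctx = _Context(trunc, spec, bundle, SamplerConfig())
        for conf in ens.conformations:
            if "clash_unresolved" in conf.flags:
                continue
            assert not _clash_pairs(ctx, conf, SamplerConfig().clash_ratio)
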