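import numpy as np
import pandas as pd
import pytest

from panicleqtl import qtl_mapping as qm
from panicleqtl import simulate as sim
from panicleqtl.io_formats import GenotypeMatrix, LinkageMap, P1_HOM, P2_HOM, MISSING


class TestKosambi:
    def test_zero_recombination_zero_distance(self):
        assert qm.kosambi_distance(0.0) == 0.0
        assert qm.kosambi_recfrac(0.0) == 0.0

    def test_round_trip(self):
        assert qm.kosambi_recfrac(qm.kosambi_distance(0.2)) == pytest.approx(0.2, abs=1e-12)

    def test_closed_form_value(self):
        # 25 ln(1.5/0.5) = 25 ln 3
        assert qm.kosambi_distance(0.25) == pytest.approx(25 * np.log(3.0), abs=1e-9)
        assert qm.kosambi_distance(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_invalid_recombination_fraction_rejected(self):
        with pytest.raises(ValueError):
            qm.kosambi_distance(0.5)


def _geno_from_calls(calls, chrom="c1"):
    lines = [f"L{i}" for i in range(calls.shape[0])]
    markers = [f"m{j}" for j in range(calls.shape[1])]
    info = pd.DataFrame(
        {"chromosome": chrom, "order": np.arange(calls.shape[1])}, index=markers
    )
    return GenotypeMatrix(pd.DataFrame(calls, index=lines, columns=markers), info)


class TestLinkageMap:
    def test_identical_columns_give_zero_interval(self):
        col = np.array([P1_HOM] * 6 + [P2_HOM] * 2)
        geno = _geno_from_calls(np.column_stack([col, col]))
        est = qm.estimate_linkage_map(geno)
        assert est.table["position_cm"].tolist() == [0.0, 0.0]

    def test_positions_nondecreasing(self, sim_bundle):
        _, geno, _, _ = sim_bundle
        est = qm.estimate_linkage_map(geno)
        for chrom in est.chromosomes:
            assert np.all(np.diff(est.positions(chrom).to_numpy()) >= 0)

    def test_simulation_round_trip_recovers_intervals(self):
        """n=300 BILs on a known 100 cM map: interval lengths recovered to
        within 10% on average (single-interval estimates are noisy; the
        average over the 20 intervals checks calibration of the expansion
        model)."""
        cfg = sim.SimConfig(
            seed=404, n_lines=300, chromosomes={"c1": 100.0}, marker_spacing_cm=5.0
        )
        geno, lmap = sim.simulate_genomes(cfg)
        est = qm.estimate_linkage_map(geno)
        true_iv = np.diff(lmap.table["position_cm"].to_numpy())
        est_iv = np.diff(est.table["position_cm"].to_numpy())
        rel_err = (est_iv - true_iv) / true_iv
        assert abs(rel_err.mean()) <= 0.10
        # total map length also within 10%
        assert est_iv.sum() == pytest.approx(true_iv.sum(), rel=0.10)

    def test_no_coobserved_lines_names_the_pair(self):
        calls = np.array([[P1_HOM, MISSING], [P2_HOM, MISSING]])
        geno = _geno_from_calls(calls)
        with pytest.raises(ValueError, match="m0.*m1"):
            qm.estimate_linkage_map(geno)


def _two_marker_grid(d_cm, calls, step=None):
    geno = _geno_from_calls(calls)
    lmap = LinkageMap(
        pd.DataFrame(
            {"chromosome": ["c1", "c1"], "position_cm": [0.0, d_cm]},
            index=pd.Index(["m0", "m1"], name="marker"),
        )
    )
    return qm.genotype_probabilities(geno, lmap, step_cm=step or d_cm / 2)


class TestGenotypeProbabilities:
    def test_observed_marker_anchors_probability(self, sim_bundle):
        """An observed call pins the posterior unless its neighbour
        contradicts it (an isolated discordance is ambiguous between a
        genotyping error and a double recombinant, so it is excluded)."""
        _, geno, lmap, _ = sim_bundle
        grid = qm.genotype_probabilities(geno, lmap, step_cm=5.0)
        pos = grid.positions
        m0, m1 = geno.markers_on("chr01")[:2]
        j = pos.index[(pos["chromosome"] == "chr01") & (pos["position_cm"] == 0.0)][0]
        calls = geno.calls[m0].to_numpy()
        neighbor = geno.calls[m1].to_numpy()
        checked = 0
        for i, call in enumerate(calls):
            if call not in (P1_HOM, P2_HOM) or neighbor[i] != call:
                continue
            checked += 1
            assert grid.probs[i, j, 0 if call == P1_HOM else 1] >= 1 - 10 * 1e-4
        assert checked > 50

    def test_single_missing_marker_returns_bc1_prior(self):
        calls = np.array([[MISSING], [P1_HOM]])
        geno = _geno_from_calls(calls)
        lmap = LinkageMap(
            pd.DataFrame(
                {"chromosome": ["c1"], "position_cm": [0.0]},
                index=pd.Index(["m0"], name="marker"),
            )
        )
        grid = qm.genotype_probabilities(geno, lmap, step_cm=1.0)
        assert np.allclose(grid.probs[0, 0], [0.75, 0.25], atol=1e-9)

    def test_midpoint_matches_bayes_enumeration_oracle(self):
        """Posterior at the midpoint of two concordant markers 10 cM apart
        equals direct enumeration over the three-locus chain, and exceeds
        the unconditional prior."""
        calls = np.array([[P1_HOM, P1_HOM], [P2_HOM, P2_HOM]])
        grid = _two_marker_grid(10.0, calls)
        pos = grid.positions
        j_mid = pos.index[pos["position_cm"] == 5.0][0]

        T = qm._transition_matrices(np.array([5.0, 5.0]))
        eps = 1e-4
        for i, obs in enumerate([0, 1]):
            e = np.array([1 - eps, eps]) if obs == 0 else np.array([eps, 1 - eps])
            joint = np.zeros(2)
            for s1 in range(2):
                for smid in range(2):
                    for s2 in range(2):
                        joint[smid] += (
                            qm.BC1_PRIOR[s1] * e[s1] * T[0][s1, smid] * T[1][smid, s2] * e[s2]
                        )
            oracle = joint / joint.sum()
            assert np.allclose(grid.probs[i, j_mid], oracle, atol=1e-9)
            assert oracle[obs] > qm.BC1_PRIOR[obs]

    def test_probabilities_sum_to_one(self, sim_bundle):
        _, geno, lmap, _ = sim_bundle
        grid = qm.genotype_probabilities(geno, lmap, step_cm=10.0)
        assert np.allclose(grid.probs.sum(axis=2), 1.0, atol=1e-10)

    def test_unmapped_marker_rejected(self):
        calls = np.array([[P1_HOM, P1_HOM], [P2_HOM, P2_HOM]])
        geno = _geno_from_calls(calls)
        lmap = LinkageMap(
            pd.DataFrame(
                {"chromosome": ["c1"], "position_cm": [0.0]},
                index=pd.Index(["m0"], name="marker"),
            )
        )
        with pytest.raises(ValueError, match="missing from the map"):
            qm.genotype_probabilities(geno, lmap)


def _informative_grid(n_lines, rng):
    """One fully informative marker (complete data, zero error rate)."""
    calls = rng.choice([P1_HOM, P2_HOM], p=[0.75, 0.25], size=(n_lines, 1))
    geno = _geno_from_calls(calls)
    lmap = LinkageMap(
        pd.DataFrame(
            {"chromosome": ["c1"], "position_cm": [0.0]},
            index=pd.Index(["m0"], name="marker"),
        )
    )
    grid = qm.genotype_probabilities(geno, lmap, step_cm=1.0, error_rate=0.0)
    return calls[:, 0], geno, grid


class TestScan:
    def test_constant_phenotype_gives_zero_lods(self, rng):
        _, _, grid = _informative_grid(20, rng)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            res = qm.scan_em(np.full(20, 1.5), grid)
        assert (res.table["lod"] == 0).all()

    def test_equal_class_means_give_zero_lod(self, rng):
        calls, _, grid = _informative_grid(24, rng)
        # spread within classes but identical sample means per class
        y = np.full(24, 2.0)
        for cls in (P1_HOM, P2_HOM):
            idx = np.flatnonzero(calls == cls)
            y[idx[: len(idx) // 2]] += 0.1
            y[idx[len(idx) // 2 : 2 * (len(idx) // 2)]] -= 0.1
        res = qm.scan_em(y, grid)
        assert res.max_lod < 1e-6

    def test_matches_marker_regression_oracle_at_informative_marker(self, rng):
        """EM LOD at a complete, fully informative marker equals
        (n/2) log10(RSS0/RSS1) from least squares."""
        calls, _, grid = _informative_grid(20, rng)
        y = 10.0 + 2.0 * (calls == P2_HOM) + rng.normal(0, 1.0, 20)
        res = qm.scan_em(y, grid)
        lod_em = res.table.loc[res.table["position_cm"] == 0.0, "lod"].iloc[0]
        X = np.column_stack([np.ones(20), calls == P2_HOM])
        rss1 = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        lod_ols = (20 / 2) * np.log10(rss0 / rss1)
        assert lod_em == pytest.approx(lod_ols, abs=1e-6)

    def test_lod_invariant_to_affine_phenotype_transform(self, rng):
        calls, _, grid = _informative_grid(30, rng)
        y = 5.0 + 1.5 * (calls == P2_HOM) + rng.normal(0, 1.0, 30)
        lod1 = qm.scan_em(y, grid).table["lod"]
        lod2 = qm.scan_em(-2.5 * y + 7.0, grid).table["lod"]
        assert np.allclose(lod1, lod2, atol=1e-6)


@pytest.fixture(scope="module")
def small_scan_setup():
    cfg = sim.SimConfig(
        seed=77, n_lines=60, chromosomes={"c1": 50.0, "c2": 50.0},
        marker_spacing_cm=10.0,
    )
    geno, lmap = sim.simulate_genomes(cfg)
    grid = qm.genotype_probabilities(geno, lmap, step_cm=10.0)
    rng = np.random.default_rng(8)
    y = rng.normal(size=60)
    return y, grid


class TestPermutationThreshold:

    def test_same_seed_reproduces_threshold(self, small_scan_setup):
        y, grid = small_scan_setup
        t1, _ = qm.permutation_threshold(y, grid, n_perm=100, seed=5)
        t2, _ = qm.permutation_threshold(y, grid, n_perm=100, seed=5)
        assert t1 == t2

    def test_alpha_one_gives_minimum_of_max_lods(self, small_scan_setup):
        y, grid = small_scan_setup
        thr, maxima = qm.permutation_threshold(y, grid, n_perm=100, alpha=1.0, seed=5)
        assert thr == pytest.approx(maxima.min())

    def test_too_few_permutations_rejected(self, small_scan_setup):
        y, grid = small_scan_setup
        with pytest.raises(ValueError, match="100"):
            qm.permutation_threshold(y, grid, n_perm=50)


class TestSupportInterval:
    def _scan_from_profile(self, pos, lod):
        table = pd.DataFrame(
            {"chromosome": "c1", "position_cm": pos, "nearest_marker": "m", "lod": lod}
        )
        return qm.QTLScanResult(table=table, n_lines=75)

    def test_unimodal_profile_brute_force_oracle(self):
        pos = np.linspace(0, 100, 101)
        lod = 6.0 - 0.01 * (pos - 50.0) ** 2
        lod = np.maximum(lod, 0.0)
        scan = self._scan_from_profile(pos, lod)
        lo, hi = qm.lod_support_interval(scan, "c1", 50.0, drop=2.0)
        inside = (pos >= lo + 1.0 + 1e-9) & (pos <= hi - 1.0 - 1e-9)
        assert (lod[inside] >= 4.0).all()
        # brute force: the crossing happens at 50 +/- sqrt(200) ~ 14.1
        assert lo == pytest.approx(50 - np.sqrt(200), abs=1.0)
        assert hi == pytest.approx(50 + np.sqrt(200), abs=1.0)

    def test_flat_profile_spans_whole_chromosome(self):
        pos = np.linspace(0, 60, 61)
        scan = self._scan_from_profile(pos, np.full(61, 3.0))
        assert qm.lod_support_interval(scan, "c1", 30.0) == (0.0, 60.0)

    def test_zero_drop_degenerates_to_flanking_points(self):
        pos = np.linspace(0, 10, 11)
        lod = np.zeros(11)
        lod[5] = 4.0
        scan = self._scan_from_profile(pos, lod)
        lo, hi = qm.lod_support_interval(scan, "c1", 5.0, drop=0.0)
        assert (lo, hi) == (4.0, 6.0)


class TestAlleleEffects:
    def test_exact_classes_no_spread(self):
        calls = np.array([[P1_HOM], [P1_HOM], [P2_HOM], [P2_HOM]])
        geno = _geno_from_calls(calls)
        y = pd.Series([10.0, 10.0, 20.0, 20.0], index=geno.lines)
        eff = qm.allele_effects(y, geno, "m0")
        assert eff["P1_HOM"] == (10.0, 0.0)
        assert eff["P2_HOM"] == (20.0, 0.0)

    def test_hand_computed_three_plus_three(self):
        calls = np.array([[P1_HOM]] * 3 + [[P2_HOM]] * 3)
        geno = _geno_from_calls(calls)
        y = pd.Series([1.0, 2.0, 3.0, 7.0, 9.0, 14.0], index=geno.lines)
        eff = qm.allele_effects(y, geno, "m0")
        assert eff["P1_HOM"][0] == pytest.approx(2.0)
        assert eff["P1_HOM"][1] == pytest.approx(1.0 / np.sqrt(3))
        assert eff["P2_HOM"][0] == pytest.approx(10.0)
        assert eff["P2_HOM"][1] == pytest.approx(np.std([7, 9, 14], ddof=1) / np.sqrt(3))

    def test_singleton_class_flagged(self):
        calls = np.array([[P1_HOM], [P1_HOM], [P2_HOM]])
        geno = _geno_from_calls(calls)
        y = pd.Series([1.0, 2.0, 5.0], index=geno.lines)
        with pytest.warns(RuntimeWarning, match="SE undefined"):
            eff = qm.allele_effects(y, geno, "m0")
        assert np.isnan(eff["P2_HOM"][1])


class TestPVE:
    def test_zero_lod_zero_pve(self):
        assert qm.pve_from_lod(0.0, 75) == 0.0

    @pytest.mark.parametrize(
        "lod, expected", [(3.960, 0.216), (3.054, 0.171)]
    )
    def test_published_lod_pve_pairs_for_75_lines(self, lod, expected):
        assert round(qm.pve_from_lod(lod, 75), 3) == expected
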