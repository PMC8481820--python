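"""Overlap estimation, Lin-Sullivan weighting, combined Z, inflation, clumping."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import meta as m
from crosstrait.errors import ConfigError, DataError, EstimationError
from crosstrait.panel import ReferencePanel, compute_ld_scores
from crosstrait.simulate import PanelConfig, SimulationConfig, make_reference_panel, simulate_pair


class TestEstimateOverlap:
    def test_independent_null_near_zero(self):
        rng = np.random.default_rng(1)
        z1, z2 = rng.standard_normal((2, 50_000))
        ov = m.estimate_overlap(z1, z2)
        assert abs(ov.r_hat) < 3 / np.sqrt(ov.n_snps_used)

    def test_deattenuation_recovers_truth_and_ordering(self):
        rng = np.random.default_rng(2)
        n = 400_000
        x = rng.standard_normal(n)
        hats = {}
        for r0 in (0.2, 0.5):
            y = r0 * x + np.sqrt(1 - r0**2) * rng.standard_normal(n)
            ov = m.estimate_overlap(x, y)
            hats[r0] = ov
            assert ov.r_hat == pytest.approx(r0, abs=0.02)
            assert ov.r_hat_raw < ov.r_hat  # truncation attenuates
        assert hats[0.5].r_hat_raw > hats[0.2].r_hat_raw

    def test_raw_mode_reports_truncated_sample_value(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200_000)
        y = 0.6 * x + 0.8 * rng.standard_normal(200_000)
        ov = m.estimate_overlap(x, y, deattenuate=False)
        # doubly truncated bivariate normal at rho=0.6 has correlation ~0.247
        assert ov.r_hat == pytest.approx(m.truncated_correlation(0.6), abs=0.02)

    def test_identical_inputs_rejected(self):
        z = np.random.default_rng(4).standard_normal(5000)
        with pytest.raises(EstimationError, match="copies"):
            m.estimate_overlap(z, z)

    def test_too_few_snps(self):
        z = np.zeros(10)
        with pytest.raises(DataError):
            m.estimate_overlap(z, z)

    def test_truncation_map_monotone(self):
        rhos = np.linspace(-0.9, 0.9, 13)
        vals = [m.truncated_correlation(r) for r in rhos]
        assert np.all(np.diff(vals) > 0)


class TestLinSullivanWeights:
    def test_two_study_exchangeable_is_half_half(self):
        for r in (-0.5, 0.0, 0.3, 0.9):
            w = m.lin_sullivan_weights(np.array([[1.0, r], [r, 1.0]]))
            assert np.allclose(w, [0.5, 0.5])

    def test_identity_three_studies(self):
        assert np.allclose(m.lin_sullivan_weights(np.eye(3)), 1 / 3)

    def test_unequal_diagonal_oracle(self):
        # direct inversion: Omega = diag(1, 4) -> w = (0.8, 0.2)
        assert np.allclose(m.lin_sullivan_weights(np.diag([1.0, 4.0])), [0.8, 0.2])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(-0.8, 0.8)
            w = m.lin_sullivan_weights(np.array([[1, a], [a, 1]]))
            assert w.sum() == pytest.approx(1.0)

    def test_singular_omega(self):
        with pytest.raises(EstimationError):
            m.lin_sullivan_weights(np.ones((2, 2)))


class TestMetaZ:
    def test_hand_evaluated_examples(self):
        w = np.array([0.5, 0.5])
        zh, _ = m.meta_z(np.array([[3.0], [4.0]]), w, np.eye(2))
        assert zh[0] == pytest.approx(7 / np.sqrt(2), abs=1e-4)
        zh, _ = m.meta_z(np.array([[3.0], [4.0]]), w,
                         np.array([[1, 0.2], [0.2, 1]]))
        assert zh[0] == pytest.approx(3.5 / np.sqrt(0.6), abs=1e-4)

    def test_fully_duplicated_studies(self):
        w = np.array([0.5, 0.5])
        z = np.array([[1.3, -2.0], [0.7, 5.0]])
        zh, _ = m.meta_z(z, w, np.ones((2, 2)))
        assert np.allclose(zh, z.mean(axis=0))

    @pytest.mark.parametrize("k", [2, 3])
    def test_matrix_expression_oracle(self, k):
        """Z_meta must equal w'Z / sqrt(w' Omega w) evaluated directly."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            a = rng.uniform(-0.4, 0.4, size=(k, k))
            omega = (a + a.T) / 2 + np.eye(k) * 1.5
            d = np.sqrt(np.diag(omega))
            omega = omega / np.outer(d, d)
            w = m.lin_sullivan_weights(omega)
            z = rng.standard_normal((k, 40))
            zh, _ = m.meta_z(z, w, omega)
            oracle = (w @ z) / np.sqrt(w @ omega @ w)
            assert np.allclose(zh, oracle, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((2, 100))
        omega = np.array([[1, 0.4], [0.4, 1]])
        w = m.lin_sullivan_weights(omega)
        zh, _ = m.meta_z(z, w, omega)
        zh_swapped, _ = m.meta_z(z[::-1], w[::-1], omega)
        assert np.allclose(zh, zh_swapped)


class TestGenomicInflation:
    def test_null_z_lambda_near_one(self):
        z = np.random.default_rng(8).standard_normal(10**6)
        lam, _ = m.genomic_inflation(z, 10**6, 10**6)
        assert lam == pytest.approx(1.0, abs=0.01)

    def test_constructed_median_exact(self):
        target = m.CHI2_MEDIAN_1DF * 1.1
        z = np.sqrt(np.array([target - 1e-9, target, target + 1e-9]))
        lam, _ = m.genomic_inflation(z, 1000, 1000)
        assert lam == pytest.approx(1.1)

    def test_thousand_case_control_design_identity(self):
        # with exactly 1000/1000 the rescaling leaves lambda unchanged
        target = m.CHI2_MEDIAN_1DF * 1.1
        z = np.full(11, np.sqrt(target))
        lam, lam1000 = m.genomic_inflation(z, 1000, 1000)
        assert lam1000 == pytest.approx(lam) == pytest.approx(1.1)

    def test_bad_counts(self):
        with pytest.raises(ConfigError):
            m.genomic_inflation(np.ones(5), 0, 10)


# ---------------------------------------------------------------------------
# clumping


def _panel_from_r(r: np.ndarray, pos: np.ndarray, chrom: np.ndarray) -> ReferencePanel:
    """Single-block panel with an explicit LD matrix (one block per chrom)."""
    n = len(pos)
    variants = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": chrom, "pos": pos,
        "ref_allele": "A", "alt_allele": "G", "af": 0.3,
        "block_id": chrom - chrom.min(),
    })
    blocks = {}
    for b in np.unique(variants["block_id"]):
        idx = np.flatnonzero(variants["block_id"] == b)
        blocks[int(b)] = r[np.ix_(idx, idx)]
    return ReferencePanel(variants=variants, blocks=blocks,
                          ld_scores=compute_ld_scores(variants, blocks))


def _meta_table(panel: ReferencePanel, pvals: np.ndarray) -> pd.DataFrame:
    v = panel.variants
    return pd.DataFrame({"snp_id": v["snp_id"], "chrom": v["chrom"],
                         "pos": v["pos"], "z_meta": 0.0, "p_meta": pvals})


def brute_force_clump(r2: np.ndarray, pos: np.ndarray, chrom: np.ndarray,
                      pvals: np.ndarray, params: m.ClumpParams):
    """Independent reference clumping on dense matrices, for the oracle test."""
    sig = [i for i in range(len(pvals)) if pvals[i] <= params.p_threshold]
    sig.sort(key=lambda i: (pvals[i], chrom[i], pos[i]))
    assigned, clumps = set(), []
    for i in sig:
        if i in assigned:
            continue
        members = [j for j in sig if j not in assigned and
                   (j == i or r2[i, j] >= params.r2_member)]
        assigned.update(members)
        clumps.append({"lead": i, "members": members})
    retained = []
    for c in clumps:
        home = next((k for k in retained
                     if any(r2[c["lead"], l] >= params.r2_lead for l in k["leads"])),
                    None)
        if home is None:
            retained.append({"leads": [c["lead"]], "members": list(c["members"])})
        else:
            home["members"].extend(c["members"])
    spans = sorted(
        ({"chrom": chrom[c["leads"][0]],
          "start": min(pos[j] for j in c["members"]),
          "end": max(pos[j] for j in c["members"]),
          "leads": c["leads"], "members": c["members"]} for c in retained),
        key=lambda s: (s["chrom"], s["start"]))
    loci = []
    for s in spans:
        if loci and s["chrom"] == loci[-1]["chrom"] and \
                s["start"] - loci[-1]["end"] <= params.merge_window_kb * 1000:
            loci[-1]["end"] = max(loci[-1]["end"], s["end"])
            loci[-1]["leads"].extend(s["leads"])
            loci[-1]["members"].extend(s["members"])
        else:
            loci.append(s)
    return loci


class TestClumpLoci:
    def test_two_loci_from_correlated_triplet_plus_distant_snp(self):
        # 3 SNPs pairwise r2 = 0.81 with p = 1e-10, 1e-9, 5e-9 and one far SNP
        r = np.eye(4)
        r[np.ix_([0, 1, 2], [0, 1, 2])] = 0.9
        np.fill_diagonal(r, 1.0)
        panel = _panel_from_r(r, np.array([100, 200, 300, 10_000_000]),
                              np.array([1, 1, 1, 2]))
        tab = _meta_table(panel, np.array([1e-10, 1e-9, 5e-9, 1e-8]))
        loci = m.clump_loci(tab, panel)
        assert len(loci) == 2
        assert loci[0].lead_snps[0] == "rs0"
        assert set(loci[0].member_snps) == {"rs0", "rs1", "rs2"}

    def test_single_significant_snp(self):
        panel = _panel_from_r(np.eye(1), np.array([100]), np.array([1]))
        loci = m.clump_loci(_meta_table(panel, np.array([1e-9])), panel)
        assert len(loci) == 1
        assert loci[0].lead_snps == loci[0].member_snps == ["rs0"]

    def test_no_significant_snps(self):
        panel = _panel_from_r(np.eye(2), np.array([1, 2]), np.array([1, 1]))
        assert m.clump_loci(_meta_table(panel, np.array([0.5, 0.1])), panel) == []

    def test_tie_break_deterministic(self):
        panel = _panel_from_r(np.eye(3), np.array([300, 100, 200]),
                              np.array([3, 1, 2]))
        tab = _meta_table(panel, np.array([1e-9, 1e-9, 1e-9]))
        a = m.clump_loci(tab, panel)
        b = m.clump_loci(tab.sample(frac=1, random_state=0), panel)
        assert [l.lead_snps for l in a] == [l.lead_snps for l in b]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        chrom = np.sort(rng.integers(1, 4, size=n))
        pos = np.zeros(n, dtype=int)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            pos[idx] = np.sort(rng.choice(np.arange(1, 3_000_000, 1000),
                                          size=len(idx), replace=False))
        # random PSD correlation per chromosome block
        r = np.eye(n)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            a = rng.standard_normal((len(idx), max(2, len(idx) // 2)))
            cov = a @ a.T + np.eye(len(idx)) * 0.5
            d = np.sqrt(np.diag(cov))
            r[np.ix_(idx, idx)] = cov / np.outer(d, d)
        pvals = 10 ** rng.uniform(-12, -2, size=n)
        panel = _panel_from_r(r, pos, chrom)
        params = m.ClumpParams()
        loci = m.clump_loci(_meta_table(panel, pvals), panel, params)
        oracle = brute_force_clump(r**2, pos, chrom, pvals, params)
        assert len(loci) == len(oracle)
        got = sorted((l.chrom, l.start, l.end, tuple(sorted(l.member_snps)))
                     for l in loci)
        want = sorted((int(s["chrom"]), int(s["start"]), int(s["end"]),
                       tuple(sorted(f"rs{j}" for j in set(s["members"]))))
                      for s in oracle)
        assert got == want

    def test_partition_and_lead_independence(self, medium_panel):
        cfg = SimulationConfig(seed=91)
        pair = simulate_pair(cfg, medium_panel)
        result = m.run_meta(pair.ss1.table, pair.ss2.table)
        params = m.ClumpParams()
        loci = m.clump_loci(result, medium_panel, params)
        sig = set(result.table.loc[result.table["p_meta"] <= params.p_threshold,
                                   "snp_id"])
        in_loci = [s for l in loci for s in l.member_snps]
        assert sorted(in_loci) == sorted(sig)  # each sig SNP in exactly one locus
        leads = [s for l in loci for s in l.lead_snps]
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                assert medium_panel.ld_r2(a, b) < params.r2_lead


class TestNullCalibration:
    def test_overlap_correction_calibrates_and_matters(self):
        """Type-I error of the combined Z at alpha=5e-4 sits inside binomial
        bounds when the estimated overlap is used, and escapes them when the
        correction is switched off under real overlap."""
        panel = make_reference_panel(PanelConfig(
            m_snps=100_000, block_size=10, ld_rho=0.0, ld_rho_range=None, seed=7))
        cfg = SimulationConfig(pi1=0, pi2=0, pi12=0, r0=0.6, seed=500)
        z1, z2 = [], []
        for rep in range(3):
            pair = simulate_pair(SimulationConfig(pi1=0, pi2=0, pi12=0, r0=0.6,
                                                  seed=500 + rep), panel)
            z1.append(pair.ss1.table["z"].to_numpy())
            z2.append(pair.ss2.table["z"].to_numpy())
        z1, z2 = np.concatenate(z1), np.concatenate(z2)
        n = len(z1)
        alpha = 5e-4
        half = 1.96 * np.sqrt(alpha * (1 - alpha) / n)

        ov = m.estimate_overlap(z1, z2)
        w = m.lin_sullivan_weights(ov)
        _, p = m.meta_z(np.vstack([z1, z2]), w, ov)
        assert abs((p <= alpha).mean() - alpha) <= half

        naive = np.eye(2)
        _, p0 = m.meta_z(np.vstack([z1, z2]), m.lin_sullivan_weights(naive), naive)
        assert (p0 <= alpha).mean() - alpha > half  # uncorrected inflates
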