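"""Variance components, heritability formulas, BLUEs, genomic heritability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nampred import (
    VarianceComponents,
    broad_sense_heritability,
    compute_blues,
    estimate_variance_components,
    genomic_heritability,
    genomic_heritability_batch,
    genomic_kernels,
    repeatability,
    simulate_phenotypes,
)


def _balanced_table(n_lines, n_years, n_reps, v_g, v_gy, v_r, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(v_g), n_lines)
    year = rng.normal(0, 3.0, n_years)
    gy = rng.normal(0, np.sqrt(v_gy), (n_lines, n_years))
    rows = []
    for j in range(n_years):
        for r in range(n_reps):
            e = rng.normal(0, np.sqrt(v_r), n_lines)
            for i in range(n_lines):
                rows.append((f"L{i:04d}", 2000 + j, r + 1, "T", g[i] + year[j] + gy[i, j] + e[i]))
    return pd.DataFrame(rows, columns=["line_id", "year", "replicate", "trait", "value"])


def _anova_mom(table):
    """Balanced two-way ANOVA estimators — independent oracle."""
    cell = table.pivot_table(index="line_id", columns="year", values="value")
    wide = table.pivot_table(index="line_id", columns=["year", "replicate"], values="value")
    n, y = cell.shape
    r = wide.shape[1] // y
    lm = cell.mean(axis=1)
    ym = cell.mean(axis=0)
    inter = cell.sub(lm, axis=0).sub(ym, axis=1) + lm.mean()
    ms_g = y * r * lm.sub(lm.mean()).pow(2).sum() / (n - 1)
    ms_gy = r * inter.pow(2).to_numpy().sum() / ((n - 1) * (y - 1))
    resid = wide.to_numpy() - np.repeat(cell.to_numpy(), r, axis=1)
    ms_e = (resid**2).sum() / (n * y * (r - 1))
    return max((ms_g - ms_gy) / (y * r), 0), max((ms_gy - ms_e) / r, 0), ms_e


class TestVarianceComponents:
    def test_reml_matches_anova_oracle_on_balanced_data(self):
        table = _balanced_table(60, 4, 2, v_g=2.0, v_gy=0.5, v_r=1.0, seed=1)
        vc = estimate_variance_components(table, "T")
        v_g, v_gy, v_r = _anova_mom(table)
        assert vc.v_g == pytest.approx(v_g, abs=1e-5)
        assert vc.v_gy == pytest.approx(v_gy, abs=1e-5)
        assert vc.v_r == pytest.approx(v_r, abs=1e-5)

    def test_recovery_of_generating_components(self):
        table = _balanced_table(500, 8, 2, v_g=2.0, v_gy=0.5, v_r=1.0, seed=2)
        vc = estimate_variance_components(table, "T")
        assert vc.v_g == pytest.approx(2.0, rel=0.15)
        assert vc.v_gy == pytest.approx(0.5, rel=0.15)
        assert vc.v_r == pytest.approx(1.0, rel=0.15)

    def test_zero_noise_gives_between_line_variance(self):
        table = _balanced_table(40, 3, 2, v_g=4.0, v_gy=0.0, v_r=0.0, seed=3)
        vc = estimate_variance_components(table, "T")
        lm = table.pivot_table(index="line_id", columns="year", values="value").mean(axis=1)
        assert vc.v_g == pytest.approx(lm.var(ddof=1), rel=1e-3)
        assert vc.v_gy == pytest.approx(0.0, abs=1e-6)
        assert vc.v_r == pytest.approx(0.0, abs=1e-6)

    def test_permuting_lines_within_year_destroys_v_g(self):
        table = _balanced_table(120, 4, 2, v_g=2.0, v_gy=0.0, v_r=0.5, seed=4)
        rng = np.random.default_rng(0)
        shuffled = []
        for _, sub in table.groupby(["year", "replicate"]):
            sub = sub.copy()
            sub["line_id"] = rng.permutation(sub["line_id"].to_numpy())
            shuffled.append(sub)
        vc = estimate_variance_components(pd.concat(shuffled), "T")
        assert vc.v_g < 0.15  # ~0 once line identity is broken

    def test_single_year_rejected(self):
        table = _balanced_table(10, 1, 2, 1, 0, 1)
        with pytest.raises(ValueError, match="year"):
            estimate_variance_components(table, "T")

    def test_unreplicated_design_rejected(self):
        table = _balanced_table(10, 3, 1, 1, 0, 1)
        with pytest.raises(ValueError, match="V_R"):
            estimate_variance_components(table, "T")


class TestHeritabilityFormulas:
    def test_direct_evaluation(self):
        vc = VarianceComponents(v_g=2.0, v_gy=1.0, v_r=4.0, n_years=5, n_reps=2)
        assert broad_sense_heritability(vc) == pytest.approx(2.0 / 2.6)

    def test_pure_genetic_signal_gives_one(self):
        vc = VarianceComponents(v_g=1.0, v_gy=0.0, v_r=0.0, n_years=2, n_reps=1)
        assert broad_sense_heritability(vc) == 1.0

    def test_more_years_never_decrease_h2(self):
        vals = [
            broad_sense_heritability(
                VarianceComponents(v_g=1.0, v_gy=0.5, v_r=2.0, n_years=y, n_reps=2)
            )
            for y in range(1, 10)
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        vc1 = VarianceComponents(v_g=1.5, v_gy=0.3, v_r=2.0, n_years=4, n_reps=2)
        vc2 = VarianceComponents(
            v_g=1.5 * c, v_gy=0.3 * c, v_r=2.0 * c, n_years=4, n_reps=2
        )
        assert broad_sense_heritability(vc1) == pytest.approx(broad_sense_heritability(vc2))
        assert repeatability(1.5, 2.0, 3) == pytest.approx(repeatability(1.5 * c, 2.0 * c, 3))

    def test_repeatability_values(self):
        assert repeatability(1.0, 0.0, 2) == 1.0
        assert repeatability(1.0, 3.0, 3) == pytest.approx(0.5)
        assert repeatability(1.0, 3.0, 10**9) == pytest.approx(1.0, abs=1e-6)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            broad_sense_heritability(
                VarianceComponents(v_g=0, v_gy=0, v_r=0, n_years=2, n_reps=2)
            )
        with pytest.raises(ValueError):
            repeatability(0.0, 0.0, 2)


class TestBlues:
    def test_single_year_reduces_to_line_means(self):
        table = _balanced_table(30, 1, 3, v_g=1.0, v_gy=0.0, v_r=0.5, seed=5)
        blues = compute_blues(table, "T")
        means = table.groupby("line_id")["value"].mean()
        assert np.allclose(blues.values.sort_index(), means.sort_index())

    def test_year_shift_leaves_line_differences_unchanged(self):
        table = _balanced_table(30, 3, 2, v_g=1.0, v_gy=0.0, v_r=0.5, seed=6)
        shifted = table.copy()
        shifted.loc[shifted["year"] == 2001, "value"] += 17.0
        a = compute_blues(table, "T").values
        b = compute_blues(shifted, "T").values
        assert np.allclose(a - a.mean(), b - b.mean())

    def test_blues_track_true_genotypic_values(self, nam):
        from nampred import broad_sense_heritability, estimate_variance_components

        vc = estimate_variance_components(nam["phen"], "TRAIT")
        h2 = broad_sense_heritability(vc)
        blues = compute_blues(nam["phen"], "TRAIT", h2=h2)
        gv = pd.Series(nam["truth"].genotypic_values, index=nam["geno"].line_ids)
        r = np.corrcoef(blues.values, gv.loc[blues.values.index])[0, 1]
        assert r >= np.sqrt(h2) - 0.05

    def test_random_year_close_to_fixed_on_balanced_data(self):
        table = _balanced_table(30, 4, 2, v_g=1.0, v_gy=0.2, v_r=0.5, seed=7)
        a = compute_blues(table, "T", year_effect="fixed").values
        b = compute_blues(table, "T", year_effect="random").values
        assert np.corrcoef(a, b)[0, 1] > 0.999


class TestGenomicHeritability:
    def test_pure_noise_metabolite_near_zero(self, nam):
        rng = np.random.default_rng(12)
        y = rng.normal(size=nam["geno"].n_lines)
        K = genomic_kernels(nam["geno"], ("additive",))["additive"]
        h2 = genomic_heritability_batch(y, K)[0]
        assert h2 < 0.05

    def test_additive_signal_recovered(self, nam):
        geno = nam["geno"]
        rng = np.random.default_rng(5)
        X = geno.dosage
        beta = rng.normal(size=X.shape[1]) * (rng.random(X.shape[1]) < 0.2)
        g = X @ beta
        g = (g - g.mean()) / g.std() * np.sqrt(0.5)
        y = g + rng.normal(0, np.sqrt(0.5), X.shape[0])
        gv = genomic_heritability(y, geno)
        assert gv.sigma2_a > gv.sigma2_d and gv.sigma2_a > gv.sigma2_i
        assert gv.h2_snp == pytest.approx(0.5, abs=0.1)

    def test_h2_snp_bounded(self, nam):
        rng = np.random.default_rng(6)
        y = rng.normal(size=nam["geno"].n_lines)
        gv = genomic_heritability(y, nam["geno"], kernels=("additive", "dominance"))
        assert 0.0 <= gv.h2_snp <= 1.0

    def test_batch_recovers_metabolite_mean(self, nam):
        K = genomic_kernels(nam["geno"], ("additive",))["additive"]
        h2s = genomic_heritability_batch(nam["mets"].to_numpy(), K)
        target = nam["met_truth"]["h2_snp_target"]
        assert h2s.mean() == pytest.approx(target.mean(), abs=0.05)
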