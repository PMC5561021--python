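import itertools
import math

import numpy as np
import pandas as pd
import pytest

from refstab.errors import InsufficientDataError, ValidationError
from refstab.io import CqTable, aggregate_technical_replicates
from refstab.simulate import SimulationConfig, simulate_cq
from refstab.stability import (
    bestkeeper,
    delta_ct_stability,
    genorm_m,
    genorm_pairwise_variation,
    genorm_stepwise,
    normfinder,
    relative_quantities,
)

from conftest import make_table


# ------------------------------------------------------------------ oracles
def brute_delta_ct(mat: np.ndarray) -> np.ndarray:
    """Naive all-pairs comparative-delta-Ct stabilities."""
    n_g = mat.shape[1]
    out = np.empty(n_g)
    for j in range(n_g):
        sds = [np.std(mat[:, j] - mat[:, k], ddof=1)
               for k in range(n_g) if k != j]
        out[j] = np.mean(sds)
    return out


def brute_genorm_m(q: np.ndarray) -> np.ndarray:
    """Naive all-pairs geNorm M on a quantity matrix."""
    y = np.log2(q)
    n_g = q.shape[1]
    out = np.empty(n_g)
    for j in range(n_g):
        vs = [np.std(y[:, j] - y[:, k], ddof=1)
              for k in range(n_g) if k != j]
        out[j] = np.mean(vs)
    return out


def _shift_sample(table: CqTable, sample: str, delta: float) -> CqTable:
    df = table.data.copy()
    df.loc[df["sample"] == sample, "cq"] += delta
    return CqTable(df, max_cycles=table.max_cycles + abs(delta))


# -------------------------------------------------------- relative quantities
class TestRelativeQuantities:
    def test_doubling_per_cycle(self):
        t = make_table([[24.0], [25.0], [26.0]])
        q = relative_quantities(t).q["g0"]
        assert list(q) == pytest.approx([1.0, 0.5, 0.25])

    def test_unit_efficiency_rejected(self):
        t = make_table([[24.0], [25.0]])
        with pytest.raises(ValidationError):
            relative_quantities(t, efficiencies=1.0)

    def test_constant_cq_gives_unit_quantities(self):
        t = make_table([[25.0, 30.0]] * 3)
        assert (relative_quantities(t).q == 1.0).all().all()

    def test_per_gene_efficiencies(self):
        t = make_table([[24.0, 24.0], [25.0, 25.0]])
        q = relative_quantities(t, {"g0": 2.0, "g1": 1.5}).q
        assert q.loc["s1", "g0"] == pytest.approx(0.5)
        assert q.loc["s1", "g1"] == pytest.approx(1 / 1.5)


# ------------------------------------------------------------------ delta Ct
class TestDeltaCt:
    def test_identical_genes_have_zero_stability(self):
        mat = np.column_stack([np.r_[24.0, 25.0, 27.0]] * 2)
        scores = delta_ct_stability(make_table(mat))
        assert all(s.value == pytest.approx(0.0, abs=1e-12) for s in scores)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        mat = rng.uniform(20, 32, size=(4, 3))
        got = {s.gene_id: s.value for s in delta_ct_stability(make_table(mat))}
        exp = brute_delta_ct(mat)
        for j, g in enumerate(sorted(got)):
            assert got[g] == pytest.approx(exp[j], abs=1e-12)

    def test_loading_shift_invariance(self, panel_table):
        base = {s.gene_id: s.value for s in delta_ct_stability(panel_table)}
        shifted = _shift_sample(panel_table, panel_table.samples[0], 1.0)
        after = {s.gene_id: s.value for s in delta_ct_stability(shifted)}
        assert base == pytest.approx(after, abs=1e-12)

    def test_pairwise_missing_handling(self):
        mat = np.array([[24.0, 25.0, 26.0],
                        [25.0, np.nan, 27.0],
                        [26.0, 27.0, 28.0],
                        [27.0, 28.0, 30.0]])
        scores = {s.gene_id: s.value for s in delta_ct_stability(make_table(mat))}
        # g0-g1 SD computed over the 3 complete rows only
        d = mat[[0, 2, 3], 0] - mat[[0, 2, 3], 1]
        sd01 = np.std(d, ddof=1)
        sd02 = np.std(mat[:, 0] - mat[:, 2], ddof=1)
        assert scores["g0"] == pytest.approx((sd01 + sd02) / 2, abs=1e-12)


# -------------------------------------------------------------------- geNorm
class TestGenorm:
    def test_two_gene_symmetry(self):
        t = make_table(np.random.default_rng(0).uniform(22, 30, (5, 2)))
        m = genorm_m(relative_quantities(t))
        assert m.iloc[0] == pytest.approx(m.iloc[1], abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        mat = rng.uniform(20, 32, size=(6, 4))
        t = make_table(mat)
        matrix = relative_quantities(t)
        got = genorm_m(matrix)
        exp = brute_genorm_m(matrix.q.to_numpy())
        for j, g in enumerate(matrix.genes):
            assert got[g] == pytest.approx(exp[j], abs=1e-12)

    def test_scaling_one_gene_leaves_m_unchanged(self):
        rng = np.random.default_rng(14)
        t = make_table(rng.uniform(22, 30, (6, 3)))
        matrix = relative_quantities(t)
        m1 = genorm_m(matrix)
        matrix.q["g1"] *= 0.37  # constant factor cancels in every ratio
        m2 = genorm_m(matrix)
        pd.testing.assert_series_equal(m1, m2, atol=1e-12)

    def test_stepwise_excludes_noisy_gene_first(self):
        rng = np.random.default_rng(15)
        sample_eff = rng.normal(0, 1, 10)
        mat = np.column_stack([
            25 + sample_eff + rng.normal(0, 0.05, 10),
            27 + sample_eff + rng.normal(0, 0.05, 10),
            29 + sample_eff + rng.normal(0, 0.05, 10),
            24 + sample_eff + rng.normal(0, 2.0, 10),   # the noisy one
        ])
        res = genorm_stepwise(relative_quantities(make_table(mat)))
        assert res.exclusion_order[0] == "g3"
        assert res.ranks["g3"] == 4.0

    def test_stepwise_tie_excludes_later_gene(self):
        # identical genes up to per-sample shifts: all M equal at every step
        base = np.array([24.0, 25.5, 27.0, 23.0])
        mat = np.column_stack([base, base + 1, base + 2])
        res = genorm_stepwise(relative_quantities(make_table(mat)))
        assert res.exclusion_order == ["g2"]
        assert set(res.final_pair) == {"g0", "g1"}

    def test_stepwise_matches_oracle_replay(self, panel_table):
        matrix = relative_quantities(panel_table)
        res = genorm_stepwise(matrix)
        remaining = list(matrix.genes)
        for excluded in res.exclusion_order:
            m = genorm_m(matrix, remaining)
            assert m[excluded] == pytest.approx(m.max(), abs=1e-12)
            assert res.m_at_step[excluded] == pytest.approx(m[excluded])
            remaining.remove(excluded)
        assert set(remaining) == set(res.final_pair)

    def test_pairwise_variation_degenerate_panel(self):
        mat = np.column_stack([np.r_[24.0, 25.0, 26.0, 27.0]] * 4)
        matrix = relative_quantities(make_table(mat))
        v = genorm_pairwise_variation(matrix, list(matrix.genes))
        assert (v.abs() < 1e-12).all()

    def test_pairwise_variation_matches_brute_force(self, panel_table):
        matrix = relative_quantities(panel_table)
        order = list(genorm_stepwise(matrix).ranks.sort_values().index)
        v = genorm_pairwise_variation(matrix, order)
        y = np.log2(matrix.q[order].to_numpy())
        for n in range(2, len(order)):
            nf_n = y[:, :n].mean(axis=1)
            nf_n1 = y[:, : n + 1].mean(axis=1)
            assert v[f"V{n}/{n + 1}"] == pytest.approx(
                np.std(nf_n - nf_n1, ddof=1), abs=1e-12)

    def test_duplicate_of_top_gene_gives_small_v(self, panel_table):
        matrix = relative_quantities(panel_table)
        order = list(genorm_stepwise(matrix).ranks.sort_values().index)
        dup = order[0]
        q = matrix.q.copy()
        q["dup"] = q[dup]
        matrix.q = q
        v = genorm_pairwise_variation(matrix, order + ["dup"])
        n = len(order)
        # appending an exact copy of a top gene barely moves the NF
        assert v[f"V{n}/{n + 1}"] < 0.05


# ---------------------------------------------------------------- BestKeeper
class TestBestkeeper:
    def test_constant_gene_degenerate(self):
        scores = bestkeeper(make_table([[25.0]] * 4))
        (s,) = scores
        assert s.value == pytest.approx(0.0, abs=1e-12)
        assert s.extras["geo_mean"] == pytest.approx(25.0, abs=1e-12)
        assert s.extras["cv_percent"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mad_about_geometric_mean(self):
        (s,) = bestkeeper(make_table([[24.0], [26.0]]))
        gm = math.sqrt(24 * 26)
        mad = (abs(24 - gm) + abs(26 - gm)) / 2
        assert s.extras["geo_mean"] == pytest.approx(24.9800, abs=1e-4)
        assert s.value == pytest.approx(mad, abs=1e-12)
        assert s.value == pytest.approx(1.0000, abs=1e-4)
        assert s.extras["cv_percent"] == pytest.approx(4.0, abs=0.01)

    def test_classical_sd_flag(self):
        (s,) = bestkeeper(make_table([[24.0], [26.0]]), use_classical_sd=True)
        assert s.value == pytest.approx(np.std([24, 26], ddof=1), abs=1e-12)

    def test_not_loading_invariant(self, panel_table):
        base = {s.gene_id: s.value for s in bestkeeper(panel_table)}
        shifted = _shift_sample(panel_table, panel_table.samples[0], 1.0)
        after = {s.gene_id: s.value for s in bestkeeper(shifted)}
        assert any(abs(base[g] - after[g]) > 1e-6 for g in base)

    def test_index_correlation_present(self, panel_table):
        for s in bestkeeper(panel_table):
            assert -1.0 <= s.extras["r_with_index"] <= 1.0


# ---------------------------------------------------------------- NormFinder
class TestNormfinder:
    def test_requires_three_genes(self):
        t = make_table([[24.0, 25.0], [25.0, 26.0]])
        with pytest.raises(InsufficientDataError):
            normfinder(relative_quantities(t))

    def test_sample_shift_invariance(self, panel_table):
        base = {s.gene_id: s.value
                for s in normfinder(relative_quantities(panel_table))}
        shifted = _shift_sample(panel_table, panel_table.samples[2], 2.5)
        after = {s.gene_id: s.value
                 for s in normfinder(relative_quantities(shifted))}
        assert base == pytest.approx(after, abs=1e-9)

    def test_zero_noise_gene_attains_minimum(self):
        rng = np.random.default_rng(3)
        n, k = 40, 6
        sample_eff = rng.normal(0, 1, n)
        mat = np.empty((n, k))
        for j in range(k):
            noise = 0.0 if j == 0 else rng.normal(0, 0.5, n)
            mat[:, j] = 25 + j + sample_eff + noise
        scores = normfinder(relative_quantities(make_table(mat)))
        by_gene = {s.gene_id: s for s in scores}
        assert by_gene["g0"].rank == 1.0
        assert by_gene["g0"].value <= min(s.value for s in scores)

    def test_exchangeable_genes_have_similar_values(self):
        rng = np.random.default_rng(4)
        n, k = 400, 5
        sample_eff = rng.normal(0, 1, n)
        mat = 25 + sample_eff[:, None] + rng.normal(0, 0.5, (n, k))
        values = [s.value for s in normfinder(relative_quantities(make_table(mat)))]
        assert max(values) - min(values) < 0.1   # Monte-Carlo tolerance at n=400

    def test_grouped_mode_runs_and_ranks(self, panel_table):
        groups = {s: cond for s, (cond, _) in panel_table.design.items()}
        scores = normfinder(relative_quantities(panel_table), groups=groups)
        ranks = sorted(s.rank for s in scores)
        assert ranks == sorted(np.arange(1, len(scores) + 1, dtype=float).tolist()) \
            or len(ranks) == len(scores)
        assert all("intergroup_difference" in s.extras for s in scores)

    def test_incomplete_samples_dropped(self):
        mat = np.array([[24.0, 25.0, 26.0],
                        [25.0, 26.0, 27.0],
                        [26.0, np.nan, 28.0],
                        [27.0, 28.0, 29.0]])
        scores = normfinder(relative_quantities(make_table(mat)))
        assert len(scores) == 3  # runs on the 3 complete samples


# ------------------------------------------------ cross-method noise response
@pytest.mark.parametrize("method", ["delta_ct", "genorm", "bestkeeper",
                                    "normfinder"])
def test_injected_noise_worsens_stability_value(method):
    """Raising one gene's independent noise raises its stability value."""
    # no loading term: with a fixed finite noise draw, loading could happen
    # to anticorrelate with the injected noise and shrink raw-Cq dispersion
    rng = np.random.default_rng(21)
    clean = np.column_stack([np.full(12, c) for c in (24.0, 26.0, 28.0, 30.0)])
    noise = rng.normal(0, 1.0, 12)
    values = []
    for sigma in (0.0, 0.3, 0.9):
        mat = clean.copy()
        mat[:, 0] = mat[:, 0] + sigma * noise
        t = make_table(mat)
        if method == "delta_ct":
            scores = delta_ct_stability(t)
        elif method == "genorm":
            m = genorm_m(relative_quantities(t))
            scores = None
            values.append(float(m["g0"]))
            continue
        elif method == "bestkeeper":
            scores = bestkeeper(t)
        else:
            scores = normfinder(relative_quantities(t))
        values.append({s.gene_id: s.value for s in scores}["g0"])
    assert values[0] <= values[1] <= values[2]
    assert values[2] > values[0]
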