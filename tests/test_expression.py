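import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from txdrivers.expression import (
    CountMatrix,
    bh_adjust,
    cpm,
    de_filter,
    de_test,
    tmm_norm_factors,
)


def _cm(arrays: dict) -> CountMatrix:
    n = len(next(iter(arrays.values())))
    return CountMatrix.from_frame(
        pd.DataFrame(arrays, index=[f"G{i:04d}" for i in range(n)])
    )


class TestTMM:
    def test_identical_samples_unit_factors(self):
        x = pd.DataFrame({"A": [10, 20, 30, 40], "B": [10, 20, 30, 40]})
        assert np.allclose(tmm_norm_factors(x).to_numpy(), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        # 2x deeper sample: all M-values zero, depth handled by library size
        x = pd.DataFrame({"A": [10, 20, 30, 40], "B": [20, 40, 60, 80]})
        assert np.allclose(tmm_norm_factors(x).to_numpy(), 1.0)

    def test_toy_matrix_matches_reference_implementation(self):
        """8-gene two-sample toy with one strongly shifted gene: factors
        frozen from an independent evaluation of the trimmed weighted-mean
        formula (edgeR calcNormFactors, refColumn=A)."""
        x = pd.DataFrame(
            {
                "A": [100, 200, 300, 50, 400, 120, 80, 60],
                "B": [110, 190, 2900, 55, 380, 130, 75, 65],
            },
            index=[f"G{i}" for i in range(1, 9)],
        )
        f = tmm_norm_factors(x, reference="A")
        assert f["A"] == pytest.approx(1.6587992035, abs=1e-8)
        assert f["B"] == pytest.approx(0.6028457199, abs=1e-8)

    def test_geometric_mean_is_one(self, rng):
        x = pd.DataFrame(
            rng.poisson(50, size=(300, 6)) + rng.integers(0, 30, size=(300, 6)),
            columns=list("ABCDEF"),
        )
        f = tmm_norm_factors(x)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        x = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="B"):
            tmm_norm_factors(x)


class TestCPM:
    def test_counts_per_million(self):
        x = pd.DataFrame({"A": [100, 999900]})
        assert cpm(x).iloc[0, 0] == pytest.approx(100.0)

    def test_log_of_zero_count_is_finite(self):
        x = pd.DataFrame({"A": [0, 100]})
        assert np.isfinite(cpm(x, log=True, prior_count=0.5)).all().all()

    def test_scale_invariance(self):
        x = pd.DataFrame({"A": [10, 90], "B": [30, 70]})
        assert np.allclose(cpm(x).to_numpy(), cpm(2 * x).to_numpy())


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_oracle(self):
        # direct step-up: p_(i) * m / i with monotonicity from the top
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # order-preserving: larger p never maps to smaller adjusted p
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestExactTest:
    def test_null_identity(self):
        cm = _cm({"L__pre__r1": [50, 100], "L__post__r1": [50, 100]})
        res = de_test(cm, "L", dispersion=0.0)
        assert np.allclose(res["log2_fc"], 0.0)
        assert (res["p_value"] >= 0.99).all()

    def test_poisson_case_equals_binomial_enumeration(self):
        """pre=5, post=20 at equal library size, dispersion 0: p must equal
        the doubled binomial tail for 20 of 25 at rate 1/2."""
        # padding genes keep the two library sizes exactly equal
        cm = _cm({"L__pre__r1": [5, 1000], "L__post__r1": [20, 985]})
        res = de_test(cm, "L", dispersion=0.0).set_index("gene_id")
        expected = min(1.0, 2 * stats.binom.sf(19, 25, 0.5))
        assert res.loc["G0000", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_nb_case_equals_exhaustive_conditional_enumeration(self):
        """With replicates and dispersion 0.1 the p-value equals a direct
        enumeration of the conditional distribution of the group sum."""
        cm = _cm(
            {
                "L__pre__r1": [12, 500],
                "L__pre__r2": [18, 500],
                "L__post__r1": [40, 490],
                "L__post__r2": [40, 500],
            }
        )
        res = de_test(cm, "L", dispersion=0.1, norm_factors=pd.Series(
            1.0, index=cm.counts.columns)).set_index("gene_id")

        # oracle: scale to the geometric-mean library size, enumerate s=0..T
        lib = cm.counts.sum(axis=0).astype(float)
        target = float(np.exp(np.mean(np.log(lib))))
        scaled = np.rint(cm.counts.loc["G0000"].to_numpy() * target / lib.to_numpy())
        s1, s2 = int(scaled[:2].sum()), int(scaled[2:].sum())
        total, phi = s1 + s2, 0.1
        mu = total / 4
        r = 2 / phi
        s = np.arange(total + 1)
        pm = stats.nbinom.pmf(s, r, r / (r + 2 * mu)) * stats.nbinom.pmf(
            total - s, r, r / (r + 2 * mu)
        )
        pm /= pm.sum()
        expected = min(1.0, 2 * min(pm[: s1 + 1].sum(), pm[s1:].sum()))
        assert res.loc["G0000", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_missing_condition_rejected(self):
        cm = _cm({"L__pre__r1": [5, 10]})
        with pytest.raises(ValueError, match="one pre and one post"):
            de_test(cm, "L")

    def test_type_one_error_calibration(self):
        """Null NB simulations (dispersion 0.1, 2 vs 2, 2000 genes, 10 seeds):
        the fraction of p < 0.05 is 0.05 within Monte-Carlo error."""
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            counts = r.poisson(r.gamma(10.0, 10.0, size=(2000, 4)))
            cm = _cm(
                {
                    "L__pre__r1": counts[:, 0],
                    "L__pre__r2": counts[:, 1],
                    "L__post__r1": counts[:, 2],
                    "L__post__r2": counts[:, 3],
                }
            )
            res = de_test(cm, "L", dispersion=0.1)
            fracs.append((res["p_value"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_power_on_planted_fourfold_changes(self):
        """Planted 4-fold inductions at mean 100 (dispersion 0.05, 3 vs 3)
        are detected at FDR < 0.05 in at least 95% of genes."""
        r = np.random.default_rng(42)
        shape = 1 / 0.05
        n_plant, n_null = 200, 1000
        mu = np.full(n_plant + n_null, 100.0)
        mu_post = mu.copy()
        mu_post[:n_plant] *= 4
        pre = r.poisson(r.gamma(shape, mu[:, None] / shape, size=(mu.size, 3)))
        post = r.poisson(r.gamma(shape, mu_post[:, None] / shape, size=(mu.size, 3)))
        cm = _cm(
            {
                **{f"L__pre__r{i+1}": pre[:, i] for i in range(3)},
                **{f"L__post__r{i+1}": post[:, i] for i in range(3)},
            }
        )
        res = de_test(cm, "L", dispersion=0.05)
        assert (res["fdr"][:n_plant] < 0.05).mean() >= 0.95

    def test_fdr_at_least_p(self, rng):
        counts = rng.poisson(80, size=(200, 2))
        cm = _cm({"L__pre__r1": counts[:, 0], "L__post__r1": counts[:, 1]})
        res = de_test(cm, "L", dispersion=0.16)
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()


class TestDEFilter:
    def test_strict_thresholds_and_direction(self):
        res = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "log2_fc": [np.log2(2.5), 1.0, -2.0, 3.0],
                "p_value": [0.001] * 4,
                "fdr": [0.01, 0.01, 0.04, 0.05],
                "mean_cpm": [10.0] * 4,
            }
        )
        out = de_filter(res, fc_threshold=2.0, fdr_threshold=0.05)
        kept = dict(zip(out["gene_id"], out["direction"]))
        assert kept == {"a": "up", "c": "down"}  # b: FC exactly 2; d: FDR exactly 0.05

    def test_empty_input(self):
        out = de_filter(pd.DataFrame(columns=["gene_id", "log2_fc", "p_value", "fdr"]))
        assert out.empty


def test_direction_balance_tracks_planted_induction_fraction(small_config):
    """With 81% of planted treatment responses being inductions, the DE-filter
    output over the treatment-responsive genes is ~81% up.

    Genes in condition-specific co-expression blocks are excluded from the
    tally: decorrelating a block between conditions necessarily changes each
    gene's per-line expression with random sign, so those calls are real but
    carry no planted direction.
    """
    import dataclasses

    from txdrivers.synthetic import generate_bundle

    cfg = dataclasses.replace(small_config, n_de_only=150, n_mediators=30)
    bundle = generate_bundle(
        n_lines=8, n_genes=2000, config=cfg, seed=21,
        nb_dispersion=0.02, expression_noise_sd=0.1,
    )
    truth = bundle.truth
    cm = CountMatrix.from_frame(
        pd.concat([bundle.counts_pre, bundle.counts_post], axis=1)
    )
    responsive = set(truth.mediator_genes) | set(truth.de_only_genes)
    ups = downs = 0
    for line in truth.line_names:
        hits = de_filter(de_test(cm, line, dispersion=0.05))
        hits = hits[hits["gene_id"].isin(responsive)]
        ups += (hits["direction"] == "up").sum()
        downs += (hits["direction"] == "down").sum()
    # realised planted fraction over per-line response events
    events = [
        v
        for d in list(truth.mediator_genes.values()) + list(truth.de_only_genes.values())
        for v in d.values()
        if v != 0
    ]
    planted_frac = np.mean([v > 0 for v in events])
    se = np.sqrt(planted_frac * (1 - planted_frac) / len(events))
    assert planted_frac == pytest.approx(
        truth.config.induction_fraction, abs=4 * se + 0.02
    )
    assert ups / (ups + downs) == pytest.approx(planted_frac, abs=0.04)


def test_mediator_fold_change_round_trip(small_config):
    """In the zero-noise limit a planted mediator's measured log2 fold change
    equals the planted per-line effect and passes the DE filter."""
    from txdrivers.synthetic import generate_expression, generate_panel

    truth = generate_panel(n_lines=11, n_genes=500, config=small_config, seed=5)
    pre, post = generate_expression(truth, 0.0, noise_sd=0.0, seed=5, deterministic=True)
    cm = CountMatrix.from_frame(pd.concat([pre, post], axis=1))
    gene, per_line = next(iter(truth.mediator_genes.items()))
    line = next(l for l, v in per_line.items() if v != 0)
    res = de_test(cm, line, dispersion=0.0).set_index("gene_id")
    assert res.loc[gene, "log2_fc"] == pytest.approx(per_line[line], abs=0.1)
    assert res.loc[gene, "fdr"] < 0.05
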