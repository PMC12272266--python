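"""JZS Bayes factors, g-prior ANOVA BFs, inclusion BFs, time-course cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from nirsdmst import stats as st

# ---------------------------------------------------------------------------
# Independent quadrature oracle for the JZS integral
# ---------------------------------------------------------------------------

def jzs_oracle(t, n, rscale):
    """Fine-grid trapezoid integration of the JZS integrand over log g."""
    nu = n - 1
    r2 = rscale**2
    u = np.linspace(-30, 30, 400_001)  # log g
    g = np.exp(u)
    log_lik = (-0.5 * np.log1p(n * g)
               - (nu + 1) / 2.0 * np.log1p(t * t / ((1 + n * g) * nu)))
    log_prior = (0.5 * np.log(r2 / 2.0) - math.lgamma(0.5)
                 - 1.5 * np.log(g) - r2 / (2.0 * g))
    integrand = np.exp(log_lik + log_prior + u)  # du jacobian: dg = g du
    num = np.trapezoid(integrand, u)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


@pytest.mark.parametrize("t", [0.5, 1.0, 2.0, 3.5, 5.0])
@pytest.mark.parametrize("n", [5, 10, 20, 50])
def test_jzs_matches_quadrature_oracle_within_one_percent(t, n):
    assert st.jzs_bf_from_t(t, n) == pytest.approx(
        jzs_oracle(t, n, st.DEFAULT_TTEST_SCALE), rel=0.01)


def test_jzs_matches_external_implementation():
    import pingouin as pg  # independent cross-check

    for t in (0.5, 1.5, 3.0):
        for n in (8, 16, 40):
            assert st.jzs_bf_from_t(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-3)


def test_jzs_null_favoring_at_t_zero_and_monotone_in_t():
    for n in (5, 16, 50):
        assert st.jzs_bf_from_t(0.0, n) < 1
    grid = [st.jzs_bf_from_t(t, 16) for t in np.arange(0.5, 5.01, 0.25)]
    assert all(b > a for a, b in zip(grid, grid[1:]))


def test_jzs_data_interface_and_zero_variance_error():
    rng = np.random.default_rng(0)
    x = rng.normal(0.5, 1, 20)
    y = rng.normal(0.0, 1, 20)
    d = x - y
    assert st.jzs_bf_ttest(x, y) == pytest.approx(st.jzs_bf_ttest(d))
    with pytest.raises(ValueError, match="zero-variance"):
        st.jzs_bf_ttest(np.ones(10))
    with pytest.raises(ValueError):
        st.jzs_bf_ttest(np.array([1.0]))


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA BF
# ---------------------------------------------------------------------------

def two_by_two_table(rng, n=16, task_eff=0.0, mat_eff=0.0, inter=0.0,
                     noise=1.0, subj_sd=1.0):
    b = rng.normal(0, subj_sd, n)
    rows = []
    for i in range(n):
        for ti, task in enumerate(("memory", "perception")):
            for mi, mat in enumerate(("musical", "verbal")):
                y = (b[i] + task_eff * (ti == 0) + mat_eff * (mi == 0)
                     + inter * (ti == 0) * (mi == 0) + rng.normal(0, noise))
                rows.append(dict(participant=i, task=task, material=mat,
                                 value=y))
    return pd.DataFrame(rows)


def test_location_invariance_of_all_model_bfs():
    rng = np.random.default_rng(1)
    df = two_by_two_table(rng, task_eff=0.8)
    m1 = st.rm_anova_bf(df, "value", ("task", "material"),
                        n_samples=50_000, seed=3)
    df2 = df.assign(value=df.value + 123.4)
    m2 = st.rm_anova_bf(df2, "value", ("task", "material"),
                        n_samples=50_000, seed=3)
    for name in m1.models:
        assert m1.models[name].bf10 == pytest.approx(
            m2.models[name].bf10, rel=1e-9)


def test_two_level_anova_reduces_to_paired_ttest_with_flat_participants():
    rng = np.random.default_rng(2)
    for eff in (0.0, 0.4, 1.0):
        df = two_by_two_table(rng, n=16, task_eff=eff)
        sub = df.groupby(["participant", "task"], as_index=False).value.mean()
        mset = st.rm_anova_bf(sub, "value", ("task",), random_slopes=False,
                              participant_prior="flat", n_samples=1000, seed=0)
        piv = sub.pivot(index="participant", columns="task", values="value")
        bf_t = st.jzs_bf_ttest(piv["memory"], piv["perception"], rscale=0.5)
        assert mset.models["task"].bf10 == pytest.approx(bf_t, rel=0.02)


def test_monte_carlo_bf_stable_across_seeds():
    rng = np.random.default_rng(3)
    df = two_by_two_table(rng, task_eff=0.7, mat_eff=0.3)
    vals = np.array([
        st.rm_anova_bf(df, "value", ("task", "material"),
                       n_samples=100_000, seed=s).models[
            "task + material"].bf10
        for s in range(10)])
    assert vals.std() / vals.mean() < 0.05


def test_unbalanced_design_rejected():
    rng = np.random.default_rng(4)
    df = two_by_two_table(rng).iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        st.rm_anova_bf(df, "value", ("task", "material"))


def test_zero_variance_response_flagged():
    rng = np.random.default_rng(5)
    df = two_by_two_table(rng, noise=0.0, subj_sd=0.0)
    with pytest.raises(ValueError, match="zero-variance"):
        st.rm_anova_bf(df, "value", ("task", "material"))


def test_strong_effect_dominates_model_comparison():
    rng = np.random.default_rng(6)
    df = two_by_two_table(rng, task_eff=2.0)
    mset = st.rm_anova_bf(df, "value", ("task", "material"),
                          n_samples=50_000, seed=1)
    assert mset.best is not None and "task" in mset.best
    assert mset.models["task"].bf10 > 10


# ---------------------------------------------------------------------------
# Inclusion BFs
# ---------------------------------------------------------------------------

def synthetic_model_set(bfs):
    return st.BFModelSet(models={
        name: st.BFResult(bf10=v, log_bf10=math.log(v)) for name, v in bfs.items()})


def test_two_model_reduction():
    ms = synthetic_model_set({"A": 7.0})
    assert st.bf_inclusion(ms, "A") == pytest.approx(7.0)


def test_four_model_inclusion_matches_hand_enumeration():
    bfs = {"A": 4.0, "B": 0.5, "A + B": 6.0, "A + B + A:B": 3.0}
    ms = synthetic_model_set(bfs)
    total = 1.0 + sum(bfs.values())
    expected_a = ((4.0 + 6.0) / total) / ((1.0 + 0.5) / total)
    assert st.bf_inclusion(ms, "A") == pytest.approx(expected_a)
    # interaction: full vs main-effects model
    assert st.bf_inclusion(ms, "A:B") == pytest.approx(3.0 / 6.0)
    assert st.bf_inclusion(ms, "B") > 0
    with pytest.raises(ValueError):
        st.bf_inclusion(ms, "C")


def test_evidence_labels():
    assert st.evidence_label(150) == "decisive (H1)"
    assert st.evidence_label(5) == "positive (H1)"
    assert st.evidence_label(0.5) == "weak (H0)"
    assert st.evidence_label(0.0001) == "decisive (H0)"


# ---------------------------------------------------------------------------
# Time-course analysis
# ---------------------------------------------------------------------------

def exp1_beta_table(rng, n=8, rois=("lIFG", "SFG"), bins=np.arange(-5.0, 19.0),
                    effect_bins=(), effect=0.0, noise=1.0):
    b = rng.normal(0, 1.0, n)
    rows = []
    for roi in rois:
        for bn in bins:
            for i in range(n):
                for task in ("memory", "perception"):
                    for mat in ("musical", "verbal"):
                        y = b[i] + rng.normal(0, noise)
                        if bn in effect_bins and task == "memory":
                            y += effect
                        rows.append(dict(participant=i, roi=roi,
                                         bin_start_s=bn, task=task,
                                         material=mat, beta=y))
    return pd.DataFrame(rows)


def test_no_statistics_outside_the_window():
    rng = np.random.default_rng(7)
    df = exp1_beta_table(rng, n=6, bins=np.arange(-5.0, 31.0))
    tc = st.analyze_timecourse(df, (-5, 18), "exp1", n_samples=500, seed=0)
    assert tc.models.bin_s.between(-5, 18).all()
    assert tc.models.bin_s.max() == 18.0


def test_degenerate_bins_flagged_not_crashed():
    rng = np.random.default_rng(8)
    df = exp1_beta_table(rng, n=6, bins=np.array([0.0, 1.0]))
    df.loc[df.bin_start_s == 1.0, "beta"] = 5.0  # zero variance at 1 s
    tc = st.analyze_timecourse(df, (0, 1), "exp1", n_samples=500, seed=0)
    flagged = tc.models[tc.models.model == "(undefined)"]
    assert (flagged.bin_s == 1.0).all() and len(flagged) == len(
        df.roi.unique())


def test_exp1_cascade_triggers_on_interaction():
    rng = np.random.default_rng(9)
    n = 12
    rows = []
    for bn in (0.0,):
        b = rng.normal(0, 0.5, n)
        for i in range(n):
            for task in ("memory", "perception"):
                for mat in ("musical", "verbal"):
                    y = b[i] + rng.normal(0, 0.5)
                    if task == "memory" and mat == "verbal":
                        y += 2.5  # pure interaction-like pattern
                    rows.append(dict(participant=i, roi="rdlPFC",
                                     bin_start_s=bn, task=task, material=mat,
                                     beta=y))
    tc = st.analyze_timecourse(pd.DataFrame(rows), (0, 0), "exp1",
                               n_samples=20_000, seed=1)
    best = tc.models[tc.models.is_best]
    assert best.model.str.contains(":").all()
    assert set(tc.posthoc.material) == {"musical", "verbal"}
    verbal = tc.posthoc[tc.posthoc.material == "verbal"]
    assert (verbal.bf10 > 3).all() and (verbal.direction > 0).all()
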