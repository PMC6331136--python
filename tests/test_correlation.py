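"""Recurrence, Fisher-z statistics, gene heats, parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from m6aflow.correlation import (
    CorrelationResult, correlate, fisher_z, gene_heat, methylation_level,
    required_sample_size, site_recurrence,
)
from m6aflow.simulate import SimulationConfig, simulate_multisample


def test_site_recurrence_distinct_sample_counting():
    calls = {
        "s1": [("t1", 10), ("t1", 10), ("t1", 99)],  # duplicate counts once
        "s2": [("t1", 10)],
        "s3": [("t1", 10)],
    }
    occ = site_recurrence(calls, n_min=3)
    assert [o.site for o in occ] == [("t1", 10)]
    assert occ[0].count == 3
    # below threshold is dropped
    assert site_recurrence(calls, n_min=4) == []
    # n_min=1 keeps everything
    assert len(site_recurrence(calls, n_min=1)) == 2


def test_required_sample_size_reference_point():
    # two-sided Fisher-z power calculation reproduces n = 12 for
    # rho = 0.8 at alpha = 0.05 with 90% power
    assert required_sample_size(0.8, 0.05, 0.9) == 12


def test_required_sample_size_monotonicity():
    grid = [0.3, 0.5, 0.7, 0.8, 0.9, 0.99]
    ns = [required_sample_size(r, 0.05, 0.9) for r in grid]
    assert ns == sorted(ns, reverse=True)  # non-increasing in rho
    assert required_sample_size(0.99, 0.05, 0.9) <= 7
    assert (
        required_sample_size(0.8, 0.05, 0.5)
        <= required_sample_size(0.8, 0.05, 0.9)
    )  # non-decreasing in power
    assert (
        required_sample_size(0.8, 0.10, 0.9)
        <= required_sample_size(0.8, 0.01, 0.9)
    )  # non-increasing in alpha
    for bad in (0.0, 1.0, -0.5):
        with pytest.raises(ValueError):
            required_sample_size(bad)


def test_methylation_level_closed_forms():
    c = 1.7
    assert methylation_level(np.full(101, c), np.exp(c)) == pytest.approx(0.0)
    assert methylation_level(np.full(101, np.log(2)), 1.0) == pytest.approx(
        np.log(2), abs=1e-12
    )
    base = methylation_level(np.full(101, 0.5), 3.0)
    doubled = methylation_level(np.full(101, 0.5), 6.0)
    assert base - doubled == pytest.approx(np.log(2), abs=1e-12)
    with pytest.raises(ValueError):
        methylation_level(np.array([np.nan] * 101), 1.0)


def test_fisher_z_reference_values():
    z, z_star = fisher_z(0.8, 12)
    assert z == pytest.approx(1.09861, abs=1e-5)
    assert z_star == pytest.approx(1.01328, abs=1e-5)
    assert fisher_z(0.0, 20) == (0.0, 0.0)


def test_correlate_agrees_with_scipy_and_corrects():
    rng = np.random.default_rng(0)
    meth = rng.normal(size=15)
    expr = 0.6 * meth + rng.normal(scale=0.5, size=15)
    res = correlate(meth, expr)
    r_ref = stats.pearsonr(meth, expr).statistic
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.z == pytest.approx(np.arctanh(r_ref), abs=1e-12)
    assert res.z_star == pytest.approx(
        res.z - (3 * res.z + res.r) / (4 * 15), abs=1e-12
    )
    # antisymmetry
    neg = correlate(-meth, expr)
    assert neg.r == pytest.approx(-res.r, abs=1e-12)
    assert neg.z_star == pytest.approx(-res.z_star, abs=1e-12)


def test_correlate_degenerate_inputs():
    with pytest.raises(ValueError, match="zero variance"):
        correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="at least 4"):
        correlate([1, 2, 3], [1, 2, 3])


def test_corrected_z_shrinks_toward_zero():
    """|z*| < |z| for every r != 0 and n >= 4, with the sign preserved."""
    for r in np.concatenate([np.arange(0.05, 1.0, 0.05),
                             -np.arange(0.05, 1.0, 0.05)]):
        for n in (4, 8, 12, 20, 50):
            z, z_star = fisher_z(float(r), n)
            assert abs(z_star) < abs(z)
            assert np.sign(z_star) == np.sign(r)


def test_gene_heat_selects_largest_absolute_z_star():
    res = lambda z_star, n=12: CorrelationResult(
        r=np.tanh(z_star), z=z_star, z_star=z_star, n=n
    )
    table = gene_heat(
        {
            ("t1", 10): ("gA", res(0.5)),
            ("t1", 90): ("gA", res(-0.9)),
            ("t2", 5): ("gB", res(0.3)),
        }
    )
    assert table.loc["gA", "heat"] == pytest.approx(0.9)
    assert table.loc["gA", "z_star"] == pytest.approx(-0.9)  # sign retained
    assert table.loc["gA", "site"] == "t1|90"
    assert table.loc["gB", "heat"] == pytest.approx(0.3)


def test_gene_heat_tie_breaks_to_lowest_site():
    res = CorrelationResult(r=0.5, z=0.55, z_star=0.5, n=12)
    neg = CorrelationResult(r=-0.5, z=-0.55, z_star=-0.5, n=12)
    table = gene_heat({("t1", 90): ("gA", neg), ("t1", 10): ("gA", res)})
    assert table.loc["gA", "site"] == "t1|10"


def test_multisample_parameter_recovery():
    """Mean recovered r over many planted genes sits near the planted rho."""
    cfg = SimulationConfig(n_genes=500, n_samples=20, planted_rho=0.8)
    data = simulate_multisample(cfg, seed=2)
    planted = data.rho[data.rho > 0].index
    rs = [
        np.corrcoef(
            data.methylation.loc[g], np.log(data.fpkm.loc[g])
        )[0, 1]
        for g in planted
    ]
    assert np.mean(rs) == pytest.approx(0.8, abs=0.05)
    null = data.rho[data.rho == 0].index
    null_rs = [
        np.corrcoef(data.methylation.loc[g], np.log(data.fpkm.loc[g]))[0, 1]
        for g in null
    ]
    assert abs(np.mean(null_rs)) < 0.05
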