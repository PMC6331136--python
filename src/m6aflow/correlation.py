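"""Recurrence filtering and methylation-expression correlation statistics.

A site called in many samples supports a statistically meaningful
correlation between its methylation degree and the expression of the host
gene.  The required recurrence comes from the power of the two-sided
Fisher-z test: to detect r = 0.8 at alpha = 0.05 with 90% power about 12
samples are needed, hence the default recurrence cutoff of 12.

Per site, methylation degree is

    Methlevel = ln( mean_j exp(RC_norm[j]) / G_FPKM )

(the window-averaged de-logged IP coverage over the host gene's FPKM), and
the Pearson correlation r of Methlevel with ln(FPKM) across the samples in
which the site was called is mapped to

    z  = atanh(r) = 1/2 ln((1+r)/(1-r))
    z* = z - (3 z + r) / (4 n)

the second-order (Hotelling) correction of the Fisher transformation.  A
gene's "heat" is the largest |z*| over its sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_RECURRENCE = 12
FPKM_FLOOR = 1e-3


@dataclass(frozen=True)
class SiteOccurrence:
    """A site together with the distinct samples in which it was called."""

    site: tuple
    samples: frozenset
    gene_id: str = ""

    @property
    def count(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its Fisher z and second-order corrected z* at size n."""

    r: float
    z: float
    z_star: float
    n: int


def site_recurrence(
    calls_per_sample: Mapping[str, Iterable[tuple]],
    gene_of_site: Mapping[tuple, str] | None = None,
    n_min: int = DEFAULT_RECURRENCE,
) -> list[SiteOccurrence]:
    """Sites called in at least ``n_min`` distinct samples.

    ``calls_per_sample`` maps sample id -> iterable of site keys; duplicate
    calls inside one sample count once.  Output sorted by site key.
    """
    samples_of: dict[tuple, set] = {}
    for sample_id, sites in calls_per_sample.items():
        for site in set(sites):
            samples_of.setdefault(site, set()).add(sample_id)
    gene_of_site = gene_of_site or {}
    return [
        SiteOccurrence(site, frozenset(samples), gene_of_site.get(site, ""))
        for site, samples in sorted(samples_of.items())
        if len(samples) >= n_min
    ]


def required_sample_size(rho: float, alpha: float = 0.05, power: float = 0.9) -> int:
    """Smallest n detecting correlation ``rho`` in a two-sided Fisher-z test.

    n >= ((z_{1-alpha/2} + z_{power}) / atanh(rho))^2 + 3, rounded up.
    """
    if not 0 < rho < 1:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    z_power = stats.norm.ppf(power)
    n = ((z_alpha + z_power) / np.arctanh(rho)) ** 2 + 3
    return int(np.ceil(n))


def methylation_level(rc_norm: np.ndarray, g_fpkm: float) -> float:
    """Methylation degree of one site in one sample (window mean over FPKM)."""
    rc_norm = np.asarray(rc_norm, dtype=np.float64)
    if not np.all(np.isfinite(rc_norm)):
        raise ValueError("RC_norm contains non-finite values")
    g_fpkm = max(float(g_fpkm), FPKM_FLOOR)
    return float(np.log(np.mean(np.exp(rc_norm)) / g_fpkm))


def fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher z and its second-order corrected z* for sample size n."""
    z = float(np.arctanh(r))
    z_star = z - (3.0 * z + r) / (4.0 * n)
    return z, z_star


def correlate(meth: Sequence[float], expr: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of methylation degree vs ln-expression, with z, z*.

    Raises on degenerate input (length < 4 or zero variance), which callers
    flag and exclude downstream.
    """
    meth = np.asarray(meth, dtype=np.float64)
    expr = np.asarray(expr, dtype=np.float64)
    if meth.shape != expr.shape or meth.ndim != 1:
        raise ValueError("methylation and expression vectors must match in length")
    n = meth.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 paired samples, got {n}")
    if np.std(meth) == 0 or np.std(expr) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(meth, expr)[0, 1])
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    z, z_star = fisher_z(r, n)
    return CorrelationResult(r=r, z=z, z_star=z_star, n=n)


def gene_heat(
    site_results: Mapping[tuple, tuple[str, CorrelationResult]]
) -> pd.DataFrame:
    """Per gene, the site with the largest |z*|; its |z*| is the gene's heat.

    ``site_results`` maps site key -> (gene_id, CorrelationResult).  Ties in
    |z*| break toward the lowest site key so the selection is deterministic.
    Returns a DataFrame indexed by gene_id with columns
    site, r, z_star, n, heat (the signed z* is retained for reporting).
    """
    best: dict[str, tuple[tuple, CorrelationResult]] = {}
    for site in sorted(site_results):
        gene, res = site_results[site]
        if gene not in best or abs(res.z_star) > abs(best[gene][1].z_star):
            best[gene] = (site, res)
    rows = []
    for gene in sorted(best):
        site, res = best[gene]
        rows.append(
            {
                "gene_id": gene,
                "site": "|".join(str(x) for x in site),
                "r": res.r,
                "z_star": res.z_star,
                "n": res.n,
                "heat": abs(res.z_star),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "site", "r", "z_star", "n", "heat"]
    )
    return df.set_index("gene_id")


def correlate_sites(
    occurrences: Sequence[SiteOccurrence],
    meth_table: Mapping[tuple, Mapping[str, float]],
    expr_table: Mapping[str, Mapping[str, float]],
) -> dict[tuple, tuple[str, CorrelationResult]]:
    """Correlate every recurrent site across the samples where it was called.

    ``meth_table`` maps site -> {sample: Methlevel}; ``expr_table`` maps
    gene -> {sample: FPKM}.  Expression is floored at 1e-3 and ln-scaled.
    Sites with degenerate vectors are skipped.
    """
    out: dict[tuple, tuple[str, CorrelationResult]] = {}
    for occ in occurrences:
        samples = sorted(occ.samples)
        gene_expr = expr_table.get(occ.gene_id, {})
        meth = []
        expr = []
        for s in samples:
            if s in meth_table.get(occ.site, {}) and s in gene_expr:
                meth.append(meth_table[occ.site][s])
                expr.append(np.log(max(gene_expr[s], FPKM_FLOOR)))
        try:
            out[occ.site] = (occ.gene_id, correlate(meth, expr))
        except ValueError:
            continue  # degenerate site: flagged by omission
    return out
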