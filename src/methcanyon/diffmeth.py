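"""Beta-distribution likelihood-ratio test for differential methylation.

Per region, the per-sample mean methylation levels are modelled as
Beta(alpha, beta) within each group. The null of a shared (alpha, beta) for
normals and tumors is tested against separate group parameters with

    D = 2 * (loglik_normal + loglik_tumor - loglik_shared),

which is asymptotically chi-squared with df = 4 - 2 = 2 (two free parameters
per group under the alternative versus two shared under the null). P-values
are BH-adjusted across all regions of a comparison, and a region is called
differentially methylated when adjusted p < 0.001 AND the DM value (absolute
difference of group mean methylation) exceeds 0.1. Calls are categorized by
direction (hyper: tumor mean above normal mean) crossed with the region's
canyon/cUMR class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core import Methylome, ReferenceUMR, Region
from .entropy_filter import region_mean_matrix

log = logging.getLogger(__name__)

CLAMP = 1e-6  # beta likelihood is undefined at the boundary
MAX_CONCENTRATION = 1e4  # cap for zero-variance groups
LRT_DF = 2  # 4 free parameters under H1 minus 2 under H0
DEFAULT_FDR = 0.001
DEFAULT_DM = 0.1


@dataclass
class BetaFit:
    alpha: float
    beta: float
    loglik: float
    n: int
    converged: bool = True

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class DMResult:
    region: Region
    umr_class: str
    fit_normal: BetaFit
    fit_tumor: BetaFit
    fit_shared: BetaFit
    D: float
    p_value: float
    dm_value: float
    fdr: float = float("nan")
    significant: bool = False
    direction: str = "none"
    category: str = "none"
    n_types_recurrent: int = 0


def _clamp(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return np.clip(v, CLAMP, 1.0 - CLAMP)


def _beta_loglik(a: float, b: float, slx: float, sl1x: float, n: int) -> float:
    return (a - 1.0) * slx + (b - 1.0) * sl1x - n * special.betaln(a, b)


def moment_estimates(values: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments (alpha, beta): alpha = m (m (1 - m) / v - 1)."""
    m = float(np.mean(values))
    v = float(np.var(values))
    m = min(max(m, CLAMP), 1.0 - CLAMP)
    if v <= 0:
        conc = MAX_CONCENTRATION
    else:
        conc = m * (1.0 - m) / v - 1.0
        conc = min(max(conc, 1e-2), MAX_CONCENTRATION)
    return m * conc, (1.0 - m) * conc


def fit_beta_mle(values: Sequence[float], tol: float = 1e-8) -> BetaFit:
    """Maximum-likelihood Beta fit of methylation fractions.

    Values are clamped to [1e-6, 1 - 1e-6]; optimization runs on
    (log alpha, log beta) with analytic gradient from a method-of-moments
    start. Zero-variance input falls back to moment estimates with the
    concentration capped at 1e4, flagged ``converged=False``.
    """
    v = _clamp(values)
    n = v.size
    if n < 3:
        raise ValueError("insufficient samples: need at least 3 values")
    slx = float(np.sum(np.log(v)))
    sl1x = float(np.sum(np.log1p(-v)))
    a0, b0 = moment_estimates(v)
    if float(np.var(v)) <= 0:
        return BetaFit(a0, b0, _beta_loglik(a0, b0, slx, sl1x, n), n, False)

    def negll_and_grad(theta):
        a, b = np.exp(theta)
        nll = -_beta_loglik(a, b, slx, sl1x, n)
        psi_ab = special.digamma(a + b)
        ga = n * (special.digamma(a) - psi_ab) - slx
        gb = n * (special.digamma(b) - psi_ab) - sl1x
        return nll, np.array([ga * a, gb * b])

    res = optimize.minimize(
        negll_and_grad,
        x0=np.log([a0, b0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(1e-4), np.log(1e6))] * 2,
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
    )
    a, b = np.exp(res.x)
    ll = _beta_loglik(a, b, slx, sl1x, n)
    ll0 = _beta_loglik(a0, b0, slx, sl1x, n)
    if not res.success or ll < ll0:
        # fall back to the moment start if the optimizer went nowhere useful
        if ll < ll0:
            a, b, ll = a0, b0, ll0
        return BetaFit(float(a), float(b), float(ll), n, False)
    return BetaFit(float(a), float(b), float(ll), n, True)


def dm_value(normal_values: Sequence[float], tumor_values: Sequence[float]) -> float:
    """Absolute difference of group mean methylation levels."""
    nv = np.asarray(normal_values, float)
    tv = np.asarray(tumor_values, float)
    nv, tv = nv[~np.isnan(nv)], tv[~np.isnan(tv)]
    if nv.size == 0 or tv.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(abs(np.mean(tv) - np.mean(nv)))


def lrt_region(
    normal_values: Sequence[float], tumor_values: Sequence[float]
) -> Tuple[float, float, BetaFit, BetaFit, BetaFit]:
    """Likelihood-ratio test of shared vs per-group Beta parameters.

    Returns (D, p, fit_normal, fit_tumor, fit_shared); D is clamped at 0 and
    p is the chi-squared (df = 2) upper tail at D.
    """
    nv = _clamp(normal_values)
    tv = _clamp(tumor_values)
    fit_n = fit_beta_mle(nv)
    fit_t = fit_beta_mle(tv)
    fit_s = fit_beta_mle(np.concatenate([nv, tv]))
    D = 2.0 * (fit_n.loglik + fit_t.loglik - fit_s.loglik)
    D = max(D, 0.0)
    p = float(stats.chi2.sf(D, LRT_DF))
    return D, p, fit_n, fit_t, fit_s


def _direction(normal_mean: float, tumor_mean: float) -> str:
    return "hyper" if tumor_mean > normal_mean else "hypo"


def _test_regions(
    ref_umrs: Sequence[ReferenceUMR],
    normal_mat: pd.DataFrame,
    tumor_mat: pd.DataFrame,
    fdr_cut: float,
    dm_cut: float,
    min_group: int,
) -> List[Optional[DMResult]]:
    """Run the LRT on every region; BH over tested regions; None where a
    group is too small."""
    results: List[Optional[DMResult]] = []
    for i, ref in enumerate(ref_umrs):
        nv = normal_mat.iloc[i].to_numpy()
        tv = tumor_mat.iloc[i].to_numpy()
        nv, tv = nv[~np.isnan(nv)], tv[~np.isnan(tv)]
        if nv.size < min_group or tv.size < min_group:
            log.info(
                "region %s skipped: group sizes %d/%d below %d",
                ref.region,
                nv.size,
                tv.size,
                min_group,
            )
            results.append(None)
            continue
        D, p, fit_n, fit_t, fit_s = lrt_region(nv, tv)
        dm = float(abs(np.mean(tv) - np.mean(nv)))
        results.append(
            DMResult(
                region=ref.region,
                umr_class=ref.umr_class,
                fit_normal=fit_n,
                fit_tumor=fit_t,
                fit_shared=fit_s,
                D=D,
                p_value=p,
                dm_value=dm,
                direction=_direction(float(np.mean(nv)), float(np.mean(tv))),
            )
        )
    tested = [r for r in results if r is not None]
    if tested:
        fdr = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, fdr):
            r.fdr = float(q)
            r.significant = (q < fdr_cut) and (r.dm_value > dm_cut)
            if r.significant:
                r.category = f"{r.direction}-{r.umr_class}"
            else:
                r.direction = "none"
                r.category = "none"
    return results


def call_pan_cancer(
    ref_umrs: Sequence[ReferenceUMR],
    normal_methylomes: Sequence[Methylome],
    tumor_methylomes: Sequence[Methylome],
    tumor_type_labels: Optional[Dict[str, str]] = None,
    fdr_cut: float = DEFAULT_FDR,
    dm_cut: float = DEFAULT_DM,
    min_group: int = 3,
) -> Tuple[List[DMResult], pd.DataFrame]:
    """Pan-cancer differential methylation over the filtered reference atlas.

    The pan-cancer comparison pools all tumors against all normals (one BH
    family over tested regions). Each tumor type is additionally tested
    against all normals the same way, and every pan-cancer result is
    annotated with the number of tumor types in which the region is also
    significant. Returns (results, per-type significance table).
    """
    if tumor_type_labels is None:
        tumor_type_labels = {
            m.sample_id: (m.tumor_type or "tumor") for m in tumor_methylomes
        }
    normal_mat = region_mean_matrix(normal_methylomes, ref_umrs)
    tumor_mat = region_mean_matrix(tumor_methylomes, ref_umrs)
    pan = _test_regions(ref_umrs, normal_mat, tumor_mat, fdr_cut, dm_cut, min_group)

    types = sorted(set(tumor_type_labels.values()))
    region_ids = normal_mat.index
    per_type = pd.DataFrame(False, index=region_ids, columns=types)
    for t in types:
        ids = [sid for sid, lab in tumor_type_labels.items() if lab == t]
        sub = tumor_mat[[c for c in tumor_mat.columns if c in ids]]
        res_t = _test_regions(ref_umrs, normal_mat, sub, fdr_cut, dm_cut, min_group)
        per_type[t] = [bool(r is not None and r.significant) for r in res_t]

    results = [r for r in pan if r is not None]
    rec = per_type.sum(axis=1)
    for r in results:
        rid = f"{r.region.chrom}:{r.region.start}-{r.region.end}"
        r.n_types_recurrent = int(rec.loc[rid])
    return results, per_type


def conserved_controls(
    dm_results: Sequence[DMResult], per_type: pd.DataFrame
) -> Tuple[List[DMResult], List[DMResult]]:
    """Conserved canyons and cUMRs: regions not differentially methylated in
    any individual tumor type."""
    canyons, cumrs = [], []
    for r in dm_results:
        rid = f"{r.region.chrom}:{r.region.start}-{r.region.end}"
        if rid in per_type.index and not per_type.loc[rid].any():
            (canyons if r.umr_class == "canyon" else cumrs).append(r)
    return canyons, cumrs


def results_table(results: Sequence[DMResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.region.chrom,
                "start": r.region.start,
                "end": r.region.end,
                "class": r.umr_class,
                "alpha_normal": r.fit_normal.alpha,
                "beta_normal": r.fit_normal.beta,
                "alpha_tumor": r.fit_tumor.alpha,
                "beta_tumor": r.fit_tumor.beta,
                "alpha_shared": r.fit_shared.alpha,
                "beta_shared": r.fit_shared.beta,
                "D": r.D,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "dm_value": r.dm_value,
                "direction": r.direction,
                "category": r.category,
                "n_types_recurrent": r.n_types_recurrent,
            }
        )
    return pd.DataFrame(rows)
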