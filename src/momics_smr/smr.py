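"""Instrument selection, the SMR ratio test, and the HEIDI heterogeneity test.

The ratio estimate for a probe is b_xy = b_zy / b_zx with delta-method
standard error; its test statistic T = z_zx^2 * z_zy^2 / (z_zx^2 + z_zy^2)
is referred to a chi-square with one degree of freedom. HEIDI compares the
ratio at SNPs in LD with the instrument against the instrument's own ratio;
heterogeneity indicates linkage or pleiotropy rather than a single shared
causal variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import (
    AssocDataset,
    LDMatrix,
    ProbeAnnotation,
    VariantStat,
    cis_window,
    harmonize,
)

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8

#: Default HEIDI eligibility rules (published SMR tool defaults; configurable).
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_EXPOSURE_P = 1.57e-3  # |z_zx| > 3.16
HEIDI_MAX_SNPS = 20


class UndefinedRatioError(ZeroDivisionError):
    """The instrument has zero exposure effect, so the ratio is undefined."""


@dataclass
class SMRResult:
    """SMR estimate for one probe-outcome pair (optionally with HEIDI)."""

    probe_id: str
    outcome_id: str
    top_snp: str
    b_zx: float
    se_zx: float
    b_zy: float
    se_zy: float
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: Optional[float] = None
    n_heidi_snps: int = 0
    or_xy: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None
    gene_id: str = ""


@dataclass
class LayerThresholds:
    """Numeric knobs of a per-layer SMR + HEIDI run."""

    instrument_p: float = GENOME_WIDE_P
    q_significant: float = 0.05
    heidi_p: float = 0.05
    heidi_r2_min: float = HEIDI_R2_MIN
    heidi_r2_max: float = HEIDI_R2_MAX
    heidi_exposure_p: float = HEIDI_EXPOSURE_P
    heidi_max_snps: int = HEIDI_MAX_SNPS
    cis_flank: int = 1_000_000


def select_instrument(
    exposure: AssocDataset,
    probe: ProbeAnnotation,
    window: Optional[tuple[int, int]] = None,
    p_threshold: float = GENOME_WIDE_P,
) -> Optional[VariantStat]:
    """Most significant cis-SNP below genome-wide significance, or None.

    Ties on p are broken by distance to the probe midpoint, then snp_id."""
    if window is None:
        window = cis_window(probe, 1_000_000, "gene_body")
    lo, hi = window
    candidates = [
        r for r in exposure.records
        if r.chrom == probe.chrom and lo <= r.pos <= hi and r.p < p_threshold
    ]
    if not candidates:
        logger.info("probe %s: no instrument at p < %.3g", probe.probe_id, p_threshold)
        return None
    mid = probe.midpoint
    return min(candidates, key=lambda r: (r.p, abs(r.pos - mid), r.snp_id))


def ratio_estimate(
    b_zx: float, se_zx: float, b_zy: float, se_zy: float
) -> tuple[float, float]:
    """Wald/SMR ratio b_zy / b_zx and its first-order delta-method SE.

    Shared by the SMR test and the phenome-wide Wald-ratio screen so the two
    are numerically identical on the same inputs."""
    if b_zx == 0.0:
        raise UndefinedRatioError("exposure effect b_zx is zero")
    b_xy = b_zy / b_zx
    # Algebraically (b_zy^2/b_zx^2) * (se_zy^2/b_zy^2 + se_zx^2/b_zx^2),
    # written to stay finite at b_zy = 0.
    var_xy = (se_zy**2 / b_zx**2) + (b_zy**2 * se_zx**2 / b_zx**4)
    return b_xy, float(np.sqrt(var_xy))


def smr_statistic(z_zx: float, z_zy: float) -> float:
    """T_SMR = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2); 0 when both z are 0."""
    q_x, q_y = z_zx * z_zx, z_zy * z_zy
    denom = q_x + q_y
    if denom == 0.0:
        return 0.0
    return q_x * q_y / denom


def smr_test(
    exposure: VariantStat,
    outcome: VariantStat,
    binary_outcome: bool = False,
    probe_id: str = "",
    outcome_id: str = "",
    gene_id: str = "",
) -> SMRResult:
    """SMR ratio test at one harmonized instrument SNP."""
    if exposure.snp_id != outcome.snp_id:
        raise ValueError("exposure/outcome stats are for different SNPs")
    b_xy, se_xy = ratio_estimate(exposure.beta, exposure.se, outcome.beta, outcome.se)
    t_smr = smr_statistic(exposure.z, outcome.z)
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    res = SMRResult(
        probe_id=probe_id,
        outcome_id=outcome_id,
        gene_id=gene_id,
        top_snp=exposure.snp_id,
        b_zx=exposure.beta,
        se_zx=exposure.se,
        b_zy=outcome.beta,
        se_zy=outcome.se,
        b_xy=b_xy,
        se_xy=se_xy,
        p_smr=p_smr,
    )
    if binary_outcome:
        res.or_xy = float(np.exp(b_xy))
        res.or_ci_low = float(np.exp(b_xy - 1.959963984540054 * se_xy))
        res.or_ci_high = float(np.exp(b_xy + 1.959963984540054 * se_xy))
    return res


def _heidi_covariance(
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    r: np.ndarray,
    top: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference vector d_i = b_xy(i) - b_xy(top) and its delta-method
    covariance, using cov(b_i, b_j) = r_ij * se_i * se_j within each trait
    and independence across the exposure and outcome samples."""
    m = len(b_zx)
    others = [i for i in range(m) if i != top]
    d = b_zy[others] / b_zx[others] - b_zy[top] / b_zx[top]

    cov_y = r * np.outer(se_zy, se_zy)
    cov_x = r * np.outer(se_zx, se_zx)

    # Gradients of d_i w.r.t. the outcome and exposure marginal estimates.
    g_y = np.zeros((len(others), m))
    g_x = np.zeros((len(others), m))
    for row, i in enumerate(others):
        g_y[row, i] = 1.0 / b_zx[i]
        g_y[row, top] = -1.0 / b_zx[top]
        g_x[row, i] = -b_zy[i] / b_zx[i] ** 2
        g_x[row, top] = b_zy[top] / b_zx[top] ** 2
    v = g_y @ cov_y @ g_y.T + g_x @ cov_x @ g_x.T
    return d, v


def satterthwaite_pvalue(t: float, corr: np.ndarray) -> float:
    """Tail probability of a sum of squared correlated standard normals by
    two-moment (Satterthwaite) matching to a scaled chi-square."""
    lam = np.linalg.eigvalsh(corr)
    lam = lam[lam > 1e-12]
    s1, s2 = lam.sum(), (lam**2).sum()
    if s1 <= 0:
        return 1.0
    scale = s2 / s1
    df = s1**2 / s2
    return float(stats.chi2.sf(t / scale, df=df))


def heidi_test(
    exposure: AssocDataset,
    outcome: AssocDataset,
    ld: LDMatrix,
    top_snp: str,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    exposure_p_threshold: float = HEIDI_EXPOSURE_P,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[Optional[float], int]:
    """HEIDI heterogeneity test around the instrument SNP.

    Eligible SNPs have r^2 with the instrument in [r2_min, r2_max] and
    exposure p below ``exposure_p_threshold``; the ``max_snps`` most
    significant (by exposure p) are used. Returns ``(None, 0)`` when no SNP
    is eligible (probe retained, HEIDI not evaluable).
    """
    exp_lookup = exposure.by_snp()
    out_lookup = outcome.by_snp()
    if top_snp not in exp_lookup or top_snp not in out_lookup:
        raise ValueError(f"top SNP {top_snp} missing from harmonized datasets")
    ld_idx = ld.index()
    if top_snp not in ld_idx:
        raise ValueError(f"top SNP {top_snp} missing from LD matrix")

    eligible = []
    for snp in exposure.snp_ids():
        if snp == top_snp or snp not in out_lookup or snp not in ld_idx:
            continue
        r2 = ld.r[ld_idx[snp], ld_idx[top_snp]] ** 2
        e = exp_lookup[snp]
        if r2_min <= r2 <= r2_max and e.p < exposure_p_threshold and e.beta != 0.0:
            eligible.append((e.p, snp))
    if not eligible:
        return None, 0
    eligible.sort()
    chosen = [snp for _, snp in eligible[:max_snps]]

    snps = chosen + [top_snp]
    idx = [ld_idx[s] for s in snps]
    r = ld.r[np.ix_(idx, idx)]
    b_zx = np.array([exp_lookup[s].beta for s in snps])
    se_zx = np.array([exp_lookup[s].se for s in snps])
    b_zy = np.array([out_lookup[s].beta for s in snps])
    se_zy = np.array([out_lookup[s].se for s in snps])

    d, v = _heidi_covariance(b_zx, se_zx, b_zy, se_zy, r, top=len(snps) - 1)
    sd = np.sqrt(np.diag(v))
    if np.any(sd <= 0):
        return 1.0, len(chosen)
    z_d = d / sd
    corr = v / np.outer(sd, sd)
    t = float(np.sum(z_d**2))
    return satterthwaite_pvalue(t, corr), len(chosen)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of m * p_(j) / j, clipped at 1; output is in the
    input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


FLAG_SIGNIFICANT = "significant"
FLAG_PLEIOTROPIC = "pleiotropic"
FLAG_NOT_SIGNIFICANT = "not_significant"
FLAG_HEIDI_NA = "heidi_not_evaluable"

RESULT_COLUMNS = [
    "probe_id", "gene_id", "top_snp", "b_zx", "se_zx", "b_zy", "se_zy",
    "b_xy", "se_xy", "or_xy", "ci_low", "ci_high", "p_smr", "q_smr",
    "p_heidi", "n_heidi_snps", "flag",
]


def run_layer(
    probes: Sequence[ProbeAnnotation],
    exposure_data: dict[str, AssocDataset],
    outcome_data: AssocDataset,
    ld_store: Callable[[str], LDMatrix],
    thresholds: Optional[LayerThresholds] = None,
    outcome_id: str = "outcome",
) -> pd.DataFrame:
    """SMR + HEIDI over all probes of one omics layer against one outcome.

    ``exposure_data`` maps probe_id to that probe's cis SNP associations;
    ``ld_store`` maps probe_id to an LD matrix covering the region. FDR is
    computed within this (layer x outcome) family. A probe is flagged
    ``significant`` iff q < q_significant and p_heidi > heidi_p; probes with
    no evaluable HEIDI SNPs are flagged separately, never excluded.
    """
    thr = thresholds or LayerThresholds()
    binary = outcome_data.trait_type == "case_control"
    rows: list[SMRResult] = []
    for probe in probes:
        if probe.probe_id not in exposure_data:
            logger.info("probe %s: no exposure data, skipped", probe.probe_id)
            continue
        try:
            exp_h, out_h, ld_h = harmonize(
                exposure_data[probe.probe_id], outcome_data, ld_store(probe.probe_id)
            )
        except Exception as exc:
            logger.warning("probe %s: harmonization failed (%s), skipped", probe.probe_id, exc)
            continue
        window = cis_window(probe, thr.cis_flank, "gene_body")
        top = select_instrument(exp_h, probe, window, thr.instrument_p)
        if top is None:
            continue
        res = smr_test(
            top, out_h.by_snp()[top.snp_id], binary_outcome=binary,
            probe_id=probe.probe_id, outcome_id=outcome_id, gene_id=probe.gene_id,
        )
        res.p_heidi, res.n_heidi_snps = heidi_test(
            exp_h, out_h, ld_h, top.snp_id,
            r2_min=thr.heidi_r2_min, r2_max=thr.heidi_r2_max,
            exposure_p_threshold=thr.heidi_exposure_p, max_snps=thr.heidi_max_snps,
        )
        rows.append(res)

    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "top_snp": [r.top_snp for r in rows],
            "b_zx": [r.b_zx for r in rows],
            "se_zx": [r.se_zx for r in rows],
            "b_zy": [r.b_zy for r in rows],
            "se_zy": [r.se_zy for r in rows],
            "b_xy": [r.b_xy for r in rows],
            "se_xy": [r.se_xy for r in rows],
            "or_xy": [r.or_xy for r in rows],
            "ci_low": [r.or_ci_low for r in rows],
            "ci_high": [r.or_ci_high for r in rows],
            "p_smr": [r.p_smr for r in rows],
            "p_heidi": [r.p_heidi for r in rows],
            "n_heidi_snps": [r.n_heidi_snps for r in rows],
        }
    )
    df["q_smr"] = bh_fdr(df["p_smr"].to_numpy())
    df["flag"] = [
        _flag(q, ph, thr) for q, ph in zip(df["q_smr"], df["p_heidi"])
    ]
    return df[RESULT_COLUMNS]


def _flag(q: float, p_heidi: Optional[float], thr: LayerThresholds) -> str:
    if q >= thr.q_significant:
        return FLAG_NOT_SIGNIFICANT
    if p_heidi is None or (isinstance(p_heidi, float) and np.isnan(p_heidi)):
        return FLAG_HEIDI_NA
    if p_heidi <= thr.heidi_p:
        return FLAG_PLEIOTROPIC
    return FLAG_SIGNIFICANT
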