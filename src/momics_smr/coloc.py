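"""Bayesian colocalization over a cis-region.

Per-SNP Wakefield approximate Bayes factors for each of two traits are
combined into posterior probabilities of five hypotheses: H0 no association,
H1/H2 association with only trait 1/2, H3 both traits via distinct causal
variants, H4 both traits via a shared causal variant. The framework assumes
at most one causal variant per trait in the region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .sumstats_io import (
    CASE_CONTROL,
    AssocDataset,
    ProbeAnnotation,
    cis_window,
    harmonize,
)
from . import smr as _smr

logger = logging.getLogger(__name__)

#: Prior SD of true effects: per-SD scale for quantitative traits,
#: log-odds scale for case-control traits.
W_QUANTITATIVE = 0.15
W_CASE_CONTROL = 0.2

PP_STRONG = 0.7
PP_MODERATE = 0.5

LABEL_STRONG = "strong"
LABEL_MODERATE = "moderate"
LABEL_NONE = "none"

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


class EmptyRegionError(ValueError):
    """No SNPs available for colocalization."""


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association with trait 1 only (p1),
    trait 2 only (p2), and both traits (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        # p12 = 0 is tolerated (nullifies H4), mainly for sensitivity checks.
        if not (0.0 <= self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 <= p12 <= min(p1, p2)")
        if min(self.p1, self.p2) <= 0.0:
            raise ValueError("p1 and p2 must be > 0")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("priors must sum to < 1")


@dataclass
class ColocResult:
    probe_id: str
    outcome_id: str
    n_snps: int
    pp: dict[str, float]

    @property
    def label(self) -> str:
        return classify_pp_h4(self.pp["pp_h4"])


def classify_pp_h4(pp_h4: float) -> str:
    """Strong colocalization above 0.7, moderate in (0.5, 0.7], else none."""
    if pp_h4 > PP_STRONG:
        return LABEL_STRONG
    if pp_h4 > PP_MODERATE:
        return LABEL_MODERATE
    return LABEL_NONE


def wakefield_labf(beta, se, trait_type: str = "quantitative", w: Optional[float] = None):
    """Log approximate Bayes factor for one SNP association.

    With V = se^2, prior variance W and r = W / (V + W):
    lABF = 0.5 * (log(1 - r) + r * z^2). Vectorized over beta/se."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if w is None:
        w = W_CASE_CONTROL**2 if trait_type == CASE_CONTROL else W_QUANTITATIVE**2
    v = se**2
    r = w / (v + w)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def coloc_pp(
    labf1,
    labf2,
    priors: Optional[ColocPriors] = None,
    probe_id: str = "",
    outcome_id: str = "",
) -> ColocResult:
    """Posterior probabilities of H0-H4 from two vectors of log ABFs.

    All arithmetic is done in log space with log-sum-exp. The H3 sum over
    distinct SNP pairs is evaluated via the identity
    sum_{i != j} = (sum_i)(sum_j) - sum_{i = j}, with negative round-off
    clamped to zero probability."""
    priors = priors or ColocPriors()
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("labf1 and labf2 must be equal-length vectors")
    m = labf1.size
    if m == 0:
        raise EmptyRegionError("no SNPs in region")

    s1 = logsumexp(labf1)
    s2 = logsumexp(labf2)
    s12 = logsumexp(labf1 + labf2)

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(priors.p1) + s1
    log_h[2] = np.log(priors.p2) + s2
    if m == 1:
        log_h[3] = -np.inf
    else:
        # log(exp(s1 + s2) - exp(s12)); the diagonal is a subset so the
        # difference is non-negative up to round-off.
        delta = s12 - (s1 + s2)
        if delta >= 0.0:
            if delta > 1e-9:
                warnings.warn("H3 cross-sum underflow; clamping PP.H3 to 0")
            log_h[3] = -np.inf
        else:
            log_h[3] = s1 + s2 + np.log1p(-np.exp(delta)) + np.log(priors.p1) + np.log(priors.p2)
    with np.errstate(divide="ignore"):
        log_h[4] = np.log(priors.p12) + s12

    log_total = logsumexp(log_h)
    pp = np.exp(log_h - log_total)
    return ColocResult(
        probe_id=probe_id,
        outcome_id=outcome_id,
        n_snps=m,
        pp=dict(zip(HYPOTHESES, (float(x) for x in pp))),
    )


def coloc_enumerate(
    labf1,
    labf2,
    priors: Optional[ColocPriors] = None,
    max_snps: int = 12,
) -> ColocResult:
    """Exact enumeration over all (m+1)^2 causal-configuration pairs.

    Test oracle only: refuses regions larger than ``max_snps``."""
    priors = priors or ColocPriors()
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    m = labf1.size
    if m == 0:
        raise EmptyRegionError("no SNPs in region")
    if m > max_snps:
        raise ValueError(f"enumeration oracle limited to {max_snps} SNPs, got {m}")

    bf1 = np.exp(labf1)
    bf2 = np.exp(labf2)
    weights = {h: 0.0 for h in HYPOTHESES}
    weights["pp_h0"] = 1.0
    for i in range(m):
        weights["pp_h1"] += priors.p1 * bf1[i]
        weights["pp_h2"] += priors.p2 * bf2[i]
        weights["pp_h4"] += priors.p12 * bf1[i] * bf2[i]
        for j in range(m):
            if i != j:
                weights["pp_h3"] += priors.p1 * priors.p2 * bf1[i] * bf2[j]
    total = sum(weights.values())
    pp = {h: w / total for h, w in weights.items()}
    return ColocResult(probe_id="", outcome_id="", n_snps=m, pp=pp)


#: Colocalization window conventions per molecular layer: methylation regions
#: are +/-500 kb around the top cis-SNP; expression and protein regions are
#: +/-1 Mb around the gene body.
WINDOW_SPECS = {
    "methylation": ("top_snp", 500_000),
    "expression": ("gene_body", 1_000_000),
    "protein": ("gene_body", 1_000_000),
}


def run_coloc(
    exposure: AssocDataset,
    outcome: AssocDataset,
    probe: ProbeAnnotation,
    priors: Optional[ColocPriors] = None,
    outcome_id: str = "outcome",
    w1: Optional[float] = None,
    w2: Optional[float] = None,
) -> ColocResult:
    """Harmonize, window per the probe's layer convention, and colocalize."""
    anchor, flank = WINDOW_SPECS[probe.layer]
    exp_h, out_h, _ = harmonize(exposure, outcome)
    if anchor == "top_snp":
        top = _smr.select_instrument(exp_h, probe, window=(1, 2**62), p_threshold=1.0)
        if top is None:
            raise EmptyRegionError(f"probe {probe.probe_id}: no SNPs for top-SNP window")
        window = cis_window(probe, flank, "top_snp", top_snp_pos=top.pos)
    else:
        window = cis_window(probe, flank, "gene_body")
    lo, hi = window
    snps = [r.snp_id for r in exp_h.records if lo <= r.pos <= hi and r.chrom == probe.chrom]
    if not snps:
        raise EmptyRegionError(f"probe {probe.probe_id}: empty coloc region")
    exp_w = exp_h.subset(snps)
    out_w = out_h.subset(snps)
    labf1 = wakefield_labf(
        [r.beta for r in exp_w.records], [r.se for r in exp_w.records],
        trait_type=exp_w.trait_type, w=w1,
    )
    labf2 = wakefield_labf(
        [r.beta for r in out_w.records], [r.se for r in out_w.records],
        trait_type=out_w.trait_type, w=w2,
    )
    return coloc_pp(labf1, labf2, priors, probe_id=probe.probe_id, outcome_id=outcome_id)
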