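"""Synthetic cis-regions of LD-correlated summary statistics.

Summary statistics are generated directly at the summary level: for
standardized genotypes the marginal effect vector is ``R @ beta_joint`` and
the sampling noise of the estimated marginals is ``N(0, R / n)`` (the standard
shared-sample result), so no individual-level genotypes are ever simulated.
Outputs are expressed per effect allele so that ratio estimators cancel the
allele scaling, exactly as with real per-allele summary data.

Case-control traits are generated on the log-odds scale with
``se = 1 / sqrt(n * v * 2 * maf * (1 - maf))`` where
``v = (n_cases/n) * (n_controls/n)`` — a small-effect approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .sumstats_io import (
    CASE_CONTROL,
    QUANTITATIVE,
    AssocDataset,
    LDMatrix,
    ProbeAnnotation,
    VariantStat,
)

#: Cohort sizes of the real data sources, usable as named presets.
SAMPLE_SIZE_PRESETS = {
    "mqtl_blood": 1980,
    "eqtlgen": 31684,
    "decode": 35559,
    "diagram_cases": 242283,
    "diagram_controls": 1569734,
}

# Non-palindromic allele pairs so harmonization keeps every simulated SNP.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_BASE_POS = 1_000_000
_SNP_SPACING = 2_000


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class RegionSpec:
    """Specification of one simulated cis-region."""

    m_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_model: str = "ar1"
    rho: float = 0.8
    block_sizes: Optional[tuple[int, ...]] = None
    within_r: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ParameterError("m_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.ld_model == "ar1":
            if not (0.0 <= self.rho < 1.0):
                raise ParameterError(f"ar1 rho must be in [0, 1), got {self.rho}")
        elif self.ld_model == "block":
            if self.block_sizes is None or sum(self.block_sizes) != self.m_snps:
                raise ParameterError("block sizes must sum to m_snps")
            if not (0.0 <= self.within_r < 1.0):
                raise ParameterError("within_r must be in [0, 1)")
        else:
            raise ParameterError(f"unknown ld_model {self.ld_model!r}")


@dataclass(frozen=True)
class CaseControlDesign:
    n_cases: int
    n_controls: int

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def v(self) -> float:
        return (self.n_cases / self.n) * (self.n_controls / self.n)


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the five colocalization scenarios for a pair of traits.

    H0: neither trait has a causal variant; H1/H2: only trait 1/2; H3: both,
    at distinct SNPs; H4: both, at the same SNP.
    """

    hypothesis: str
    n1: int
    n2: int
    causal_index_trait1: Optional[int] = None
    causal_index_trait2: Optional[int] = None
    var_explained_1: float = 0.01
    var_explained_2: float = 0.01
    trait2_design: Union[str, CaseControlDesign] = QUANTITATIVE

    def __post_init__(self) -> None:
        h = self.hypothesis
        if h not in ("H0", "H1", "H2", "H3", "H4"):
            raise ParameterError(f"unknown hypothesis {h!r}")
        if not (0.0 <= self.var_explained_1 < 1.0) or not (0.0 <= self.var_explained_2 < 1.0):
            raise ParameterError("var_explained must be in [0, 1)")
        c1, c2 = self.causal_index_trait1, self.causal_index_trait2
        if h in ("H1", "H3", "H4") and c1 is None:
            raise ParameterError(f"{h} requires causal_index_trait1")
        if h in ("H2", "H3") and c2 is None:
            raise ParameterError(f"{h} requires causal_index_trait2")
        if h == "H4" and c2 is not None and c2 != c1:
            raise ParameterError("H4 requires a shared causal index")
        if h == "H3" and c1 == c2:
            raise ParameterError("H3 requires distinct causal indices")


@dataclass(frozen=True)
class ChainSpec:
    """Causal chain SNP -> methylation -> expression -> {protein, disease}.

    ``theta_me`` is the effect of methylation on expression (SD per SD),
    ``theta_ep`` of expression on protein, and ``theta_ed`` of expression on
    disease liability (log-odds per SD). By construction the true SMR ratio
    methylation->expression equals ``theta_me`` and expression->disease
    equals ``theta_ed``.
    """

    theta_me: float
    theta_ep: float
    theta_ed: float
    causal_index: int
    n_meth: int = 10_000
    n_expr: int = 30_000
    n_prot: int = 30_000
    disease_design: CaseControlDesign = field(
        default_factory=lambda: CaseControlDesign(25_000, 25_000)
    )
    var_explained_meth: float = 0.05

    def __post_init__(self) -> None:
        for theta in (self.theta_me, self.theta_ep, self.theta_ed):
            if not np.isfinite(theta):
                raise ParameterError("chain effects must be finite")
        for n in (self.n_meth, self.n_expr, self.n_prot, self.disease_design.n):
            if n < 100:
                raise ParameterError("sample sizes must be >= 100")
        if not (0.0 < self.var_explained_meth < 1.0):
            raise ParameterError("var_explained_meth must be in (0, 1)")


@dataclass
class Region:
    """A simulated cis-region: SNP annotations, LD matrix and MAF vector."""

    spec: RegionSpec
    snp_ids: list[str]
    chrom: str
    positions: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    maf: np.ndarray
    ld: LDMatrix
    _chol: Optional[np.ndarray] = None

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def cholesky(self) -> np.ndarray:
        """Cached Cholesky factor of the LD matrix (jittered if needed)."""
        if self._chol is None:
            r = self.ld.r
            try:
                self._chol = np.linalg.cholesky(r)
            except np.linalg.LinAlgError:
                self._chol = np.linalg.cholesky(r + 1e-10 * np.eye(self.m))
        return self._chol


def _build_ld(spec: RegionSpec) -> np.ndarray:
    m = spec.m_snps
    if spec.ld_model == "ar1":
        idx = np.arange(m)
        return spec.rho ** np.abs(idx[:, None] - idx[None, :])
    blocks = []
    for size in spec.block_sizes:  # type: ignore[union-attr]
        b = np.full((size, size), spec.within_r)
        np.fill_diagonal(b, 1.0)
        blocks.append(b)
    out = np.zeros((m, m))
    off = 0
    for b in blocks:
        k = b.shape[0]
        out[off : off + k, off : off + k] = b
        off += k
    return out


def simulate_region(spec: RegionSpec) -> Region:
    """Build SNP annotations, LD matrix and MAFs for one cis-region.

    Deterministic for a fixed spec (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.m_snps
    snp_ids = [f"rs{spec.seed % 1000:03d}{i:05d}" for i in range(m)]
    positions = _BASE_POS + _SNP_SPACING * np.arange(m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=m)
    r = _build_ld(spec)
    ld = LDMatrix(snp_ids, r, effect_alleles=ea, other_alleles=oa, eaf=maf.copy())
    return Region(spec, snp_ids, "1", positions, ea, oa, maf, ld)


def default_probe(region: Region, layer: str, probe_id: Optional[str] = None,
                  gene_id: str = "GENE1") -> ProbeAnnotation:
    """A probe annotation centered on the simulated region."""
    center = int(region.positions[region.m // 2])
    if layer == "methylation":
        start = end = center
    else:
        start, end = max(1, center - 10_000), center + 10_000
    default_ids = {"methylation": "cg00000001", "expression": gene_id, "protein": f"{gene_id}_prot"}
    return ProbeAnnotation(
        probe_id=probe_id or default_ids[layer],
        gene_id=gene_id,
        chrom=region.chrom,
        start=start,
        end=end,
        layer=layer,
    )


def _draw_marginals(
    region: Region,
    beta_joint: np.ndarray,
    se_sd_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw observed per-allele marginal betas and their SEs.

    On the standardized-genotype scale the estimated marginals are
    ``R @ beta_joint + L @ eps * se`` with ``L`` the Cholesky factor of R;
    both are then rescaled to the per-allele scale by 1/sqrt(2*maf*(1-maf)).
    """
    marg_sd = region.ld.r @ beta_joint
    noise = region.cholesky() @ rng.standard_normal(region.m)
    beta_sd = marg_sd + se_sd_scale * noise
    allele_scale = np.sqrt(2.0 * region.maf * (1.0 - region.maf))
    return beta_sd / allele_scale, np.full(region.m, se_sd_scale) / allele_scale


def _dataset_from_betas(
    region: Region,
    trait_id: str,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait_type: str = QUANTITATIVE,
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
) -> AssocDataset:
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
    records = [
        VariantStat(
            snp_id=region.snp_ids[i],
            chrom=region.chrom,
            pos=int(region.positions[i]),
            effect_allele=region.effect_alleles[i],
            other_allele=region.other_alleles[i],
            eaf=float(region.maf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            p=float(p[i]),
            n=float(n),
        )
        for i in range(region.m)
    ]
    return AssocDataset(trait_id, trait_type, records, n_cases=n_cases, n_controls=n_controls)


def simulate_sumstats(
    region: Region,
    scenario: ScenarioSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AssocDataset, AssocDataset]:
    """Simulate a pair of trait summary-statistic datasets under H0-H4.

    The causal SNP's joint effect is sized so it explains ``var_explained``
    of trait variance; the expected causal-SNP |z| is therefore approximately
    ``sqrt(n * var_explained)`` for quantitative traits (and
    ``sqrt(n * v * var_explained)`` for case-control)."""
    if rng is None:
        rng = np.random.default_rng(seed)

    b1 = np.zeros(region.m)
    b2 = np.zeros(region.m)
    h = scenario.hypothesis
    if h in ("H1", "H3", "H4"):
        b1[scenario.causal_index_trait1] = np.sqrt(scenario.var_explained_1)
    if h in ("H2", "H3"):
        b2[scenario.causal_index_trait2] = np.sqrt(scenario.var_explained_2)
    if h == "H4":
        b2[scenario.causal_index_trait1] = np.sqrt(scenario.var_explained_2)

    beta1, se1 = _draw_marginals(region, b1, 1.0 / np.sqrt(scenario.n1), rng)
    trait1 = _dataset_from_betas(region, "trait1", beta1, se1, scenario.n1)

    design = scenario.trait2_design
    if isinstance(design, CaseControlDesign):
        se_scale = 1.0 / np.sqrt(design.n * design.v)
        beta2, se2 = _draw_marginals(region, b2, se_scale, rng)
        trait2 = _dataset_from_betas(
            region, "trait2", beta2, se2, design.n, CASE_CONTROL,
            n_cases=design.n_cases, n_controls=design.n_controls,
        )
    else:
        beta2, se2 = _draw_marginals(region, b2, 1.0 / np.sqrt(scenario.n2), rng)
        trait2 = _dataset_from_betas(region, "trait2", beta2, se2, scenario.n2)
    return trait1, trait2


def simulate_chain(
    region: Region,
    chain: ChainSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, AssocDataset]:
    """Simulate the four layers of a molecular causal chain sharing one SNP.

    Returns a map ``{"methylation", "expression", "protein", "disease"}`` to
    per-layer :class:`AssocDataset` (independent samples per layer)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    c = chain.causal_index
    if not (0 <= c < region.m):
        raise ParameterError(f"causal_index {c} outside region of {region.m} SNPs")

    b_meth = np.sqrt(chain.var_explained_meth)
    b_expr = chain.theta_me * b_meth
    b_prot = chain.theta_ep * b_expr
    b_dis = chain.theta_ed * b_expr  # log-odds per SD genotype

    out: dict[str, AssocDataset] = {}
    for layer, effect, n in (
        ("methylation", b_meth, chain.n_meth),
        ("expression", b_expr, chain.n_expr),
        ("protein", b_prot, chain.n_prot),
    ):
        bj = np.zeros(region.m)
        bj[c] = effect
        beta, se = _draw_marginals(region, bj, 1.0 / np.sqrt(n), rng)
        out[layer] = _dataset_from_betas(region, layer, beta, se, n)

    design = chain.disease_design
    bj = np.zeros(region.m)
    bj[c] = b_dis
    se_scale = 1.0 / np.sqrt(design.n * design.v)
    beta, se = _draw_marginals(region, bj, se_scale, rng)
    out["disease"] = _dataset_from_betas(
        region, "disease", beta, se, design.n, CASE_CONTROL,
        n_cases=design.n_cases, n_controls=design.n_controls,
    )
    return out
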