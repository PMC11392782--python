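"""Phenome-wide Wald-ratio screening and hypergeometric over-representation.

The phenome screen tests each gene's instrument SNP against many disease
phenotypes with the single-instrument Wald ratio, drops phenotypes with too
few cases before testing, and applies one Benjamini-Hochberg correction over
the pooled (gene x phenotype) family. Over-representation uses the exact
hypergeometric upper tail against a user-supplied gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import VariantStat
from .smr import UndefinedRatioError, bh_fdr, ratio_estimate

logger = logging.getLogger(__name__)

MIN_CASES = 500
PHEMR_FDR = 0.1
ORA_FDR = 0.1

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class PhenotypeAssoc:
    """One phenotype's association statistics at one SNP (log-odds scale)."""

    phenotype_id: str
    description: str
    n_cases: int
    n_controls: int
    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.se <= 0:
            raise ValueError("se must be > 0")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


def wald_ratio(
    b_exposure: float, se_exposure: float, b_outcome: float, se_outcome: float
) -> tuple[float, float, float]:
    """Single-instrument Wald ratio: b_outcome / b_exposure, delta-method SE,
    and a two-sided normal p-value. The ratio and SE are computed by the same
    routine as the SMR test, so the two agree bitwise on identical inputs."""
    b_xy, se_xy = ratio_estimate(b_exposure, se_exposure, b_outcome, se_outcome)
    if b_xy == 0.0:
        return b_xy, se_xy, 1.0
    z = b_xy / se_xy
    return b_xy, se_xy, float(2.0 * stats.norm.sf(abs(z)))


SCREEN_COLUMNS = [
    "gene_id", "phenotype_id", "description", "snp", "ea", "oa",
    "n_cases", "b_xy", "se_xy", "or_xy", "ci_low", "ci_high",
    "p", "q", "significant",
]


def phemr_screen(
    instruments: dict[str, VariantStat],
    phenome: Sequence[PhenotypeAssoc],
    min_cases: int = MIN_CASES,
    fdr_threshold: float = PHEMR_FDR,
) -> pd.DataFrame:
    """Wald-ratio screen of gene instruments across a phenome.

    ``instruments`` maps gene_id to the instrument SNP's exposure statistics.
    Phenotype records are matched to instruments by SNP id with allele
    alignment (records whose alleles match neither orientation are dropped);
    phenotypes with fewer than ``min_cases`` cases are excluded before any
    testing. One BH correction is applied over all retained tests.
    """
    by_snp: dict[str, list[tuple[str, VariantStat]]] = {}
    for gene_id, stat in instruments.items():
        by_snp.setdefault(stat.snp_id, []).append((gene_id, stat))

    rows = []
    n_low_cases = 0
    for assoc in phenome:
        if assoc.n_cases < min_cases:
            n_low_cases += 1
            continue
        for gene_id, exp in by_snp.get(assoc.snp_id, []):
            if (assoc.effect_allele, assoc.other_allele) == (exp.effect_allele, exp.other_allele):
                b_out = assoc.beta
            elif (assoc.effect_allele, assoc.other_allele) == (exp.other_allele, exp.effect_allele):
                b_out = -assoc.beta
            else:
                logger.debug(
                    "phenotype %s: allele mismatch at %s, dropped",
                    assoc.phenotype_id, assoc.snp_id,
                )
                continue
            try:
                b_xy, se_xy, p = wald_ratio(exp.beta, exp.se, b_out, assoc.se)
            except UndefinedRatioError:
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "phenotype_id": assoc.phenotype_id,
                    "description": assoc.description,
                    "snp": assoc.snp_id,
                    "ea": exp.effect_allele,
                    "oa": exp.other_allele,
                    "n_cases": assoc.n_cases,
                    "b_xy": b_xy,
                    "se_xy": se_xy,
                    "or_xy": float(np.exp(b_xy)),
                    "ci_low": float(np.exp(b_xy - Z_95 * se_xy)),
                    "ci_high": float(np.exp(b_xy + Z_95 * se_xy)),
                    "p": p,
                }
            )
    if n_low_cases:
        logger.info("excluded %d phenotype record(s) with < %d cases", n_low_cases, min_cases)
    if not rows:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < fdr_threshold
    return df[SCREEN_COLUMNS]


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


@dataclass
class ORAResult:
    set_id: str
    name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    expected: float
    p: float
    q: float = float("nan")
    overlap_genes: list[str] = field(default_factory=list)


def ora_test(
    query: Sequence[str], gene_set: GeneSet, universe: Sequence[str]
) -> tuple[float, int, float]:
    """Hypergeometric upper-tail p of observing at least the seen overlap.

    Returns (p, overlap, expected overlap). The gene set is intersected with
    the universe before testing; the query must be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be a subset of the universe")
    members = gene_set.members & uni
    if not members:
        raise ValueError(f"gene set {gene_set.set_id} has no members in the universe")
    k = len(q & members)
    m_universe, m_set, m_query = len(uni), len(members), len(q)
    # P(X >= k) for X ~ Hypergeom(M=universe, K=set, n=query)
    p = float(stats.hypergeom.sf(k - 1, m_universe, m_set, m_query))
    expected = m_set * m_query / m_universe
    return min(p, 1.0), k, expected


def ora_collection(
    query: Sequence[str],
    gene_sets: Sequence[GeneSet],
    universe: Sequence[str],
    fdr_threshold: float = ORA_FDR,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """BH-corrected over-representation over a gene-set collection.

    With ``top`` set, returns the ``top`` smallest-q sets (ties broken by
    larger overlap, then set_id)."""
    results = []
    q_genes = set(query)
    for gs in gene_sets:
        try:
            p, overlap, expected = ora_test(query, gs, universe)
        except ValueError:
            logger.info("gene set %s skipped (no universe members)", gs.set_id)
            continue
        results.append(
            ORAResult(
                set_id=gs.set_id,
                name=gs.name,
                overlap=overlap,
                set_size=len(gs.members & set(universe)),
                query_size=len(q_genes),
                universe_size=len(set(universe)),
                expected=expected,
                p=p,
                overlap_genes=sorted(q_genes & gs.members),
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["set_id", "name", "overlap", "set_size", "query_size",
                     "universe_size", "expected", "p", "q", "significant", "overlap_genes"]
        )
    qvals = bh_fdr([r.p for r in results])
    for r, qv in zip(results, qvals):
        r.q = float(qv)
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "expected": [r.expected for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "overlap_genes": [",".join(r.overlap_genes) for r in results],
        }
    )
    df["significant"] = df["q"] < fdr_threshold
    df = df.sort_values(
        by=["q", "overlap", "set_id"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df


def read_gmt(path: str) -> list[GeneSet]:
    """Read gene sets in GMT format (set_id, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def read_phenome_table(path: str) -> list[PhenotypeAssoc]:
    """Read a phenome TSV: phenotype_id, description, n_cases, n_controls,
    snp, ea, oa, beta, se, p."""
    df = pd.read_csv(path, sep="\t", dtype={"phenotype_id": str})
    return [
        PhenotypeAssoc(
            phenotype_id=str(r.phenotype_id),
            description=str(r.description),
            n_cases=int(r.n_cases),
            n_controls=int(r.n_controls),
            snp_id=str(r.snp),
            effect_allele=str(r.ea).upper(),
            other_allele=str(r.oa).upper(),
            beta=float(r.beta),
            se=float(r.se),
        )
        for r in df.itertuples(index=False)
    ]
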