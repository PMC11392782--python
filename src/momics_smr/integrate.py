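"""Gene-level collation of layer evidence, evidence-tier labels, cross-omics
MR, and tissue-specific validation bookkeeping.

A gene-layer is *causal* when any of its probes passes the layer SMR screen
(FDR-adjusted q below threshold and HEIDI p above threshold) and
*colocalized* when such a probe additionally has PP.H4 above threshold.
Tier 1: causal at >= 2 omics layers with colocalization support at >= 2
layers; Tier 2: causal at >= 2 layers, colocalization at exactly one;
Tier 3: causal at >= 2 layers, no colocalization support. Genes causal at
fewer than two layers are left unclassified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import AssocDataset, LDMatrix, ProbeAnnotation, LAYERS
from . import coloc as _coloc
from . import smr as _smr

logger = logging.getLogger(__name__)

TIER1 = "tier1"
TIER2 = "tier2"
TIER3 = "tier3"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class LayerEvidence:
    """Per (gene, layer, probe) SMR + coloc evidence."""

    gene_id: str
    layer: str
    probe_id: str
    q_smr: float
    p_heidi: Optional[float]
    pp_h4: float
    direction: int

    def __post_init__(self) -> None:
        if not (0.0 < self.q_smr <= 1.0):
            raise ValueError(f"{self.gene_id}/{self.probe_id}: q_smr outside (0, 1]")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")


@dataclass
class TierThresholds:
    q_smr: float = 0.05
    p_heidi: float = 0.05
    pp_h4: float = 0.5


@dataclass
class TierAssignment:
    gene_id: str
    tier: str
    n_causal_layers: int
    n_coloc_layers: int
    supporting_probes: list[str] = field(default_factory=list)


def _heidi_passes(p_heidi: Optional[float], threshold: float) -> bool:
    # A probe with no evaluable HEIDI p is retained (exclusion is conditional
    # on a computed HEIDI p), mirroring the layer-level flagging rule.
    if p_heidi is None or (isinstance(p_heidi, float) and math.isnan(p_heidi)):
        return True
    return p_heidi > threshold


def gene_layer_status(
    evidence: Sequence[LayerEvidence],
    thresholds: Optional[TierThresholds] = None,
) -> tuple[bool, bool, Optional[str]]:
    """Aggregate one gene-layer's probes into (causal, colocalized, best probe).

    Causal iff any probe has q below threshold and passes HEIDI; colocalized
    iff any causal probe additionally has PP.H4 above threshold. The best
    probe is the causal probe with smallest q, preferring coloc-supported ones.
    """
    if not evidence:
        raise ValueError("gene_layer_status needs at least one probe record")
    thr = thresholds or TierThresholds()
    causal_probes = [
        e for e in evidence
        if e.q_smr < thr.q_smr and _heidi_passes(e.p_heidi, thr.p_heidi)
    ]
    if not causal_probes:
        return False, False, None
    coloc_probes = [e for e in causal_probes if e.pp_h4 > thr.pp_h4]
    pool = coloc_probes or causal_probes
    best = min(pool, key=lambda e: (e.q_smr, e.probe_id))
    return True, bool(coloc_probes), best.probe_id


def assign_tier(
    gene_id: str,
    layer_statuses: dict[str, tuple[bool, bool, Optional[str]]],
) -> TierAssignment:
    """Tier label from per-layer (causal, coloc, best probe) statuses.

    Only layers present in ``layer_statuses`` count — genes lacking a layer
    entirely are classified on their available layers."""
    n_causal = sum(1 for causal, _, _ in layer_statuses.values() if causal)
    n_coloc = sum(1 for causal, has_coloc, _ in layer_statuses.values() if causal and has_coloc)
    probes = [p for causal, _, p in layer_statuses.values() if causal and p]
    if n_causal < 2:
        tier = UNCLASSIFIED
    elif n_coloc >= 2:
        tier = TIER1
    elif n_coloc == 1:
        tier = TIER2
    else:
        tier = TIER3
    return TierAssignment(gene_id, tier, n_causal, n_coloc, probes)


def assign_tiers(
    evidence: pd.DataFrame,
    thresholds: Optional[TierThresholds] = None,
) -> pd.DataFrame:
    """Classify every gene in a long-format evidence table.

    ``evidence`` columns: gene_id, layer, probe_id, q_smr, p_heidi, pp_h4,
    direction (p_heidi may be NaN for probes where HEIDI was not evaluable).
    Returns one row per classified gene (unclassified genes are dropped),
    sorted by tier then gene_id.
    """
    thr = thresholds or TierThresholds()
    rows = []
    for gene_id, gene_df in evidence.groupby("gene_id", sort=True):
        statuses = {}
        for layer, layer_df in gene_df.groupby("layer"):
            recs = [
                LayerEvidence(
                    gene_id=str(gene_id),
                    layer=str(layer),
                    probe_id=str(r.probe_id),
                    q_smr=float(r.q_smr),
                    p_heidi=None if pd.isna(r.p_heidi) else float(r.p_heidi),
                    pp_h4=float(r.pp_h4),
                    direction=int(np.sign(getattr(r, "direction", 0))),
                )
                for r in layer_df.itertuples(index=False)
            ]
            statuses[str(layer)] = gene_layer_status(recs, thr)
        ta = assign_tier(str(gene_id), statuses)
        if ta.tier == UNCLASSIFIED:
            continue
        rows.append(
            {
                "gene_id": ta.gene_id,
                "tier": ta.tier,
                "n_causal_layers": ta.n_causal_layers,
                "n_coloc_layers": ta.n_coloc_layers,
                "supporting_probes": ",".join(ta.supporting_probes),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "tier", "n_causal_layers", "n_coloc_layers", "supporting_probes"])
    return out.sort_values(["tier", "gene_id"], kind="stable").reset_index(drop=True)


def tier_counts(tiers: pd.DataFrame) -> dict[str, int]:
    counts = tiers["tier"].value_counts().to_dict()
    return {t: int(counts.get(t, 0)) for t in (TIER1, TIER2, TIER3)}


# ---------------------------------------------------------------------------
# Cross-omics MR
# ---------------------------------------------------------------------------


def cross_omics_mr(
    probes_a: Sequence[ProbeAnnotation],
    layer_a_data: dict[str, AssocDataset],
    layer_b_data: AssocDataset,
    ld_store: Callable[[str], LDMatrix],
    thresholds: Optional[_smr.LayerThresholds] = None,
    outcome_id: str = "layer_b",
) -> pd.DataFrame:
    """SMR of one molecular layer on another (methylation -> expression,
    expression -> protein), reusing the disease-layer machinery."""
    return _smr.run_layer(
        probes_a, layer_a_data, layer_b_data, ld_store,
        thresholds=thresholds, outcome_id=outcome_id,
    )


def direction_consistency(
    b_xy_a_to_b: float, b_xy_b_to_disease: float, b_xy_a_to_disease: float
) -> bool:
    """Whether the mediated sign (a->b times b->disease) matches the direct
    a->disease sign. Reported, never enforced."""
    mediated = np.sign(b_xy_a_to_b) * np.sign(b_xy_b_to_disease)
    return bool(mediated == np.sign(b_xy_a_to_disease))


# ---------------------------------------------------------------------------
# Tissue validation
# ---------------------------------------------------------------------------

VALIDATION_COLUMNS = [
    "gene_id", "tissue", "b_xy", "p_smr", "p_heidi", "pp_h4",
    "validated", "coloc_label", "direction_concordant",
]


LABEL_NO_DATA = "no_data"


def tissue_validate(
    stats_table: pd.DataFrame,
    p_threshold: float = 0.05,
    heidi_threshold: float = 0.05,
    blood_directions: Optional[dict[str, int]] = None,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-(gene, tissue) validation flags from an SMR/coloc stats table.

    ``stats_table`` columns: gene_id, tissue, b_xy, p_smr, p_heidi, pp_h4.
    A row is validated when p_smr < 0.05 and p_heidi > 0.05 (marginal
    significance, per the complication-outcome relaxation); its coloc label
    is strong above 0.7 and moderate above 0.5. Directional concordance with
    blood is recorded when blood directions are supplied, but not required.
    """
    rows = []
    for r in stats_table.itertuples(index=False):
        validated = bool(r.p_smr < p_threshold and r.p_heidi > heidi_threshold)
        label = _coloc.classify_pp_h4(float(r.pp_h4)) if validated else _coloc.LABEL_NONE
        concordant = None
        if blood_directions and r.gene_id in blood_directions:
            concordant = bool(np.sign(r.b_xy) == blood_directions[r.gene_id])
        rows.append(
            {
                "gene_id": r.gene_id,
                "tissue": r.tissue,
                "b_xy": r.b_xy,
                "p_smr": r.p_smr,
                "p_heidi": r.p_heidi,
                "pp_h4": r.pp_h4,
                "validated": validated,
                "coloc_label": label,
                "direction_concordant": concordant,
            }
        )
    if genes is not None:
        present = set(stats_table["gene_id"])
        for gene_id in genes:
            if gene_id not in present:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "tissue": None,
                        "b_xy": np.nan,
                        "p_smr": np.nan,
                        "p_heidi": np.nan,
                        "pp_h4": np.nan,
                        "validated": False,
                        "coloc_label": LABEL_NO_DATA,
                        "direction_concordant": None,
                    }
                )
    return pd.DataFrame(rows, columns=VALIDATION_COLUMNS)


def validated_genes(validation: pd.DataFrame) -> list[str]:
    """Distinct genes with at least one validated tissue row."""
    return sorted(validation.loc[validation["validated"], "gene_id"].unique())
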