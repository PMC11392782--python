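"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order on simulated (or pre-ingested) data:
per-layer SMR + HEIDI against the disease outcome, colocalization per probe,
gene tier classification, and a reproducibility manifest with a SHA-256 hash
of every output. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coloc as _coloc
from . import integrate as _integrate
from . import simulate as _sim
from . import smr as _smr
from .sumstats_io import AssocDataset, ProbeAnnotation

logger = logging.getLogger(__name__)

MOLECULAR_LAYERS = ("methylation", "expression", "protein")


@dataclass
class SimulationConfig:
    n_genes: int = 5
    m_snps: int = 61
    rho: float = 0.8
    maf_low: float = 0.1
    maf_high: float = 0.5
    theta_me: float = -0.5
    theta_ep: float = 0.6
    theta_ed: float = 0.4
    var_explained_meth: float = 0.05
    n_meth: int = 10_000
    n_expr: int = 30_000
    n_prot: int = 30_000
    n_cases: int = 25_000
    n_controls: int = 25_000


@dataclass
class PipelineConfig:
    """Every numeric constant of the analysis in one auditable place."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    instrument_p: float = _smr.GENOME_WIDE_P
    q_significant: float = 0.05
    heidi_p: float = 0.05
    heidi_r2_min: float = _smr.HEIDI_R2_MIN
    heidi_r2_max: float = _smr.HEIDI_R2_MAX
    heidi_exposure_p: float = _smr.HEIDI_EXPOSURE_P
    heidi_max_snps: int = _smr.HEIDI_MAX_SNPS
    cis_flank: int = 1_000_000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp_strong: float = 0.7
    pp_moderate: float = 0.5
    tier_pp_h4: float = 0.5

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def thresholds(self) -> _smr.LayerThresholds:
        return _smr.LayerThresholds(
            instrument_p=self.instrument_p,
            q_significant=self.q_significant,
            heidi_p=self.heidi_p,
            heidi_r2_min=self.heidi_r2_min,
            heidi_r2_max=self.heidi_r2_max,
            heidi_exposure_p=self.heidi_exposure_p,
            heidi_max_snps=self.heidi_max_snps,
            cis_flank=self.cis_flank,
        )

    def priors(self) -> _coloc.ColocPriors:
        return _coloc.ColocPriors(self.coloc_p1, self.coloc_p2, self.coloc_p12)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _simulate_inputs(cfg: PipelineConfig):
    """Simulate one causal-chain region per gene.

    Returns (probes per layer, exposure data per layer, combined disease
    dataset, LD lookup by probe)."""
    sim = cfg.simulation
    probes: dict[str, list[ProbeAnnotation]] = {layer: [] for layer in MOLECULAR_LAYERS}
    exposure: dict[str, dict[str, AssocDataset]] = {layer: {} for layer in MOLECULAR_LAYERS}
    ld_by_probe: dict[str, object] = {}
    disease_records = []
    n_cc = None
    for g in range(sim.n_genes):
        region_seed = cfg.seed * 1009 + g
        region = _sim.simulate_region(
            _sim.RegionSpec(
                m_snps=sim.m_snps,
                maf_range=(sim.maf_low, sim.maf_high),
                ld_model="ar1",
                rho=sim.rho,
                seed=region_seed,
            )
        )
        chain = _sim.ChainSpec(
            theta_me=sim.theta_me,
            theta_ep=sim.theta_ep,
            theta_ed=sim.theta_ed,
            causal_index=sim.m_snps // 2,
            n_meth=sim.n_meth,
            n_expr=sim.n_expr,
            n_prot=sim.n_prot,
            disease_design=_sim.CaseControlDesign(sim.n_cases, sim.n_controls),
            var_explained_meth=sim.var_explained_meth,
        )
        layers = _sim.simulate_chain(region, chain, seed=region_seed + 7)
        gene_id = f"GENE{g + 1}"
        for layer in MOLECULAR_LAYERS:
            probe = _sim.default_probe(
                region, layer,
                probe_id=f"{gene_id}_{layer[:4]}", gene_id=gene_id,
            )
            probes[layer].append(probe)
            exposure[layer][probe.probe_id] = layers[layer]
            ld_by_probe[probe.probe_id] = region.ld
        disease_records.extend(layers["disease"].records)
        n_cc = (layers["disease"].n_cases, layers["disease"].n_controls)

    disease = AssocDataset(
        "disease", "case_control", disease_records,
        n_cases=n_cc[0], n_controls=n_cc[1],
    )
    return probes, exposure, disease, ld_by_probe


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate -> per-layer SMR+HEIDI -> coloc -> tiers; return manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logger.info("effective config: %s", json.dumps(asdict(cfg), sort_keys=True))

    stage = "simulate"
    try:
        probes, exposure, disease, ld_by_probe = _simulate_inputs(cfg)

        outputs: dict[str, str] = {}
        evidence_rows = []
        for layer in MOLECULAR_LAYERS:
            stage = f"smr:{layer}"
            layer_df = _smr.run_layer(
                probes[layer], exposure[layer], disease,
                ld_store=lambda pid: ld_by_probe[pid],
                thresholds=cfg.thresholds(), outcome_id="disease",
            )
            path = os.path.join(cfg.out_dir, f"smr_{layer}.tsv")
            _write_tsv(layer_df, path)
            outputs[f"smr_{layer}.tsv"] = path
            logger.info("%s: %d probes tested, %d significant", stage, len(layer_df),
                        int((layer_df["flag"] == _smr.FLAG_SIGNIFICANT).sum()) if len(layer_df) else 0)

            stage = f"coloc:{layer}"
            coloc_rows = []
            for probe in probes[layer]:
                if probe.probe_id not in set(layer_df["probe_id"]):
                    continue
                res = _coloc.run_coloc(
                    exposure[layer][probe.probe_id], disease, probe,
                    priors=cfg.priors(), outcome_id="disease",
                )
                coloc_rows.append(
                    {"probe_id": probe.probe_id, "outcome_id": "disease",
                     "n_snps": res.n_snps, **res.pp, "label": res.label}
                )
            coloc_df = pd.DataFrame(
                coloc_rows,
                columns=["probe_id", "outcome_id", "n_snps", *(_coloc.HYPOTHESES), "label"],
            )
            path = os.path.join(cfg.out_dir, f"coloc_{layer}.tsv")
            _write_tsv(coloc_df, path)
            outputs[f"coloc_{layer}.tsv"] = path

            pp_by_probe = dict(zip(coloc_df["probe_id"], coloc_df["pp_h4"]))
            for row in layer_df.itertuples(index=False):
                evidence_rows.append(
                    {
                        "gene_id": row.gene_id,
                        "layer": layer,
                        "probe_id": row.probe_id,
                        "q_smr": row.q_smr,
                        "p_heidi": row.p_heidi,
                        "pp_h4": pp_by_probe.get(row.probe_id, 0.0),
                        "direction": np.sign(row.b_xy),
                    }
                )

        stage = "tiers"
        evidence = pd.DataFrame(evidence_rows)
        tiers = _integrate.assign_tiers(
            evidence,
            _integrate.TierThresholds(cfg.q_significant, cfg.heidi_p, cfg.tier_pp_h4),
        )
        path = os.path.join(cfg.out_dir, "tiers.tsv")
        _write_tsv(tiers, path)
        outputs["tiers.tsv"] = path
        logger.info("tiers: %s", _integrate.tier_counts(tiers))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
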