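"""Bundled worked-example tables for the classification stages.

Three small TSVs ship with the package: per-gene multi-omics evidence with
published tier labels, tissue-level validation statistics, and a
phenome-screen result table with its FDR column. They exercise the tier
classifier, the tissue-validation rules, and the phenome-screen significance
filter end to end without any external downloads.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("momics_smr.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_tier_evidence() -> pd.DataFrame:
    """Long-format gene/layer evidence table with columns
    gene_id, layer, probe_id, q_smr, p_heidi, pp_h4, direction, tier_label.

    All rows passed the upstream HEIDI screen, so p_heidi is absent (NaN);
    direction is the sign of the log odds ratio."""
    df = _load("tier_evidence.tsv")
    df["p_heidi"] = np.nan
    df["direction"] = np.sign(np.log(df["or_xy"]))
    return df


def load_tissue_validation() -> pd.DataFrame:
    """Per-(gene, tissue) SMR and colocalization statistics with columns
    gene_id, tissue, b_xy, p_smr, p_heidi, pp_h4."""
    df = _load("tissue_validation.tsv")
    df["b_xy"] = np.log(df["or_xy"])
    return df


def load_phewas_screen() -> pd.DataFrame:
    """Phenome-screen associations with their FDR-adjusted values:
    gene_id, disease, snp, ea, oa, or_xy, ci_low, ci_high, fdr."""
    return _load("phewas_screen.tsv")
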