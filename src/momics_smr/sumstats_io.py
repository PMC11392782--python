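"""Reading, validation, harmonization and windowing of per-SNP summary statistics.

All coordinates are 1-based with both-ends-inclusive intervals. BED-like probe
annotation files (0-based half-open) are converted on load. Downstream modules
consume only the types defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column names for delimited summary-statistic tables.
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")

#: GCTA-COJO ".ma" dialect mapped onto the canonical names.
MA_SCHEMA = {
    "SNP": "snp", "A1": "ea", "A2": "oa", "freq": "eaf",
    "b": "beta", "se": "se", "p": "p", "N": "n",
}

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

QUANTITATIVE = "quantitative"
CASE_CONTROL = "case_control"

LAYERS = ("methylation", "expression", "protein")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A value could not be parsed; message names the offending line."""


class NoOverlapError(ValueError):
    """Harmonization found no shared SNPs between datasets."""


class LDCoverageError(ValueError):
    """The LD matrix does not cover a requested SNP set."""


@dataclass(frozen=True)
class VariantStat:
    """Summary association statistic for one SNP against one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float

    def validate(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]: {self.eaf}")
        if not self.effect_allele or not self.other_allele:
            raise ValueError(f"{self.snp_id}: empty allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: identical alleles {self.effect_allele}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p outside (0, 1]: {self.p}")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be > 0")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return (self.effect_allele.upper(), self.other_allele.upper()) in PALINDROMIC_PAIRS

    def flipped(self) -> "VariantStat":
        """Return the same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class AssocDataset:
    """Per-SNP summary statistics for one trait (molecular probe or disease)."""

    trait_id: str
    trait_type: str
    records: list[VariantStat] = field(default_factory=list)
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in (QUANTITATIVE, CASE_CONTROL):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == CASE_CONTROL:
            if not self.n_cases or not self.n_controls or self.n_cases < 1 or self.n_controls < 1:
                raise ValueError("case_control datasets need n_cases >= 1 and n_controls >= 1")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate snp_ids in dataset {self.trait_id}")

    def __len__(self) -> int:
        return len(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def by_snp(self) -> dict[str, VariantStat]:
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids: Sequence[str]) -> "AssocDataset":
        lookup = self.by_snp()
        return replace(self, records=[lookup[s] for s in snp_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [r.snp_id for r in self.records],
                "chr": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ea": [r.effect_allele for r in self.records],
                "oa": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "p": [r.p for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic annotation of a molecular probe (CpG, transcript or protein)."""

    probe_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    layer: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.probe_id}: start > end")
        if self.layer not in LAYERS:
            raise ValueError(f"{self.probe_id}: unknown layer {self.layer!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class LDMatrix:
    """SNP x SNP allelic correlation matrix aligned to known effect alleles.

    ``effect_alleles`` and ``eaf`` are optional panel metadata; when present
    they participate in allele alignment and the allele-frequency QC rule.
    """

    snp_ids: list[str]
    r: np.ndarray
    effect_alleles: Optional[list[str]] = None
    other_alleles: Optional[list[str]] = None
    eaf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD entries outside [-1, 1]")
        evals = np.linalg.eigvalsh(self.r)
        if evals.min() < -1e-6:
            raise ValueError(f"LD matrix far from PSD (min eigenvalue {evals.min():.3g})")
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, dtype=float)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snp_ids)}

    def subset(self, snp_ids: Sequence[str], signs: Optional[Sequence[float]] = None) -> "LDMatrix":
        """Subset (and optionally sign-flip) rows/columns for the given SNPs."""
        idx_map = self.index()
        missing = [s for s in snp_ids if s not in idx_map]
        if missing:
            raise LDCoverageError(f"LD matrix missing SNPs: {missing[:5]}")
        idx = [idx_map[s] for s in snp_ids]
        r = self.r[np.ix_(idx, idx)].copy()
        ea = [self.effect_alleles[i] for i in idx] if self.effect_alleles else None
        oa = [self.other_alleles[i] for i in idx] if self.other_alleles else None
        eaf = self.eaf[idx].copy() if self.eaf is not None else None
        if signs is not None:
            s = np.asarray(signs, dtype=float)
            r = r * np.outer(s, s)
            if ea is not None and oa is not None:
                ea, oa = (
                    [o if sg < 0 else e for e, o, sg in zip(ea, oa, s)],
                    [e if sg < 0 else o for e, o, sg in zip(ea, oa, s)],
                )
            if eaf is not None:
                eaf = np.where(s < 0, 1.0 - eaf, eaf)
        return LDMatrix(list(snp_ids), r, ea, oa, eaf)

    def r2(self, snp_a: str, snp_b: str) -> float:
        idx = self.index()
        return float(self.r[idx[snp_a], idx[snp_b]] ** 2)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_sumstats(
    path: str,
    schema: Optional[Mapping[str, str]] = None,
    trait_type: str = QUANTITATIVE,
    trait_id: Optional[str] = None,
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
    p_z_check: bool = True,
) -> AssocDataset:
    """Load a delimited summary-statistics table into an :class:`AssocDataset`.

    ``schema`` maps file column names onto the canonical names
    ``snp, chr, pos, ea, oa, eaf, beta, se, p, n``. Rows with missing beta/se
    or violating per-record invariants are dropped with a logged count.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[VariantStat] = []
    n_dropped = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        raw = dict(zip(df.columns, row))
        if _is_missing(raw["beta"]) or _is_missing(raw["se"]):
            n_dropped += 1
            continue
        try:
            numeric = {k: float(raw[k]) for k in ("eaf", "beta", "se", "p", "n")}
            pos = int(float(raw["pos"]))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {line_no}: non-numeric field ({exc})") from None
        rec = VariantStat(
            snp_id=str(raw["snp"]),
            chrom=str(raw["chr"]),
            pos=pos,
            effect_allele=str(raw["ea"]).upper(),
            other_allele=str(raw["oa"]).upper(),
            eaf=numeric["eaf"],
            beta=numeric["beta"],
            se=numeric["se"],
            p=numeric["p"],
            n=numeric["n"],
        )
        try:
            rec.validate()
        except ValueError as exc:
            logger.info("dropping row at line %d: %s", line_no, exc)
            n_dropped += 1
            continue
        if p_z_check:
            _warn_p_inconsistent(rec)
        records.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)

    return AssocDataset(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        records=records,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def _is_missing(value) -> bool:
    if value is None:
        return True
    s = str(value).strip()
    return s == "" or s.lower() in ("na", "nan", ".")


def _warn_p_inconsistent(rec: VariantStat, rel_tol: float = 0.1) -> None:
    # Published sumstats often carry rounded p-values: warn, never fail.
    p_expected = 2.0 * stats.norm.sf(abs(rec.z))
    if p_expected <= 0:
        return
    if abs(rec.p - p_expected) > rel_tol * p_expected and abs(np.log10(max(rec.p, 1e-300)) - np.log10(p_expected)) > 0.05:
        logger.warning(
            "%s: p=%.3g inconsistent with beta/se (expected %.3g)",
            rec.snp_id, rec.p, p_expected,
        )


def write_sumstats(dataset: AssocDataset, path: str) -> None:
    """Write a dataset in the canonical TSV dialect (full float precision)."""
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld_matrix(path: str) -> LDMatrix:
    """Read LD as a square TSV with SNP ids as header row and first column,
    or a long-format triplet file with columns (snp_i, snp_j, r)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) == 3 and header[2].lower() in ("r", "corr", "ld"):
        return _read_ld_triplets(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.columns]
    if [str(s) for s in df.index] != snp_ids:
        raise ParseError(f"{path}: LD row ids differ from column ids")
    return LDMatrix(snp_ids, df.to_numpy(dtype=float))


def _read_ld_triplets(path: str) -> LDMatrix:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["snp_i", "snp_j", "r"]
    snps = sorted(set(df["snp_i"]).union(df["snp_j"]))
    idx = {s: i for i, s in enumerate(snps)}
    r = np.eye(len(snps))
    for si, sj, val in df.itertuples(index=False):
        r[idx[si], idx[sj]] = val
        r[idx[sj], idx[si]] = val
    return LDMatrix(snps, r)


def write_ld_matrix(ld: LDMatrix, path: str) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_probe_annotations(path: str) -> list[ProbeAnnotation]:
    """Read BED-like probe annotations (chrom, start, end, probe_id, gene_id, layer).

    BED coordinates are 0-based half-open; converted to 1-based inclusive here.
    """
    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "probe_id", "gene_id", "layer"],
        dtype={"chrom": str}, comment="#",
    )
    return [
        ProbeAnnotation(
            probe_id=str(row.probe_id),
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            start=int(row.start) + 1,
            end=int(row.end),
            layer=str(row.layer),
        )
        for row in df.itertuples(index=False)
    ]


def write_probe_annotations(probes: Iterable[ProbeAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for pr in probes:
            fh.write(f"{pr.chrom}\t{pr.start - 1}\t{pr.end}\t{pr.probe_id}\t{pr.gene_id}\t{pr.layer}\n")


# ---------------------------------------------------------------------------
# Harmonization and windowing
# ---------------------------------------------------------------------------


def harmonize(
    exposure: AssocDataset,
    outcome: AssocDataset,
    ld: Optional[LDMatrix] = None,
    eaf_max_diff: float = 0.2,
    drop_palindromic: bool = True,
) -> tuple[AssocDataset, AssocDataset, Optional[LDMatrix]]:
    """Align outcome (and LD panel) effect alleles to the exposure.

    Returns the triple restricted to the intersection of SNPs, with outcome
    betas sign-flipped (and eaf complemented) where alleles are swapped,
    strand-ambiguous palindromic SNPs dropped, and any SNP whose effect-allele
    frequency differs by more than ``eaf_max_diff`` between any pair of
    {exposure, outcome, LD panel} excluded. LD rows/columns are subset and
    sign-adjusted to the exposure's effect alleles.
    """
    exp_lookup = exposure.by_snp()
    out_lookup = outcome.by_snp()
    shared = [s for s in exposure.snp_ids() if s in out_lookup]
    if ld is not None:
        ld_index = ld.index()
        shared = [s for s in shared if s in ld_index]
    if not shared:
        raise NoOverlapError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )

    kept: list[str] = []
    out_records: list[VariantStat] = []
    ld_signs: list[float] = []
    for snp in shared:
        e, o = exp_lookup[snp], out_lookup[snp]
        if drop_palindromic and (e.is_palindromic() or o.is_palindromic()):
            logger.debug("dropping palindromic SNP %s", snp)
            continue
        if o.effect_allele == e.effect_allele and o.other_allele == e.other_allele:
            aligned = o
        elif o.effect_allele == e.other_allele and o.other_allele == e.effect_allele:
            aligned = o.flipped()
        else:
            logger.debug("dropping allele-mismatched SNP %s", snp)
            continue

        freqs = [e.eaf, aligned.eaf]
        ld_sign = 1.0
        if ld is not None and ld.effect_alleles is not None:
            i = ld.index()[snp]
            if ld.effect_alleles[i] == e.other_allele:
                ld_sign = -1.0
            elif ld.effect_alleles[i] != e.effect_allele:
                logger.debug("dropping SNP %s: LD panel alleles mismatch", snp)
                continue
            if ld.eaf is not None:
                panel_eaf = ld.eaf[i] if ld_sign > 0 else 1.0 - ld.eaf[i]
                freqs.append(float(panel_eaf))
        if max(freqs) - min(freqs) > eaf_max_diff:
            logger.debug("dropping SNP %s: eaf spread %.3f", snp, max(freqs) - min(freqs))
            continue

        kept.append(snp)
        out_records.append(aligned)
        ld_signs.append(ld_sign)

    if not kept:
        raise NoOverlapError(
            f"harmonization left no SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )

    exp_out = exposure.subset(kept)
    out_out = replace(outcome, records=out_records)
    ld_out = ld.subset(kept, signs=ld_signs) if ld is not None else None
    return exp_out, out_out, ld_out


def cis_window(
    probe: ProbeAnnotation,
    flank: int,
    anchor: str = "gene_body",
    top_snp_pos: Optional[int] = None,
) -> tuple[int, int]:
    """Cis-region interval around a probe: gene body +/- flank, or
    top SNP position +/- flank. 1-based inclusive; lower bound clipped at 1."""
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    if anchor == "gene_body":
        if top_snp_pos is not None:
            raise ValueError("top_snp_pos only valid with anchor='top_snp'")
        lo, hi = probe.start - flank, probe.end + flank
    elif anchor == "top_snp":
        if top_snp_pos is None:
            raise ValueError("anchor='top_snp' requires top_snp_pos")
        lo, hi = top_snp_pos - flank, top_snp_pos + flank
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return max(lo, 1), hi
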