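"""Readers and writers: PGS-Catalog-style scoring files, VCF genotype panels,
phenotype tables, and the tab-separated association report.

Conventions
-----------
* Positions are 1-based throughout (VCF convention).  Scoring-file positions
  are assumed to be on the same genome build as the panel; no liftover.
* Genotype dosages are ALT-allele dosages in [0, 2].  The DS FORMAT field
  takes precedence over GT when both are present; ``./.`` is missing.
* Multiallelic VCF records are skipped with a warning, not split.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreVariant:
    """One line of a published scoring file.

    ``weight`` is the per-effect-allele log-odds weight; ``other_allele`` may
    be ``None`` (some catalog files omit it), which restricts harmonization
    to effect-allele-only matching.
    """

    variant_id: str
    chrom: str | None
    pos: int | None
    effect_allele: str
    other_allele: str | None
    weight: float

    def __post_init__(self):
        if self.pos is not None and self.pos < 1:
            raise ValidationError(f"{self.variant_id}: position must be >= 1")
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.variant_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in VALID_ALLELES:
                raise ValidationError(f"{self.variant_id}: bad other allele {self.other_allele!r}")
            if self.other_allele == self.effect_allele:
                raise ValidationError(f"{self.variant_id}: effect and other allele identical")
        if not np.isfinite(self.weight):
            raise ValidationError(f"{self.variant_id}: non-finite weight")


@dataclass
class ScoreSet:
    """A published polygenic score: ordered variants with effect weights."""

    pgs_id: str
    variants: list[ScoreVariant]

    def __post_init__(self):
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"{self.pgs_id}: duplicate variant ids")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)


@dataclass
class GenotypePanel:
    """Samples x variants ALT-dosage matrix plus variant metadata.

    ``variant_meta`` columns: id, chrom, pos, ref, alt.  ``dosage`` holds
    real dosages in [0, 2] (mean-imputable); ``missing_mask`` marks cells
    with no genotype information.
    """

    sample_ids: list[str]
    variant_meta: pd.DataFrame
    dosage: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.variant_meta) != m:
            raise ValidationError("panel dimensions inconsistent")
        if self.missing_mask.shape != (n, m):
            raise ValidationError("missing_mask shape mismatch")
        ok = self.dosage[~self.missing_mask]
        if ok.size and (np.nanmin(ok) < -1e-9 or np.nanmax(ok) > 2 + 1e-9):
            raise ValidationError("dosages outside [0, 2]")
        if (self.variant_meta["ref"] == self.variant_meta["alt"]).any():
            raise ValidationError("ref == alt for some variant")
        self.variant_meta = self.variant_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def position_index(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> column index."""
        return {
            (str(c), int(p)): j
            for j, (c, p) in enumerate(zip(self.variant_meta["chrom"], self.variant_meta["pos"]))
        }

    def id_index(self) -> dict[str, int]:
        return {str(v): j for j, v in enumerate(self.variant_meta["id"])}

    def subset_samples(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in keep],
            variant_meta=self.variant_meta.copy(),
            dosage=self.dosage[keep].copy(),
            missing_mask=self.missing_mask[keep].copy(),
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variant_meta=self.variant_meta.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep].copy(),
            missing_mask=self.missing_mask[:, keep].copy(),
        )

    def hard_calls(self) -> np.ndarray:
        """Round dosages to integer genotypes (ties-to-even); missing -> -1."""
        g = np.rint(self.dosage).astype(int)
        g[self.missing_mask] = -1
        return g


@dataclass
class PhenotypeTable:
    """Case-control status and model covariates, one row per sample."""

    REQUIRED = ("sample_id", "case_status", "sex", "age", "weight", "t2dm",
                "smoking", "sbp", "total_chol")

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        cs = self.df["case_status"]
        if not cs.isin([0, 1]).all():
            bad = sorted(cs[~cs.isin([0, 1])].unique().tolist())
            raise ValidationError(f"case_status values outside {{0,1}}: {bad}")
        if (self.df["age"] <= 0).any():
            raise ValidationError("non-positive age")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_ids in phenotype table")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Scoring files (PGS Catalog dialect)
# ---------------------------------------------------------------------------

_SCORE_COLS = {
    "rsID": "variant_id",
    "chr_name": "chrom",
    "chr_position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "weight",
}


def read_score_file(path) -> ScoreSet:
    """Parse a tab-separated PGS-Catalog-style scoring file.

    Lines beginning with ``#`` are header metadata; ``#pgs_id=...`` is
    recorded when present.  Mandatory columns: ``effect_allele`` and
    ``effect_weight``.  A non-numeric weight raises :class:`FormatError`
    naming the offending (1-based, comment-inclusive) line number.
    """
    pgs_id = ""
    header_lines = 0
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                stripped = line.lstrip("#").strip()
                if stripped.lower().startswith("pgs_id"):
                    pgs_id = stripped.split("=", 1)[-1].strip()
            else:
                body.append(line)
    if not body:
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t", dtype=str)
    for col in ("effect_allele", "effect_weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    variants = []
    for i, row in df.iterrows():
        line_no = header_lines + 2 + i  # +1 column header, +1 1-based
        try:
            weight = float(row["effect_weight"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}, line {line_no}: non-numeric effect_weight "
                f"{row['effect_weight']!r}"
            ) from None
        other = row.get("other_allele")
        if other is not None and (pd.isna(other) or other == ""):
            other = None
        chrom = row.get("chr_name")
        chrom = None if chrom is None or pd.isna(chrom) else str(chrom)
        pos = row.get("chr_position")
        pos = None if pos is None or pd.isna(pos) else int(pos)
        vid = row.get("rsID")
        if vid is None or pd.isna(vid):
            vid = f"{chrom}:{pos}" if chrom is not None else f"row{line_no}"
        variants.append(
            ScoreVariant(
                variant_id=str(vid), chrom=chrom, pos=pos,
                effect_allele=str(row["effect_allele"]),
                other_allele=None if other is None else str(other),
                weight=weight,
            )
        )
    if not pgs_id:
        pgs_id = str(path)
    return ScoreSet(pgs_id=pgs_id, variants=variants)


def write_score_file(scoreset: ScoreSet, path) -> None:
    """Emit a scoring file in the dialect :func:`read_score_file` accepts."""
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={scoreset.pgs_id}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for v in scoreset.variants:
            fh.write(
                "\t".join([
                    v.variant_id,
                    "" if v.chrom is None else str(v.chrom),
                    "" if v.pos is None else str(v.pos),
                    v.effect_allele,
                    "" if v.other_allele is None else v.other_allele,
                    repr(v.weight),
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# VCF genotype panels
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path) -> GenotypePanel:
    """Load a biallelic-SNP VCF into a :class:`GenotypePanel` via cyvcf2.

    Dosage comes from the DS FORMAT field when present, otherwise from the
    ALT-allele count of GT.  Missing genotypes (``./.`` or missing DS) set
    ``missing_mask``; the stored dosage at those cells is 0 and must be
    ignored or imputed downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")

    meta_rows = []
    dosage_cols = []
    missing_cols = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = v.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(col)
        else:
            gts = np.array(v.genotypes, dtype=object)
            a = np.array([g[0] for g in gts], dtype=int)
            b = np.array([g[1] for g in gts], dtype=int)
            miss = (a < 0) | (b < 0)
            col = np.where(miss, 0.0, a + b).astype(float)
        col = np.where(miss, 0.0, np.clip(col, 0.0, 2.0))
        dosage_cols.append(col)
        missing_cols.append(miss)
        meta_rows.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS),
                          v.REF, v.ALT[0]))
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multiallelic record(s)")
        logger.warning("%s: skipped %d multiallelic record(s)", path, n_multi)
    if not meta_rows:
        raise FormatError(f"{path}: no usable biallelic records")
    meta = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypePanel(
        sample_ids=samples,
        variant_meta=meta,
        dosage=np.column_stack(dosage_cols),
        missing_mask=np.column_stack(missing_cols),
    )


def write_genotypes_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as VCF 4.2 with GT (hard call) and DS (dosage) fields."""
    hard = panel.hard_calls()
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        for c in pd.unique(panel.variant_meta["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, row in panel.variant_meta.iterrows():
            cells = []
            for i in range(panel.n_samples):
                if panel.missing_mask[i, j]:
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(hard[i, j])]}:{panel.dosage[i, j]:.4f}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, panel_sample_ids=None) -> PhenotypeTable:
    """Read a delimited (TSV/CSV) phenotype/covariate table.

    Unknown columns are kept but flagged with a warning; samples absent from
    ``panel_sample_ids`` (when given) produce a warning list, not an error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    extra = [c for c in df.columns if c not in PhenotypeTable.REQUIRED]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    df["sample_id"] = df["sample_id"].astype(str)
    table = PhenotypeTable(df=df)
    if panel_sample_ids is not None:
        absent = sorted(set(table.sample_ids) - set(map(str, panel_sample_ids)))
        if absent:
            warnings.warn(f"{path}: {len(absent)} sample(s) absent from panel: {absent[:5]}")
    return table


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def write_report(results, path) -> None:
    """Write the association results as a TSV table.

    Columns mirror the standard PRS-replication report: score ID, full-model
    Nagelkerke R-squared, incremental (adjusted PRS) R-squared, PRS odds
    ratio with 95% CI, Wald p-value, and the Bonferroni significance flag.
    R-squareds print as percentages with one decimal; ORs with three
    decimals; p-values in scientific notation.
    """
    results = list(results)
    if not results:
        raise ValueError("write_report: empty results")
    with open(path, "w") as fh:
        fh.write("ID\tmodel\tR2\tadjusted_PRS_R2\tPRS_OR\tOR_95CI\tp_value\t"
                 "bonferroni_significant\n")
        for r in results:
            fh.write("\t".join([
                r.pgs_id,
                r.model,
                _fmt_pct(r.r2_full),
                _fmt_pct(r.adjusted_prs_r2),
                f"{r.odds_ratio:.3f}",
                f"[{r.ci_low:.3f}, {r.ci_high:.3f}]",
                _fmt_p(r.p_value),
                str(bool(r.bonferroni_significant)),
            ]) + "\n")
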