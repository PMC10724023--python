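"""Readers and writers for the external formats the pipeline touches.

Genotypes travel as derived-allele dosage matrices polarized against the
ancestral allele; everything else is plain TSV with a header row. The VCF
reader accepts any VCF 4.x with diploid GT fields and optional INFO keys
``AA`` (ancestral allele), ``SIFT``, ``RS``, ``GENE`` and ``CSQ``
(consequence term); the writer emits the same keys so that a write/read
round trip is the identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: dosage code for a missing genotype
MISSING = -1

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "ancestral",
    "gene_id",
    "consequence",
    "sift",
    "rs",
]

METADATA_COLUMNS = [
    "sample_id",
    "accession_id",
    "acquisition_year",
    "storage_years",
    "regenerations",
    "germination_pct",
    "mating_system",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantAnnotation:
    """One variant's site annotation: position, alleles, scores.

    ``sift_score`` is SIFT's predicted tolerance of the amino-acid change
    (<= 0.05 conventionally deleterious); ``rs_score`` is the GERP
    rejected-substitution score (positive means the site is more conserved
    than neutrally expected). Either may be None when unscored.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None
    gene_id: str | None = None
    consequence: str | None = None
    sift_score: float | None = None
    rs_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.sift_score is not None and not (0.0 <= self.sift_score <= 1.0):
            raise ValueError(f"sift_score must be in [0, 1], got {self.sift_score}")
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError(
                f"ancestral allele {self.ancestral_allele!r} matches neither "
                f"REF {self.ref_allele!r} nor ALT {self.alt_allele!r}"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    @property
    def derived_is_alt(self) -> bool:
        """True when the ALT allele is the derived one (REF ancestral)."""
        return self.ancestral_allele != self.alt_allele


@dataclass
class GenotypeMatrix:
    """Samples x loci derived-allele dosages; ``MISSING`` (-1) marks no call."""

    sample_ids: list[str]
    variant_keys: list[str]
    dosage: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage codes outside {{-1, 0, 1, 2}}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column(self, key: str) -> np.ndarray:
        return self.dosage[:, self.variant_keys.index(key)]

    def subset(self, keys: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_keys.index(k) for k in keys]
        return GenotypeMatrix(self.sample_ids, list(keys), self.dosage[:, idx])


@dataclass(frozen=True)
class AccessionMetadata:
    """Genebank passport data for one assayed sample."""

    sample_id: str
    accession_id: str
    acquisition_year: int
    storage_years: float
    regenerations: int
    germination_pct: float
    mating_system: str = "selfing"

    def __post_init__(self) -> None:
        if self.storage_years < 0:
            raise ValueError("storage_years must be >= 0")
        if not (0.0 <= self.germination_pct <= 100.0):
            raise ValueError("germination_pct must be in [0, 100]")
        if self.regenerations < 0:
            raise ValueError("regenerations must be >= 0")
        if self.mating_system not in ("selfing", "outcrossing"):
            raise ValueError(f"unknown mating_system {self.mating_system!r}")


@dataclass
class VcfReadStats:
    """Per-file tally of records dropped by the reader."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_unknown_ancestral_skipped: int = 0
    n_ref_fallback: int = 0


def _info_float(variant, key: str) -> float | None:
    val = variant.INFO.get(key)
    if val is None:
        return None
    try:
        f = float(val)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_vcf(
    path: str | Path, ancestral_policy: str = "aa-then-ref"
) -> tuple[GenotypeMatrix, list[VariantAnnotation], VcfReadStats]:
    """Read diploid biallelic SNPs and polarize dosages to derived alleles.

    Parameters
    ----------
    path:
        VCF 4.x file with GT fields.
    ancestral_policy:
        ``"aa-then-ref"`` uses INFO/AA when it names one of the two alleles
        and otherwise falls back to REF-as-ancestral (counted in the stats);
        ``"strict"`` skips records without a usable AA; ``"ref"`` ignores AA
        and always treats REF as ancestral.

    Returns
    -------
    (GenotypeMatrix, annotations, VcfReadStats)
        Dosages count derived alleles per sample; multiallelic and non-SNP
        records are skipped and counted.
    """
    if ancestral_policy not in ("aa-then-ref", "strict", "ref"):
        raise ValueError(f"unknown ancestral_policy {ancestral_policy!r}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    annotations: list[VariantAnnotation] = []
    stats = VcfReadStats()
    for variant in vcf:
        if len(variant.ALT) != 1:
            stats.n_multiallelic += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            stats.n_non_snp += 1
            continue
        aa = variant.INFO.get("AA")
        if isinstance(aa, bytes):
            aa = aa.decode()
        if aa is not None:
            aa = aa.upper()
        ancestral: str | None
        if ancestral_policy == "ref":
            ancestral = ref
        elif aa in (ref, alt):
            ancestral = aa
        elif ancestral_policy == "strict":
            stats.n_unknown_ancestral_skipped += 1
            continue
        else:  # aa-then-ref fallback
            ancestral = ref
            stats.n_ref_fallback += 1

        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        alt_dosage = np.asarray(variant.gt_types, dtype=np.int8)
        alt_dosage[alt_dosage == 3] = MISSING
        if ancestral == alt:
            called = alt_dosage != MISSING
            alt_dosage[called] = 2 - alt_dosage[called]

        gene = variant.INFO.get("GENE")
        csq = variant.INFO.get("CSQ")
        annotations.append(
            VariantAnnotation(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref_allele=ref,
                alt_allele=alt,
                ancestral_allele=ancestral,
                gene_id=str(gene) if gene is not None else None,
                consequence=str(csq) if csq is not None else None,
                sift_score=_info_float(variant, "SIFT"),
                rs_score=_info_float(variant, "RS"),
            )
        )
        rows.append(alt_dosage)
        stats.n_kept += 1
    vcf.close()
    dosage = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples, [a.key for a in annotations], dosage)
    logger.info(
        "read_vcf: kept %d records (%d multiallelic, %d non-SNP, "
        "%d skipped for unknown ancestral, %d REF-ancestral fallbacks)",
        stats.n_kept,
        stats.n_multiallelic,
        stats.n_non_snp,
        stats.n_unknown_ancestral_skipped,
        stats.n_ref_fallback,
    )
    return gm, annotations, stats


def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    annotations: list[VariantAnnotation],
) -> None:
    """Write derived-dosage genotypes back to a minimal VCF 4.2 text file.

    Dosages are converted to REF/ALT genotypes using each record's ancestral
    allele, so reading the file back reproduces the input matrix.
    """
    if len(annotations) != gm.n_variants:
        raise ValueError("annotation count does not match genotype matrix")
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        # scores declared as String: htslib would truncate Type=Float to float32
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT score">\n')
        fh.write('##INFO=<ID=RS,Number=1,Type=String,Description="GERP RS score">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene ID">\n')
        fh.write(
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, ann in enumerate(annotations):
            info = []
            if ann.ancestral_allele is not None:
                info.append(f"AA={ann.ancestral_allele}")
            if ann.sift_score is not None:
                info.append(f"SIFT={ann.sift_score:.9g}")
            if ann.rs_score is not None:
                info.append(f"RS={ann.rs_score:.9g}")
            if ann.gene_id is not None:
                info.append(f"GENE={ann.gene_id}")
            if ann.consequence is not None:
                info.append(f"CSQ={ann.consequence}")
            derived = gm.dosage[:, j]
            if ann.derived_is_alt:
                alt_dosage = derived
            else:
                alt_dosage = np.where(derived == MISSING, MISSING, 2 - derived)
            gts = "\t".join(gt_strings[int(d)] for d in alt_dosage)
            fh.write(
                f"{ann.chrom}\t{ann.pos}\t.\t{ann.ref_allele}\t{ann.alt_allele}"
                f"\t.\t.\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def _parse_score(raw, row: int, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s in ("", "NA", "nan", "."):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable {col} score {raw!r} at data row {row}") from exc


def read_annotation_tsv(path: str | Path) -> list[VariantAnnotation]:
    """Read a per-variant annotation table (one row per variant, header row).

    Missing scores (``NA`` or empty) are preserved as None, never coerced to
    zero. Duplicate variant keys are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing_cols)}")
    annotations: list[VariantAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ancestral = row.ancestral if row.ancestral not in ("", "NA", ".") else None
        ann = VariantAnnotation(
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            ancestral_allele=ancestral,
            gene_id=row.gene_id if row.gene_id not in ("", "NA", ".") else None,
            consequence=row.consequence
            if row.consequence not in ("", "NA", ".")
            else None,
            sift_score=_parse_score(row.sift, i, "sift"),
            rs_score=_parse_score(row.rs, i, "rs"),
        )
        if ann.key in seen:
            raise ValueError(f"duplicate variant key {ann.key} at data row {i}")
        seen.add(ann.key)
        annotations.append(ann)
    return annotations


def write_annotation_tsv(path: str | Path, annotations: list[VariantAnnotation]) -> None:
    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return format(x, ".12g")
        return str(x)

    df = pd.DataFrame(
        {
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "ref": [a.ref_allele for a in annotations],
            "alt": [a.alt_allele for a in annotations],
            "ancestral": [fmt(a.ancestral_allele) for a in annotations],
            "gene_id": [fmt(a.gene_id) for a in annotations],
            "consequence": [fmt(a.consequence) for a in annotations],
            "sift": [fmt(a.sift_score) for a in annotations],
            "rs": [fmt(a.rs_score) for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> list[AccessionMetadata]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing_cols = set(METADATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing_cols)}")
    return [
        AccessionMetadata(
            sample_id=str(r.sample_id),
            accession_id=str(r.accession_id),
            acquisition_year=int(r.acquisition_year),
            storage_years=float(r.storage_years),
            regenerations=int(r.regenerations),
            germination_pct=float(r.germination_pct),
            mating_system=str(r.mating_system),
        )
        for r in df.itertuples(index=False)
    ]


def write_metadata_tsv(path: str | Path, metadata: list[AccessionMetadata]) -> None:
    pd.DataFrame([m.__dict__ for m in metadata])[METADATA_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def metadata_frame(metadata: list[AccessionMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id."""
    return pd.DataFrame([m.__dict__ for m in metadata]).set_index("sample_id")


def read_tpm_tsv(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample TPM matrix; first column gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if (df.to_numpy() < 0).any():
        raise ValueError("TPM matrix contains negative values")
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in TPM matrix")
    return df


def write_tpm_tsv(path: str | Path, tpm: pd.DataFrame) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


def write_table_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    """Write an output table with reals at 12 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")
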