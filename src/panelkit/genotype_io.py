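"""Read, write, validate and subset diploid biallelic genotype data.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
alternate-allele dosages (0, 1, 2) with ``MISSING`` (-1) for uncalled
genotypes.  Two on-disk representations are supported: VCF 4.x (GT field
only) and PLINK text PED/MAP.  Sample metadata (subspecies label, label
confidence, source) travels in a separate TSV, never in VCF headers.

Conventions
-----------
* Coordinates are 1-based, as in VCF; PLINK MAP positions are treated
  identically.
* Dosage counts the ALT allele.  Minor-allele frequency is derived
  downstream, so ref/alt orientation never flips silently.
* Half-calls and ploidy != 2 are recorded as MISSING with a warning.
* Sex chromosomes and mitochondria are skipped: only autosomal diploid
  records are accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("panelkit")

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING: int = -1

_NON_AUTOSOMES = {"x", "y", "mt", "m", "chrx", "chry", "chrm", "chrmt"}

SubspeciesLabel = Literal["plains", "wood", "hybrid", "unknown"]


class GenotypeIOError(ValueError):
    """Raised for malformed or unsupported genotype input."""


@dataclass(frozen=True)
class LocusRecord:
    """Per-locus annotation for a biallelic SNP.

    ``qual`` is the variant caller's site quality (e.g. GATK QUAL);
    ``conversion_type`` is the genotyping-array QC category (e.g. ``OTV``);
    both are optional because they only exist for some data sources.
    ``one_probe_per_strand`` / ``gatk_qc_pass`` are optional platform/caller
    QC flags filterable like ``conversion_type``.
    """

    locus_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float | None = None
    conversion_type: str | None = None
    purpose_tag: Literal["parentage_candidate", "composition_candidate", "none"] = "none"
    one_probe_per_strand: bool | None = None
    gatk_qc_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise GenotypeIOError(f"{self.locus_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise GenotypeIOError(f"{self.locus_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subspecies_label: SubspeciesLabel = "unknown"
    confidence_level: int = 4
    source: str = ""

    def __post_init__(self) -> None:
        if self.confidence_level not in (1, 2, 3, 4):
            raise GenotypeIOError(
                f"{self.sample_id}: confidence_level must be 1-4, "
                f"got {self.confidence_level}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosage matrix.

    ``dosages[i, j]`` is the number of ALT alleles carried by sample ``i``
    at locus ``j``: 0, 1, 2, or :data:`MISSING`.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.locus_ids):
            raise GenotypeIOError(
                f"dosage matrix is {self.dosages.shape}, expected "
                f"({len(self.sample_ids)}, {len(self.locus_ids)})"
            )
        if len(set(self.sample_ids)) != n:
            raise GenotypeIOError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise GenotypeIOError("duplicate locus ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeIOError(
                f"dosages contain values outside {{0,1,2,{MISSING}}}: "
                f"{np.unique(self.dosages[bad])}"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def dosage_row(self, sample_id: str) -> np.ndarray:
        return self.dosages[self.sample_index(sample_id)]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.dosages != MISSING

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        locus_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the requested samples/loci, in the requested order."""
        return subset(self, sample_ids=sample_ids, locus_ids=locus_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosages, other.dosages)
        )


def subset(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    locus_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Subset a :class:`GenotypeMatrix` preserving the requested order.

    Unknown identifiers raise ``KeyError`` listing every offender.
    """
    out_samples = list(gm.sample_ids if sample_ids is None else sample_ids)
    out_loci = list(gm.locus_ids if locus_ids is None else locus_ids)

    sidx = {s: i for i, s in enumerate(gm.sample_ids)}
    lidx = {l: j for j, l in enumerate(gm.locus_ids)}
    missing_ids = [s for s in out_samples if s not in sidx]
    missing_ids += [l for l in out_loci if l not in lidx]
    if missing_ids:
        raise KeyError(f"unknown ids: {missing_ids}")

    rows = np.array([sidx[s] for s in out_samples], dtype=int)
    cols = np.array([lidx[l] for l in out_loci], dtype=int)
    dos = gm.dosages[np.ix_(rows, cols)] if rows.size and cols.size else np.empty(
        (rows.size, cols.size), dtype=np.int8
    )
    return GenotypeMatrix(out_samples, out_loci, dos)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _is_autosome(chrom: str) -> bool:
    return chrom.lower() not in _NON_AUTOSOMES


def _read_vcf(path: Path, on_multiallelic: str) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    loci: list[LocusRecord] = []
    rows: list[np.ndarray] = []
    half_call_warned = False

    for var in vcf:
        if len(var.ALT) != 1:
            msg = f"{var.CHROM}:{var.POS}: multiallelic record"
            if on_multiallelic == "error":
                raise GenotypeIOError(msg)
            warnings.warn(msg + " skipped", stacklevel=3)
            continue
        if not _is_autosome(var.CHROM):
            logger.debug("skipping non-autosomal record %s:%s", var.CHROM, var.POS)
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(
                f"{var.CHROM}:{var.POS}: non-SNP record skipped", stacklevel=3
            )
            continue
        dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            alleles = call[:-1]  # last element is the phase flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                if len(alleles) == 2 and any(a >= 0 for a in alleles):
                    half_call_warned = True
                continue
            dos[i] = alleles[0] + alleles[1]
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(
            LocusRecord(
                locus_id=locus_id,
                chromosome=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                qual=var.QUAL,
            )
        )
        rows.append(dos)

    if half_call_warned:
        warnings.warn("half-calls or ploidy != 2 treated as missing", stacklevel=3)
    dosages = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sample_ids, [l.locus_id for l in loci], dosages)
    return gm, loci


def _write_vcf(gm: GenotypeMatrix, loci: Sequence[LocusRecord], path: Path) -> None:
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(l.chromosome for l in loci))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelkit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, loc in enumerate(loci):
            qual = "." if loc.qual is None else f"{loc.qual:g}"
            gts = "\t".join(gt_of[int(d)] for d in gm.dosages[:, j])
            sep = "\t" if gm.n_samples else ""
            fh.write(
                f"{loc.chromosome}\t{loc.position}\t{loc.locus_id}\t"
                f"{loc.ref_allele}\t{loc.alt_allele}\t{qual}\t.\t.\tGT{sep}{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def _plink_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix in (".ped", ".map") else path
    return base.with_suffix(".ped"), base.with_suffix(".map")


def _read_plink(
    path: Path, loci: Sequence[LocusRecord] | None
) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    ped_path, map_path = _plink_paths(path)
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise GenotypeIOError(f"{map_path}:{lineno}: expected 4 fields")
            map_rows.append((parts[0], parts[1], int(parts[3])))

    m = len(map_rows)
    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeIOError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pairs = list(zip(parts[6::2], parts[7::2]))
            allele_rows.append(pairs)

    by_id = {l.locus_id: l for l in loci} if loci is not None else {}
    out_loci: list[LocusRecord] = []
    dosages = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    keep_cols: list[int] = []
    for j, (chrom, locus_id, pos) in enumerate(map_rows):
        if not _is_autosome(chrom):
            logger.debug("skipping non-autosomal MAP record %s", locus_id)
            continue
        observed = [a for row in allele_rows for a in row[j] if a != "0"]
        if loci is not None and locus_id in by_id:
            rec = by_id[locus_id]
            ref, alt = rec.ref_allele, rec.alt_allele
        else:
            # Orientation is not stored in PED/MAP: call the minor allele ALT
            # (ties broken lexicographically) unless LocusRecords are supplied.
            uniq = sorted(set(observed))
            if len(uniq) > 2:
                raise GenotypeIOError(f"{locus_id}: more than two alleles in PED")
            counts = {a: observed.count(a) for a in uniq}
            if len(uniq) == 2:
                alt = min(uniq, key=lambda a: (counts[a], a))
                ref = next(a for a in uniq if a != alt)
            elif len(uniq) == 1:
                ref, alt = uniq[0], "."
            else:
                ref, alt = ".", "N"
            rec = LocusRecord(locus_id, chrom, pos, ref, alt)
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0" or b == "0":
                continue
            if {a, b} - {rec.ref_allele, rec.alt_allele}:
                raise GenotypeIOError(
                    f"{locus_id}: allele not in {{{rec.ref_allele},{rec.alt_allele}}}"
                )
            dosages[i, j] = (a == rec.alt_allele) + (b == rec.alt_allele)
        out_loci.append(rec)
        keep_cols.append(j)

    gm = GenotypeMatrix(
        sample_ids, [l.locus_id for l in out_loci], dosages[:, keep_cols]
    )
    return gm, out_loci


def _write_plink(gm: GenotypeMatrix, loci: Sequence[LocusRecord], path: Path) -> None:
    ped_path, map_path = _plink_paths(path)
    with open(map_path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.locus_id}\t0\t{loc.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = ["FAM", sid, "0", "0", "0", "-9"]
            for j, loc in enumerate(loci):
                d = int(gm.dosages[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [loc.ref_allele, loc.ref_allele]
                elif d == 1:
                    fields += [loc.ref_allele, loc.alt_allele]
                else:
                    fields += [loc.alt_allele, loc.alt_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: Literal["vcf", "plink_text"] = "vcf",
    loci: Sequence[LocusRecord] | None = None,
    on_multiallelic: Literal["skip", "error"] = "skip",
) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    """Read genotypes from VCF or PLINK text.

    Parameters
    ----------
    path:
        VCF file, or PED/MAP basename (either extension accepted).
    loci:
        For ``plink_text`` only: known :class:`LocusRecord` annotations that
        fix the ref/alt orientation; without them the minor allele is taken
        as ALT.
    on_multiallelic:
        ``"skip"`` drops multiallelic VCF records with a warning,
        ``"error"`` raises.
    """
    path = Path(path)
    if format == "vcf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_vcf(path, on_multiallelic)
    if format == "plink_text":
        return _read_plink(path, loci)
    raise GenotypeIOError(f"unsupported format: {format!r}")


def write_genotypes(
    gm: GenotypeMatrix,
    loci: Sequence[LocusRecord],
    path: str | Path,
    format: Literal["vcf", "plink_text"] = "vcf",
) -> None:
    """Write a genotype matrix to VCF or PLINK text (PED + MAP)."""
    if [l.locus_id for l in loci] != gm.locus_ids:
        raise GenotypeIOError("loci do not match the genotype matrix columns")
    path = Path(path)
    if format == "vcf":
        _write_vcf(gm, loci, path)
    elif format == "plink_text":
        _write_plink(gm, loci, path)
    else:
        raise GenotypeIOError(f"unsupported format: {format!r}")


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (sample_id, subspecies_label,
    confidence_level, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "subspecies_label", "confidence_level"}
    if not required <= set(df.columns):
        raise GenotypeIOError(f"metadata must have columns {sorted(required)}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            subspecies_label=row.subspecies_label,
            confidence_level=int(row.confidence_level),
            source=getattr(row, "source", ""),
        )
        for row in df.itertuples(index=False)
    ]


def write_sample_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.subspecies_label, r.confidence_level, r.source)
            for r in records
        ],
        columns=["sample_id", "subspecies_label", "confidence_level", "source"],
    )
    df.to_csv(path, sep="\t", index=False)
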