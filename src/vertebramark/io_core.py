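"""Genotype matrix model, VCF/manifest/BED I/O and genotype probabilities.

The in-memory model is a dense loci x samples grid of diploid calls backed
by numpy arrays:

* ``alleles``  -- ``(L, S, 2)`` int8, allele indices (0 = ref, 1 = alt),
  ``-1`` for a missing allele.  A call with any missing allele is treated
  as missing by every whole-call operation.
* ``phased``   -- ``(L, S)`` bool, True where the VCF call used ``|``.
* ``gq``       -- ``(L, S)`` int16 genotype quality, ``-1`` when absent.
* ``pl``       -- ``(L, S, 3)`` int32 phred-scaled genotype likelihoods
  (hom-ref, het, hom-alt), ``-1`` when absent.

Coordinates are 1-based in ``loci.pos`` (as printed in VCF); interval
arithmetic against gene annotations converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: sentinel returned when a call carries neither GQ nor PL
NO_PROBABILITY = None


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class ConfigurationError(ValueError):
    """Raised for sample/population bookkeeping mismatches."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantLocus:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class GenotypeMatrix:
    """Dense diploid genotype grid over sorted biallelic SNV loci."""

    loci: pd.DataFrame  # columns chrom, pos, ref, alt, locus_id
    samples: list[str]
    alleles: np.ndarray  # (L, S, 2) int8
    phased: np.ndarray  # (L, S) bool
    gq: np.ndarray  # (L, S) int16
    pl: np.ndarray  # (L, S, 3) int32

    def __post_init__(self) -> None:
        L, S = len(self.loci), len(self.samples)
        if self.alleles.shape != (L, S, 2):
            raise ValueError("alleles grid does not match loci x samples")
        if self.phased.shape != (L, S) or self.gq.shape != (L, S):
            raise ValueError("phase/quality grids do not match loci x samples")
        if self.pl.shape != (L, S, 3):
            raise ValueError("PL grid does not match loci x samples")
        ids = self.loci["locus_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate locus id {dup}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise ConfigurationError(f"sample {exc.args[0]!r} not in matrix") from None

    def missing_mask(self) -> np.ndarray:
        """(L, S) bool, True where the call has any missing allele."""
        return (self.alleles == MISSING).any(axis=2)

    def dosage(self) -> np.ndarray:
        """(L, S) float alt-allele dosage 0/1/2, NaN where missing."""
        d = self.alleles.sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def subset_loci(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            loci=self.loci.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            alleles=self.alleles[index],
            phased=self.phased[index],
            gq=self.gq[index],
            pl=self.pl[index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            loci=self.loci.copy(),
            samples=list(sample_ids),
            alleles=self.alleles[:, idx],
            phased=self.phased[:, idx],
            gq=self.gq[:, idx],
            pl=self.pl[:, idx],
        )


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "population", "thoracic", "lumbar"]


@dataclass
class SampleManifest:
    """Sample-to-population map with vertebral phenotype counts.

    ``formula`` is derived as ``T{thoracic}L{lumbar}``; ``total`` is the
    thoracolumbar vertebra count (thoracic + lumbar).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"manifest missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate sample {dup!r} in manifest")
        t = self.table
        t["thoracic"] = t["thoracic"].astype(int)
        t["lumbar"] = t["lumbar"].astype(int)
        t["formula"] = "T" + t["thoracic"].astype(str) + "L" + t["lumbar"].astype(str)
        t["total"] = t["thoracic"] + t["lumbar"]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_of(self, population: str) -> list[str]:
        if population not in set(self.table["population"]):
            raise ConfigurationError(f"unknown population {population!r}")
        sel = self.table["population"] == population
        return list(self.table.loc[sel, "sample_id"])

    def samples_of_group(self, populations: Sequence[str]) -> list[str]:
        out: list[str] = []
        for pop in populations:
            out.extend(self.samples_of(pop))
        return out

    def phenotype_groups(self, contrast: str) -> dict[str, list[str]]:
        """Split samples into groups by phenotype value.

        ``contrast`` is ``"total"`` (thoracolumbar vertebra count, e.g. the
        19-vs-20 comparison) or ``"thoracic"`` (e.g. 14 vs 15).
        """
        if contrast not in ("total", "thoracic"):
            raise ConfigurationError(f"unknown contrast {contrast!r}")
        groups: dict[str, list[str]] = {}
        for value, sub in self.table.groupby(contrast):
            groups[str(value)] = list(sub["sample_id"])
        return groups


def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    if table.empty:
        log.warning("manifest %s is empty", path)
    return SampleManifest(table=table)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read BED4 gene intervals (0-based half-open, as BED specifies)."""
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise VcfParseError(f"{path}:{lineno}: BED line needs 4 columns")
            try:
                genes.append(GeneInterval(parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise VcfParseError(f"{path}:{lineno}: {exc}") from None
    if not genes:
        log.warning("no gene intervals read from %s", path)
    return genes


def read_gene_gff3(path: str | Path, feature: str = "gene") -> list[GeneInterval]:
    """Read gene intervals from GFF3 (1-based closed -> 0-based half-open)."""
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise VcfParseError(f"{path}:{lineno}: GFF3 line needs 9 columns")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id") or f"{parts[0]}:{parts[3]}"
            genes.append(GeneInterval(parts[0], int(parts[3]) - 1, int(parts[4]), gene_id))
    return genes


def write_gene_bed(genes: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as UTF-8 TSV with a header line."""
    records.to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    min_quality: int = 0,
    biallelic_only: bool = True,
    samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of biallelic SNVs.

    Multiallelic records and indels are dropped (counted and logged) when
    ``biallelic_only`` is set.  Calls with GQ below ``min_quality`` are
    masked as missing rather than removing the whole locus.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    if samples is not None:
        got = set(vcf.samples)
        absent = [s for s in samples if s not in got]
        if absent:
            raise ConfigurationError(
                f"samples {absent} from manifest not present in {path}"
            )

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    allele_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    pl_rows: list[np.ndarray] = []
    n_dropped = 0

    n_samples = len(vcf.samples)
    for rec in vcf:
        if biallelic_only and (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or rec.ALT[0] is None
            or len(rec.ALT[0]) != 1
            or rec.ALT[0] not in "ACGT"
            or rec.REF not in "ACGT"
        ):
            n_dropped += 1
            continue
        gts = np.asarray(rec.genotypes, dtype=np.int64)  # (S, 3): a1, a2, phased
        if gts.shape != (n_samples, 3):
            raise VcfParseError(
                f"{path}: malformed genotypes at {rec.CHROM}:{rec.POS}"
            )
        alleles = gts[:, :2].astype(np.int8)
        alleles[alleles < 0] = MISSING
        phased = gts[:, 2].astype(bool)

        gq = np.full(n_samples, MISSING, dtype=np.int16)
        raw_gq = rec.gt_quals
        if raw_gq is not None:
            valid = raw_gq >= 0
            gq[valid] = np.round(raw_gq[valid]).astype(np.int16)

        pl = np.full((n_samples, 3), MISSING, dtype=np.int32)
        try:
            raw_pl = rec.format("PL")
        except KeyError:  # PL absent from the header entirely
            raw_pl = None
        if raw_pl is not None and raw_pl.shape[1] >= 3:
            arr = raw_pl[:, :3].astype(np.int64)
            ok = (arr >= 0).all(axis=1)
            pl[ok] = arr[ok].astype(np.int32)

        if min_quality > 0:
            low = (gq != MISSING) & (gq < min_quality)
            alleles[low] = MISSING

        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        allele_rows.append(alleles)
        phased_rows.append(phased)
        gq_rows.append(gq)
        pl_rows.append(pl)

    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic-SNV records", n_dropped)

    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    loci["locus_id"] = loci["chrom"] + ":" + loci["pos"].astype(str)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)

    L = len(loci)
    stack = lambda rows, shape, dtype: (
        np.stack(rows)[order] if rows else np.empty(shape, dtype=dtype)
    )
    return GenotypeMatrix(
        loci=loci,
        samples=list(vcf.samples),
        alleles=stack(allele_rows, (L, n_samples, 2), np.int8),
        phased=stack(phased_rows, (L, n_samples), bool),
        gq=stack(gq_rows, (L, n_samples), np.int16),
        pl=stack(pl_rows, (L, n_samples, 3), np.int32),
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a matrix as plain-text VCF v4.2 with GT:GQ:PL."""
    if contig_lengths is None:
        contig_lengths = {
            str(c): int(sub["pos"].max()) + 10_000
            for c, sub in matrix.loci.groupby("chrom", sort=True)
        }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n')
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_loci):
            row = matrix.loci.iloc[i]
            fields = [
                str(row["chrom"]), str(row["pos"]), ".", row["ref"], row["alt"],
                ".", "PASS", ".", "GT:GQ:PL",
            ]
            for j in range(matrix.n_samples):
                a1, a2 = matrix.alleles[i, j]
                sep = "|" if matrix.phased[i, j] else "/"
                gt = (
                    f"{'.' if a1 == MISSING else a1}{sep}"
                    f"{'.' if a2 == MISSING else a2}"
                )
                gq = matrix.gq[i, j]
                gq_s = "." if gq == MISSING else str(int(gq))
                pl = matrix.pl[i, j]
                pl_s = "." if (pl == MISSING).any() else ",".join(str(int(x)) for x in pl)
                fields.append(f"{gt}:{gq_s}:{pl_s}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

def genotype_probability(
    alleles: tuple[int, int],
    gq: int | None = None,
    pl: tuple[int, int, int] | None = None,
) -> float | None:
    """Probability of the called genotype.

    If PL is present, return the flat-prior posterior of the called
    genotype, ``10^(-PL_g/10) / sum_k 10^(-PL_k/10)``.  Otherwise fall back
    to ``1 - 10^(-GQ/10)``.  Returns :data:`NO_PROBABILITY` (None) when
    neither field is available -- never a silent default.
    """
    a1, a2 = alleles
    if a1 == MISSING or a2 == MISSING:
        raise ValueError("cannot compute probability of a missing call")
    if pl is not None and all(p >= 0 for p in pl):
        lik = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
        g = a1 + a2  # 0 -> hom ref, 1 -> het, 2 -> hom alt
        return float(np.clip(lik[g] / lik.sum(), 0.0, 1.0))
    if gq is not None and gq >= 0:
        return float(np.clip(1.0 - 10.0 ** (-gq / 10.0), 0.0, 1.0))
    return NO_PROBABILITY


def probability_grid(matrix: GenotypeMatrix) -> np.ndarray:
    """(L, S) genotype probabilities; NaN where missing or unavailable.

    Vectorised counterpart of :func:`genotype_probability` with the same
    PL-first, GQ-fallback convention.
    """
    L, S = matrix.n_loci, matrix.n_samples
    out = np.full((L, S), np.nan)

    has_pl = (matrix.pl != MISSING).all(axis=2)
    if has_pl.any():
        lik = np.power(10.0, -matrix.pl.astype(float) / 10.0)
        total = lik.sum(axis=2)
        g = matrix.alleles.sum(axis=2)  # genotype index where non-missing
        g_safe = np.clip(g, 0, 2)
        called = np.take_along_axis(lik, g_safe[:, :, None], axis=2)[:, :, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            post = called / total
        out[has_pl] = post[has_pl]

    has_gq = ~has_pl & (matrix.gq != MISSING)
    out[has_gq] = 1.0 - np.power(10.0, -matrix.gq[has_gq].astype(float) / 10.0)

    out[matrix.missing_mask()] = np.nan
    return np.clip(out, 0.0, 1.0)
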