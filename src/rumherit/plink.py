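"""PLINK text-dialect (PED/MAP, ``--recode12``) genotype I/O and quality control.

Genotypes are stored as counts of the "1"-coded reference allele, so a PED
genotype field pair ``1 1`` is 2, ``1 2`` is 1, ``2 2`` is 0 and any pair
containing ``0`` is missing.  QC applies the standard chip filters in the
order individual call rate -> SNP missingness -> minor allele frequency,
recomputing each statistic on the individuals retained so far.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, FormatError

MISSING = -1  # sentinel in the int8 call matrix


@dataclass
class SNPRecord:
    """One MAP line: identifier plus genomic coordinates."""

    snp_id: str
    chromosome: str
    genetic_distance: float
    position: int


@dataclass
class GenotypeMatrix:
    """Animals x SNPs reference-allele counts with PED/MAP metadata.

    Attributes
    ----------
    family_ids, animal_ids : list of str
        PED columns 1 and 2.  Uniqueness is enforced on the pair.
    ped_info : list of tuple of str
        PED columns 3-6 (paternal id, maternal id, sex, phenotype), kept
        verbatim so write/read round-trips are exact.
    snps : list of SNPRecord
    calls : ndarray of int8, shape (n_animals, n_snps)
        Values in {0, 1, 2, MISSING}.
    """

    family_ids: list[str]
    animal_ids: list[str]
    ped_info: list[tuple[str, str, str, str]]
    snps: list[SNPRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if not (len(self.family_ids) == len(self.animal_ids) == len(self.ped_info) == n):
            raise FormatError("animal metadata length does not match call matrix rows")
        if len(self.snps) != m:
            raise FormatError("SNP record count does not match call matrix columns")
        keys = list(zip(self.family_ids, self.animal_ids))
        if len(set(keys)) != n:
            raise FormatError("duplicate (family id, individual id) pairs")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype calls outside {0, 1, 2, missing}")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING


@dataclass
class QCReport:
    """Per-criterion removal counts from :func:`apply_qc`."""

    individuals_removed: int
    snps_removed_missing: int
    snps_removed_maf: int
    snps_passing: int
    thresholds: tuple[float, float, float]  # (mind, geno, maf)

    def to_tsv(self, path: str | Path) -> None:
        mind, geno, maf = self.thresholds
        lines = [
            "criterion\tthreshold\tremoved",
            f"individual_call_rate\t{mind}\t{self.individuals_removed}",
            f"snp_missingness\t{geno}\t{self.snps_removed_missing}",
            f"snp_maf\t{maf}\t{self.snps_removed_maf}",
            f"snps_passing\t-\t{self.snps_passing}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _open_lines(source) -> list[str]:
    if isinstance(source, (str, Path)):
        return Path(source).read_text().splitlines()
    if isinstance(source, io.TextIOBase):
        return source.read().splitlines()
    raise FormatError(f"unsupported source type {type(source)!r}")


def read_plink_text(ped_source, map_source) -> GenotypeMatrix:
    """Parse a PED/MAP pair in ``--recode12`` coding into a GenotypeMatrix.

    Parameters
    ----------
    ped_source, map_source : path or text stream

    Raises
    ------
    FormatError
        Ragged rows, allele codes outside {0,1,2} or a PED/MAP SNP-count
        mismatch, with the offending 1-based line number in the message.
    """
    snps: list[SNPRecord] = []
    for lineno, line in enumerate(_open_lines(map_source), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"MAP line {lineno}: expected 4 fields, got {len(parts)}")
        chrom, snp_id, dist, pos = parts
        try:
            snps.append(SNPRecord(snp_id, chrom, float(dist), int(pos)))
        except ValueError as exc:
            raise FormatError(f"MAP line {lineno}: {exc}") from exc

    m = len(snps)
    fids: list[str] = []
    iids: list[str] = []
    info: list[tuple[str, str, str, str]] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(_open_lines(ped_source), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"PED line {lineno}: expected {6 + 2 * m} fields for {m} SNPs, "
                f"got {len(parts)}"
            )
        fids.append(parts[0])
        iids.append(parts[1])
        info.append(tuple(parts[2:6]))
        alleles = parts[6:]
        row = np.empty(m, dtype=np.int8)
        for i in range(m):
            a, b = alleles[2 * i], alleles[2 * i + 1]
            if a not in ("0", "1", "2") or b not in ("0", "1", "2"):
                raise FormatError(
                    f"PED line {lineno}: allele code outside 0/1/2 at SNP {i + 1}"
                )
            if a == "0" or b == "0":
                row[i] = MISSING
            else:
                row[i] = (a == "1") + (b == "1")
        rows.append(row)

    calls = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    return GenotypeMatrix(fids, iids, info, snps, calls)


def write_plink_text(g: GenotypeMatrix, ped_sink, map_sink) -> None:
    """Emit the recode12 dialect exactly as :func:`read_plink_text` consumes it.

    Missing calls become ``0 0``; call 2 -> ``1 1``, 1 -> ``1 2``, 0 -> ``2 2``.
    """
    pair = {2: "1 1", 1: "1 2", 0: "2 2", MISSING: "0 0"}
    ped_lines = []
    for j in range(g.n_animals):
        head = [g.family_ids[j], g.animal_ids[j], *g.ped_info[j]]
        geno = [pair[int(c)] for c in g.calls[j]]
        ped_lines.append(" ".join(head + geno))
    map_lines = [
        f"{s.chromosome} {s.snp_id} {s.genetic_distance:g} {s.position}" for s in g.snps
    ]

    def _write(sink, lines):
        text = "\n".join(lines) + ("\n" if lines else "")
        if isinstance(sink, (str, Path)):
            try:
                Path(sink).write_text(text)
            except OSError as exc:
                raise OSError(f"writing {sink}: {exc}") from exc
        else:
            sink.write(text)

    _write(ped_sink, ped_lines)
    _write(map_sink, map_lines)


def _subset(g: GenotypeMatrix, keep_animals: np.ndarray, keep_snps: np.ndarray) -> GenotypeMatrix:
    idx_a = np.flatnonzero(keep_animals)
    idx_s = np.flatnonzero(keep_snps)
    return GenotypeMatrix(
        [g.family_ids[i] for i in idx_a],
        [g.animal_ids[i] for i in idx_a],
        [g.ped_info[i] for i in idx_a],
        [g.snps[i] for i in idx_s],
        g.calls[np.ix_(idx_a, idx_s)],
    )


def minor_allele_frequencies(calls: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency, missing calls excluded.

    SNPs with no non-missing calls get MAF 0 (they are removed by the
    missingness stage first under any sensible thresholds).
    """
    miss = calls == MISSING
    nonmiss = (~miss).sum(axis=0)
    ref = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, ref / (2.0 * np.maximum(nonmiss, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    g: GenotypeMatrix,
    mind: float = 0.05,
    geno: float = 0.05,
    maf: float = 0.05,
    reference: GenotypeMatrix | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply chip QC: individual call rate, SNP missingness, then MAF.

    Stage 1 removes individuals whose missing-call fraction exceeds ``mind``;
    stage 2 removes SNPs whose missing fraction among the remaining
    individuals exceeds ``geno``; stage 3 removes SNPs whose minor allele
    frequency (remaining individuals, missing excluded) is strictly below
    ``maf`` — frequency exactly equal to the threshold is kept.

    Parameters
    ----------
    reference : GenotypeMatrix, optional
        A larger reference panel sharing this matrix's SNP order.  When
        given, stage 2/3 statistics are computed on the pooled panel +
        cohort, mirroring a QC run against a breed-wide reference set, but
        only the cohort's animals are returned.

    Returns
    -------
    (GenotypeMatrix, QCReport)
    """
    for name, t in (("mind", mind), ("geno", geno), ("maf", maf)):
        if not (0.0 <= t < 1.0):
            raise DegenerateDataError(f"threshold {name}={t} outside [0, 1)")
    if reference is not None and reference.snp_ids != g.snp_ids:
        raise FormatError("reference panel SNPs do not match cohort SNPs")

    calls = g.calls
    n, m = calls.shape

    # stage 1: individual call rate
    ind_missing = (calls == MISSING).mean(axis=1) if m else np.zeros(n)
    keep_ind = ind_missing <= mind
    if not keep_ind.any():
        raise DegenerateDataError("QC removed every individual (mind filter)")
    removed_ind = int((~keep_ind).sum())
    kept = calls[keep_ind]

    pool = kept if reference is None else np.vstack([reference.calls, kept])

    # stage 2: SNP missingness on retained individuals
    snp_missing = (pool == MISSING).mean(axis=0) if len(pool) else np.zeros(m)
    keep_geno = snp_missing <= geno
    removed_geno = int((~keep_geno).sum())

    # stage 3: MAF on retained individuals, surviving SNPs only
    mafs = minor_allele_frequencies(pool[:, keep_geno])
    keep_maf_local = mafs >= maf
    removed_maf = int((~keep_maf_local).sum())

    keep_snp = keep_geno.copy()
    keep_snp[np.flatnonzero(keep_geno)[~keep_maf_local]] = False

    out = _subset(g, keep_ind, keep_snp)
    report = QCReport(
        individuals_removed=removed_ind,
        snps_removed_missing=removed_geno,
        snps_removed_maf=removed_maf,
        snps_passing=out.n_snps,
        thresholds=(mind, geno, maf),
    )
    return out, report
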