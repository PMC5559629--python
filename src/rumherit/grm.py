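"""SNP-based genetic relationship matrix (GRM).

The relationship estimate between animals j and k is

    A_jk = (1/n) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

where x are reference-allele counts, p_i the reference-allele frequency at
SNP i and n the number of SNPs informative for the pair.  With missing
calls, n is the per-pair count of SNPs non-missing in both animals
(pairwise-complete), which reduces to the global SNP count on complete
data.  Equivalently, on complete data A = W W^T / n with W the
column-standardized genotype matrix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InputError
from .plink import MISSING, GenotypeMatrix


@dataclass
class AlleleFrequencies:
    """Per-SNP reference-allele frequencies with a monomorphic flag.

    Monomorphic SNPs (p in {0, 1}) are flagged and excluded from the GRM:
    their standardization denominator 2p(1-p) vanishes.
    """

    snp_ids: list[str]
    freqs: np.ndarray
    monomorphic: np.ndarray  # bool mask, aligned to snp_ids

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)


@dataclass
class RelatednessMatrix:
    """Symmetric animal x animal relationship estimates with per-pair SNP counts."""

    family_ids: list[str]
    animal_ids: list[str]
    values: np.ndarray = field(repr=False)
    pair_counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts)
        n = len(self.animal_ids)
        if self.values.shape != (n, n) or self.pair_counts.shape != (n, n):
            raise InputError("relatedness matrix dimensions do not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InputError("relatedness matrix is not symmetric within 1e-12")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def align(self, animal_ids: list[str]) -> "RelatednessMatrix":
        """Return the submatrix for ``animal_ids`` in the given order."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            idx = [pos[a] for a in animal_ids]
        except KeyError as exc:
            raise InputError(f"animal {exc.args[0]!r} not in relatedness matrix") from exc
        return RelatednessMatrix(
            [self.family_ids[i] for i in idx],
            [self.animal_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.pair_counts[np.ix_(idx, idx)],
        )


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Reference-allele proportion per SNP over non-missing animals."""
    miss = g.calls == MISSING
    nonmiss = (~miss).sum(axis=0)
    if (nonmiss == 0).any():
        bad = [g.snps[i].snp_id for i in np.flatnonzero(nonmiss == 0)]
        raise InputError(f"SNPs with zero non-missing calls: {bad[:5]}")
    p = np.where(miss, 0, g.calls).sum(axis=0) / (2.0 * nonmiss)
    mono = (p <= 0.0) | (p >= 1.0)
    return AlleleFrequencies(g.snp_ids, p, mono)


def compute_grm(
    g: GenotypeMatrix,
    p: AlleleFrequencies | None = None,
    diagonal_mode: str = "plain",
) -> RelatednessMatrix:
    """Compute the GRM from allele counts and reference-allele frequencies.

    Parameters
    ----------
    p : AlleleFrequencies, optional
        Defaults to frequencies computed from ``g`` itself; pass frequencies
        from a reference panel to reproduce a pooled-panel analysis.
    diagonal_mode : {"plain", "gcta"}
        "plain" applies the off-diagonal formula with j = k.  "gcta" uses
        the alternative diagonal
        ``1 + (1/n) sum_i (x^2 - (1+2p)x + 2p^2) / (2p(1-p))``.

    Raises
    ------
    InputError
        If frequency coverage is incomplete or any pair of animals shares
        zero non-missing SNPs.
    """
    if diagonal_mode not in ("plain", "gcta"):
        raise InputError(f"unknown diagonal_mode {diagonal_mode!r}")
    if p is None:
        p = allele_frequencies(g)
    if p.snp_ids != g.snp_ids:
        raise InputError("allele frequencies do not cover the genotype matrix's SNPs")

    use = ~p.monomorphic
    calls = g.calls[:, use].astype(float)
    freqs = p.freqs[use]
    miss = calls == MISSING

    denom = 2.0 * freqs * (1.0 - freqs)
    z = (calls - 2.0 * freqs) / np.sqrt(denom)
    z[miss] = 0.0
    obs = (~miss).astype(float)

    counts = obs @ obs.T
    if (counts < 1).any():
        jj, kk = np.unravel_index(int(np.argmin(counts)), counts.shape)
        raise InputError(
            f"animals {g.animal_ids[jj]!r} and {g.animal_ids[kk]!r} share no "
            "non-missing SNPs"
        )
    values = (z @ z.T) / counts

    if diagonal_mode == "gcta":
        x = calls.copy()
        x[miss] = 0.0
        term = (x * x - (1.0 + 2.0 * freqs) * x + 2.0 * freqs**2) / denom
        term[miss] = 0.0
        n_self = obs.sum(axis=1)
        np.fill_diagonal(values, 1.0 + term.sum(axis=1) / n_self)

    values = (values + values.T) / 2.0  # exact symmetry against fp noise
    return RelatednessMatrix(
        list(g.family_ids), list(g.animal_ids), values, counts.astype(np.int64)
    )


def write_grm(a: RelatednessMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.grm.id`` and ``<prefix>.grm.gz`` (GCTA text-GRM layout).

    The triangle file holds one line per lower-triangle pair including the
    diagonal: 1-based indices j >= k, the pair's SNP count, and A_jk.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in zip(a.family_ids, a.animal_ids):
            fh.write(f"{fid}\t{iid}\n")
    # mtime=0 keeps the gzip byte stream deterministic across reruns
    with open(f"{prefix}.grm.gz", "wb") as raw, gzip.GzipFile(
        fileobj=raw, mode="wb", mtime=0
    ) as gz:
        for j in range(a.n_animals):
            for k in range(j + 1):
                line = (
                    f"{j + 1}\t{k + 1}\t{int(a.pair_counts[j, k])}\t"
                    f"{float(a.values[j, k])!r}\n"
                )
                gz.write(line.encode())


def read_grm(prefix: str | Path) -> RelatednessMatrix:
    """Inverse of :func:`write_grm`."""
    prefix = Path(prefix)
    fids, iids = [], []
    for line in Path(f"{prefix}.grm.id").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{prefix}.grm.id: expected 2 fields, got {len(parts)}")
        fids.append(parts[0])
        iids.append(parts[1])
    n = len(iids)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    n_lines = 0
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{prefix}.grm.gz line {lineno}: expected 4 fields")
            j, k = int(parts[0]) - 1, int(parts[1]) - 1
            if not (0 <= k <= j < n):
                raise FormatError(f"{prefix}.grm.gz line {lineno}: index out of range")
            counts[j, k] = counts[k, j] = int(parts[2])
            values[j, k] = values[k, j] = float(parts[3])
            n_lines += 1
    if n_lines != n * (n + 1) // 2:
        raise FormatError(
            f"{prefix}.grm.gz: truncated triangle ({n_lines} of {n * (n + 1) // 2} lines)"
        )
    return RelatednessMatrix(fids, iids, values, counts)
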