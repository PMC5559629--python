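"""16S sequence relatedness of an OTU set versus random subsets.

Percent identity is computed from a global (end-to-end) pairwise alignment
under affine gap scoring (Gotoh's algorithm): identity = 100 * matched
columns / total alignment columns, gap columns included in the denominator.
A gap of length L costs ``gap_open + gap_extend * (L - 1)``; end gaps are
penalized like internal ones.  ``N`` symbols align but never count as
matches and score as mismatches.

The clade test compares the mean pairwise identity of a candidate OTU set
against the distribution over random same-size subsets of an eligible pool,
with the add-one empirical p-value (1 + #{null >= observed}) / (1 + draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, InputError

_ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_NEG = -1e30  # effective -inf that survives additions

#: lineage ranks in a greengenes-style string, outermost first
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class AlignmentScoring:
    """Affine-gap alignment parameters (defaults: +2/-1, open -5, extend -2)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def substitution(self) -> np.ndarray:
        s = np.full((5, 5), self.mismatch)
        for i in range(4):
            s[i, i] = self.match
        s[4, :] = self.mismatch  # N never matches, not even N vs N
        s[:, 4] = self.mismatch
        return s


@dataclass
class SequenceSet:
    """OTU id -> nucleotide sequence, with optional taxonomy lineages."""

    sequences: dict[str, str]
    taxonomy: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for oid, seq in self.sequences.items():
            if not seq:
                raise InputError(f"empty sequence for {oid!r}")
            if set(seq) - set(_ALPHABET):
                raise InputError(f"non-ACGTN symbol in sequence {oid!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=oid, description="")
            for oid, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path, taxonomy=None) -> "SequenceSet":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs, taxonomy)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise InputError(f"non-ACGTN symbol {exc.args[0]!r}") from exc


try:  # numba makes the DP ~50x faster; the identical code runs without it
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=True)
def _gotoh_kernel(a, b, sub, go, ge):  # pragma: no cover - exercised via wrapper
    """Global affine-gap DP (Gotoh).  Returns (score, matches, columns).

    Three states: M (diagonal), Ix (vertical gap, consumes a), Iy
    (horizontal gap, consumes b); gap switches are allowed at opening cost.
    Identity is made path-independent: alongside the score DP, a second DP
    over score-tight transitions carries the maximum match count among all
    optimal alignments (ties broken toward fewer columns), so the reported
    identity does not depend on an arbitrary traceback order and is
    invariant under jointly reversing or complementing both sequences.
    """
    n1, n2 = len(a), len(b)
    neg = _NEG
    eps = 1e-9
    # score matrices per state
    M = np.full((n1 + 1, n2 + 1), neg)
    Ix = np.full((n1 + 1, n2 + 1), neg)
    Iy = np.full((n1 + 1, n2 + 1), neg)
    # best (matches, -columns) lexicographic per state over tight paths
    Mm = np.full((n1 + 1, n2 + 1), -1, dtype=np.int64)
    Xm = np.full((n1 + 1, n2 + 1), -1, dtype=np.int64)
    Ym = np.full((n1 + 1, n2 + 1), -1, dtype=np.int64)
    Mc = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    Xc = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    Yc = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    M[0, 0] = 0.0
    Mm[0, 0] = 0
    for j in range(1, n2 + 1):
        Iy[0, j] = go + ge * (j - 1)
        Ym[0, j] = 0
        Yc[0, j] = j
    for i in range(1, n1 + 1):
        Ix[i, 0] = go + ge * (i - 1)
        Xm[i, 0] = 0
        Xc[i, 0] = i
    for i in range(1, n1 + 1):
        ai = a[i - 1]
        for j in range(1, n2 + 1):
            bj = b[j - 1]
            s = sub[ai, bj]
            hit = 1 if (ai == bj and ai != 4) else 0
            # --- M state: diagonal from any state at (i-1, j-1)
            best = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best + s
            bm, bc = -1, 0
            if M[i - 1, j - 1] > best - eps and Mm[i - 1, j - 1] >= 0:
                bm, bc = Mm[i - 1, j - 1], Mc[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best - eps and Xm[i - 1, j - 1] >= 0:
                if Xm[i - 1, j - 1] > bm or (
                    Xm[i - 1, j - 1] == bm and Xc[i - 1, j - 1] < bc
                ):
                    bm, bc = Xm[i - 1, j - 1], Xc[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best - eps and Ym[i - 1, j - 1] >= 0:
                if Ym[i - 1, j - 1] > bm or (
                    Ym[i - 1, j - 1] == bm and Yc[i - 1, j - 1] < bc
                ):
                    bm, bc = Ym[i - 1, j - 1], Yc[i - 1, j - 1]
            Mm[i, j] = bm + hit if bm >= 0 else -1
            Mc[i, j] = bc + 1
            # --- Ix state: vertical gap consuming a[i-1]
            c0 = M[i - 1, j] + go
            c1 = Ix[i - 1, j] + ge
            c2 = Iy[i - 1, j] + go
            best = max(c0, c1, c2)
            Ix[i, j] = best
            bm, bc = -1, 0
            if c0 > best - eps and Mm[i - 1, j] >= 0:
                bm, bc = Mm[i - 1, j], Mc[i - 1, j]
            if c1 > best - eps and Xm[i - 1, j] >= 0:
                if Xm[i - 1, j] > bm or (Xm[i - 1, j] == bm and Xc[i - 1, j] < bc):
                    bm, bc = Xm[i - 1, j], Xc[i - 1, j]
            if c2 > best - eps and Ym[i - 1, j] >= 0:
                if Ym[i - 1, j] > bm or (Ym[i - 1, j] == bm and Yc[i - 1, j] < bc):
                    bm, bc = Ym[i - 1, j], Yc[i - 1, j]
            Xm[i, j] = bm
            Xc[i, j] = bc + 1
            # --- Iy state: horizontal gap consuming b[j-1]
            c0 = M[i, j - 1] + go
            c1 = Ix[i, j - 1] + go
            c2 = Iy[i, j - 1] + ge
            best = max(c0, c1, c2)
            Iy[i, j] = best
            bm, bc = -1, 0
            if c0 > best - eps and Mm[i, j - 1] >= 0:
                bm, bc = Mm[i, j - 1], Mc[i, j - 1]
            if c1 > best - eps and Xm[i, j - 1] >= 0:
                if Xm[i, j - 1] > bm or (Xm[i, j - 1] == bm and Xc[i, j - 1] < bc):
                    bm, bc = Xm[i, j - 1], Xc[i, j - 1]
            if c2 > best - eps and Ym[i, j - 1] >= 0:
                if Ym[i, j - 1] > bm or (Ym[i, j - 1] == bm and Yc[i, j - 1] < bc):
                    bm, bc = Ym[i, j - 1], Yc[i, j - 1]
            Ym[i, j] = bm
            Yc[i, j] = bc + 1

    score = max(M[n1, n2], Ix[n1, n2], Iy[n1, n2])
    matches, columns = -1, 0
    if M[n1, n2] > score - eps and Mm[n1, n2] >= 0:
        matches, columns = Mm[n1, n2], Mc[n1, n2]
    if Ix[n1, n2] > score - eps and Xm[n1, n2] >= 0:
        if Xm[n1, n2] > matches or (Xm[n1, n2] == matches and Xc[n1, n2] < columns):
            matches, columns = Xm[n1, n2], Xc[n1, n2]
    if Iy[n1, n2] > score - eps and Ym[n1, n2] >= 0:
        if Ym[n1, n2] > matches or (Ym[n1, n2] == matches and Yc[n1, n2] < columns):
            matches, columns = Ym[n1, n2], Yc[n1, n2]
    return score, matches, columns


def _gotoh(a: np.ndarray, b: np.ndarray, sc: AlignmentScoring):
    score, matches, columns = _gotoh_kernel(
        a.astype(np.int64), b.astype(np.int64), sc.substitution(),
        float(sc.gap_open), float(sc.gap_extend),
    )
    return float(score), int(matches), int(columns)


def pairwise_identity(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Percent identity of a global pairwise alignment of two sequences.

    Symmetric in its arguments; returns a value in [0, 100].
    """
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    scoring = scoring or AlignmentScoring()
    _, matches, columns = _gotoh(_encode(seq_a), _encode(seq_b), scoring)
    return 100.0 * matches / columns


def alignment_score(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Optimal global alignment score (exposed for oracle comparisons)."""
    scoring = scoring or AlignmentScoring()
    score, _, _ = _gotoh(_encode(seq_a), _encode(seq_b), scoring)
    return score


def mean_pairwise_similarity(
    s: SequenceSet,
    ids,
    scoring: AlignmentScoring | None = None,
    _cache: dict | None = None,
) -> float:
    """Mean percent identity over all unordered pairs in ``ids``."""
    ids = list(ids)
    if len(ids) < 2:
        raise InputError("need at least two sequences for pairwise similarity")
    missing = set(ids) - set(s.sequences)
    if missing:
        raise InputError(f"ids not in sequence set: {sorted(missing)[:5]}")
    total = 0.0
    count = 0
    for x, y in combinations(ids, 2):
        if _cache is not None:
            key = (x, y) if x <= y else (y, x)
            if key not in _cache:
                _cache[key] = pairwise_identity(s.sequences[x], s.sequences[y], scoring)
            total += _cache[key]
        else:
            total += pairwise_identity(s.sequences[x], s.sequences[y], scoring)
        count += 1
    return total / count


@dataclass
class SimilarityNullResult:
    """Observed mean identity versus random same-size subsets."""

    observed: float
    null_means: np.ndarray
    p_value: float
    n_draws: int
    subset_size: int
    seed: int | None


def similarity_null_test(
    s: SequenceSet,
    heritable_ids,
    eligible_ids,
    n_draws: int = 100,
    seed: int | None = None,
    scoring: AlignmentScoring | None = None,
) -> SimilarityNullResult:
    """Test whether a candidate OTU set is more 16S-similar than random sets.

    Draws ``n_draws`` uniform subsets of the eligible pool, each the size of
    the candidate set, and ranks the candidate set's mean pairwise identity
    among them; p = (1 + #{null >= observed}) / (n_draws + 1), never zero.
    """
    heritable = list(heritable_ids)
    eligible = list(eligible_ids)
    if len(heritable) < 2:
        raise InputError("candidate set needs at least two OTUs")
    if not set(heritable) <= set(eligible):
        raise InputError("candidate ids must be a subset of the eligible pool")
    if not set(eligible) <= set(s.sequences):
        raise InputError("eligible ids must all have sequences")
    if len(eligible) < len(heritable):
        raise InputError("eligible pool smaller than candidate set")
    if n_draws < 1:
        raise ConfigError("n_draws must be at least 1")

    cache: dict = {}
    observed = mean_pairwise_similarity(s, heritable, scoring, _cache=cache)
    rng = np.random.default_rng(seed)
    m = len(heritable)
    null_means = np.empty(n_draws)
    pool = np.asarray(eligible, dtype=object)
    for t in range(n_draws):
        subset = rng.choice(pool, size=m, replace=False)
        null_means[t] = mean_pairwise_similarity(s, subset, scoring, _cache=cache)
    p = (1.0 + int((null_means >= observed).sum())) / (n_draws + 1.0)
    return SimilarityNullResult(observed, null_means, p, n_draws, m, seed)


def taxon_at_rank(lineage: str, rank: str) -> str:
    """Extract the taxon name at a rank from a ';'-separated lineage string;
    absent or blank levels map to ``"unclassified"``."""
    if rank not in RANKS:
        raise ConfigError(f"unknown rank {rank!r}; choose from {RANKS}")
    parts = [p.strip() for p in str(lineage).split(";")]
    idx = RANKS.index(rank)
    if idx >= len(parts) or not parts[idx]:
        return "unclassified"
    return parts[idx]


def taxon_enrichment(taxonomy: pd.Series, heritable_ids, rank: str = "order") -> pd.DataFrame:
    """Per-taxon 2x2 enrichment of a candidate OTU set, Fisher exact test.

    For each taxon at ``rank`` among the eligible OTUs (the index of
    ``taxonomy``), builds the table (heritable vs not) x (in taxon vs not)
    and computes the two-sided Fisher exact p-value.

    Returns a DataFrame indexed by taxon with columns hc, hn, nc, nn,
    odds_ratio, p_value.
    """
    heritable = set(heritable_ids)
    missing = heritable - set(taxonomy.index)
    if missing:
        raise InputError(f"heritable ids not in taxonomy: {sorted(missing)[:5]}")
    taxa = taxonomy.map(lambda s: taxon_at_rank(s, rank))
    is_h = taxonomy.index.isin(heritable)
    rows = {}
    for taxon in sorted(taxa.unique()):
        in_t = (taxa == taxon).to_numpy()
        hc = int((is_h & in_t).sum())
        hn = int((is_h & ~in_t).sum())
        nc = int((~is_h & in_t).sum())
        nn = int((~is_h & ~in_t).sum())
        odds, p = stats.fisher_exact([[hc, hn], [nc, nn]], alternative="two-sided")
        rows[taxon] = dict(hc=hc, hn=hn, nc=nc, nn=nn, odds_ratio=odds, p_value=p)
    return pd.DataFrame.from_dict(rows, orient="index")
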