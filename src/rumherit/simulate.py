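"""Synthetic herd, microbiome, 16S and trait generators.

These generators reproduce the statistical structure the downstream
analyses assume, at desk scale:

* a cohort structured as half-sib sire families (expected additive
  relatedness 0.25 within a family), with independent biallelic SNPs drawn
  from per-SNP allele frequencies;
* an OTU table in which a planted subset has genetically driven abundance:
  the genetic latent is drawn with covariance ``true_h2 * A`` through the
  relatedness matrix, day replicates share it, and a strictly monotone
  (exponential) map plus presence-zeroing and per-sample renormalization
  produce a right-skewed compositional table;
* 16S sequences in which the planted OTUs form a tight star-tree clade
  with a controllable within-clade identity, against a more diverged
  background, with the clade enriched for one taxonomic order;
* trait/index columns linearly linked to chosen OTUs plus noise.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .errors import ConfigError, InputError
from .grm import RelatednessMatrix
from .phylo import SequenceSet
from .plink import MISSING, GenotypeMatrix, SNPRecord

#: sire-family layout of the study herd: 11 groups of half-siblings,
#: one of four, one of three, nine of two
DEFAULT_FAMILIES: tuple[tuple[str, int], ...] = tuple(
    [("F01", 4), ("F02", 3)] + [(f"F{i:02d}", 2) for i in range(3, 12)]
)


@dataclass
class HerdDesign:
    """Cohort layout and SNP-panel parameters for :func:`simulate_genotypes`.

    Defaults mirror the study herd: 78 animals, 47 genotyped, 11 half-sib
    sire families, ~40k biallelic SNPs surviving QC with MAF >= 0.05, and a
    small chip missing-call rate.
    """

    n_animals: int = 78
    n_genotyped: int = 47
    families: tuple[tuple[str, int], ...] = DEFAULT_FAMILIES
    n_snps: int = 40_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotyped > self.n_animals:
            raise ConfigError("n_genotyped exceeds n_animals")
        if sum(c for _, c in self.families) > self.n_animals:
            raise ConfigError("family offspring counts exceed n_animals")
        if sum(c for _, c in self.families) > self.n_genotyped:
            raise ConfigError("family offspring counts exceed n_genotyped")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")

    def animal_ids(self) -> list[str]:
        return [f"cow{i + 1:03d}" for i in range(self.n_animals)]

    def genotyped_ids(self) -> list[str]:
        return self.animal_ids()[: self.n_genotyped]


def simulate_genotypes(design: HerdDesign) -> tuple[GenotypeMatrix, RelatednessMatrix]:
    """Simulate genotypes for the genotyped subset of a half-sib herd.

    Per SNP, the reference-allele frequency is uniform on ``maf_range``.
    Each sire carries two haplotype alleles drawn from that frequency;
    every offspring inherits one of them (chosen independently per SNP —
    SNPs are unlinked) plus a fresh dam allele.  Animals outside the
    families are unrelated draws from the population frequencies.

    Returns the genotype matrix and the pedigree-expected relatedness
    matrix (1 on the diagonal, 0.25 for half-sib pairs, 0 elsewhere).
    """
    rng = np.random.default_rng(design.seed)
    n, m = design.n_genotyped, design.n_snps
    p = rng.uniform(*design.maf_range, size=m)

    family_of = {}
    fids = []
    idx = 0
    for fid, count in design.families:
        for _ in range(count):
            family_of[idx] = fid
            fids.append(fid)
            idx += 1
    for k in range(idx, n):
        fids.append(f"U{k + 1:03d}")

    calls = np.empty((n, m), dtype=np.int8)
    row = 0
    for fid, count in design.families:
        sire = rng.random((2, m)) < p  # two sire haplotypes
        for _ in range(count):
            pick = rng.integers(0, 2, size=m)
            sire_allele = sire[pick, np.arange(m)]
            dam_allele = rng.random(m) < p
            calls[row] = sire_allele.astype(np.int8) + dam_allele.astype(np.int8)
            row += 1
    for r in range(row, n):
        calls[r] = (rng.random(m) < p).astype(np.int8) + (rng.random(m) < p).astype(
            np.int8
        )

    if design.missing_rate > 0:
        calls[rng.random((n, m)) < design.missing_rate] = MISSING

    ids = design.genotyped_ids()
    snps = [
        SNPRecord(f"snp{i + 1:06d}", str(1 + i % 29), 0.0, 1000 * (i + 1))
        for i in range(m)
    ]
    info = [("0", "0", "2", "-9")] * n  # dams of a dairy herd
    g = GenotypeMatrix(fids, ids, info, snps, calls)

    ped = np.eye(n)
    for j in range(n):
        for k in range(n):
            if j != k and j in family_of and k in family_of:
                if family_of[j] == family_of[k]:
                    ped[j, k] = 0.25
    pedigree = RelatednessMatrix(fids, ids, ped, np.full((n, n), m, dtype=np.int64))
    return g, pedigree


@dataclass
class PlantedMicrobiome:
    """Parameters of the planted-signal OTU table and 16S sequences.

    ``true_h2`` is the heritability of each planted OTU's latent on the
    per-day scale; ``presence_profile`` is the fraction of animals in which
    an OTU is nonzero (scalar applied to all OTUs, or a mapping by OTU id).
    ``clade_divergence``/``background_divergence`` are expected pairwise
    identity fractions of the planted clade and the background pool.
    """

    n_otus: int = 2000
    n_days: int = 3
    n_heritable: int = 22
    true_h2: float = 0.85
    presence_profile: float | dict = 1.0
    clade_divergence: float = 0.90
    background_divergence: float = 0.75
    day_noise_frac: float = 0.2
    latent_scale: float = 0.25
    seq_length: int = 250
    seed: int = 0
    heritable_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_h2 <= 1.0):
            raise ConfigError("true_h2 must lie in [0, 1]")
        if self.clade_divergence <= self.background_divergence:
            raise ConfigError(
                "clade_divergence must exceed background_divergence"
            )
        if self.n_heritable > self.n_otus:
            raise ConfigError("more heritable OTUs than OTUs")

    def otu_ids(self) -> list[str]:
        return [f"otu{i + 1:05d}" for i in range(self.n_otus)]

    def planted_ids(self) -> list[str]:
        if self.heritable_ids is not None:
            ids = list(self.heritable_ids)
            if not set(ids) <= set(self.otu_ids()):
                raise ConfigError("heritable_ids outside the OTU id range")
            return ids
        return self.otu_ids()[: self.n_heritable]

    def presence_of(self, otu_id: str) -> float:
        if isinstance(self.presence_profile, dict):
            frac = float(self.presence_profile.get(otu_id, 1.0))
        else:
            frac = float(self.presence_profile)
        if not (0.0 < frac <= 1.0):
            raise ConfigError(f"presence fraction {frac} outside (0, 1]")
        return frac


def simulate_abundances(
    grm: RelatednessMatrix | np.ndarray,
    spec: PlantedMicrobiome,
    ungenotyped_ids: tuple[str, ...] = (),
) -> AbundanceTable:
    """Generate a compositional OTU table with planted heritable abundances.

    For each planted OTU the per-animal latent is ``g + e_shared + e_day``
    with ``g ~ N(0, true_h2 * A)``, the environmental parts independent and
    scaled so the per-day latent has unit variance and genetic fraction
    ``true_h2``.  Day noise has standard deviation ``day_noise_frac`` of the
    latent sd (capped by the available non-genetic variance), so the three
    day replicates share the genetic component.  Background OTUs get
    pure-noise latents of the same structure with ``true_h2 = 0``.
    Latents map to abundances through an exponential (log-normal shape),
    the lowest-latent animals are zeroed to match the presence fraction,
    and each (animal, day) sample is renormalized to sum to one.

    Animals in ``ungenotyped_ids`` (no genotypes, hence outside ``A``)
    receive independent unit-variance latents — noise from the genetic
    model's point of view, present so the full cohort can be traited.
    """
    if isinstance(grm, RelatednessMatrix):
        ids = list(grm.animal_ids)
        a = grm.values
    else:
        a = np.asarray(grm, dtype=float)
        ids = [f"cow{i + 1:03d}" for i in range(a.shape[0])]
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("relatedness matrix must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise InputError("relatedness matrix is not symmetric")
    overlap = set(ids) & set(ungenotyped_ids)
    if overlap:
        raise InputError(f"ungenotyped ids overlap the GRM: {sorted(overlap)[:5]}")

    n_g = a.shape[0]
    all_ids = ids + list(ungenotyped_ids)
    n = len(all_ids)
    rng = np.random.default_rng(spec.seed)

    # factor A = L L^T through its eigendecomposition, clipping the mildly
    # negative eigenvalues a pairwise-complete realized GRM can carry
    lam, q = np.linalg.eigh((a + a.T) / 2.0)
    if lam.min() < -0.05 * max(np.trace(a) / n_g, 1e-12):
        raise InputError("relatedness matrix is far from positive semidefinite")
    chol = q * np.sqrt(np.maximum(lam, 0.0))

    planted = set(spec.planted_ids())
    otu_ids = spec.otu_ids()
    values = np.empty((spec.n_otus, n, spec.n_days))
    for r, oid in enumerate(otu_ids):
        h2 = spec.true_h2 if oid in planted else 0.0
        var_day = min(spec.day_noise_frac**2, max(1.0 - h2, 0.0))
        var_shared = max(1.0 - h2 - var_day, 0.0)

        g = np.zeros(n)
        if h2 > 0:
            g[:n_g] = np.sqrt(h2) * (chol @ rng.standard_normal(n_g))
            g[n_g:] = np.sqrt(h2) * rng.standard_normal(n - n_g)
        e_shared = np.sqrt(var_shared) * rng.standard_normal(n)
        base = g + e_shared
        day_noise = np.sqrt(var_day) * rng.standard_normal((n, spec.n_days))
        latent = base[:, None] + day_noise

        abund = np.exp(spec.latent_scale * latent)
        frac = spec.presence_of(oid)
        n_zero = n - int(np.ceil(frac * n))
        if n_zero > 0:
            drop = np.argsort(base, kind="stable")[:n_zero]
            abund[drop, :] = 0.0
        values[r] = abund

    sums = values.sum(axis=0, keepdims=True)
    values = values / np.where(sums > 0, sums, 1.0)

    taxonomy = pd.Series("", index=otu_ids)
    return AbundanceTable.from_arrays(
        otu_ids, all_ids, list(range(1, spec.n_days + 1)), values, taxonomy
    )


def _identity_to_rate(target: float) -> float:
    """Per-branch substitution probability q so that two sequences diverged
    independently from a common ancestor have expected identity ``target``:
    P(match) = (1-q)^2 + q^2/3 (a mutated site matches only if both lineages
    mutated to the same of three alternatives)."""
    if not (0.0 < target <= 1.0):
        raise ConfigError(f"identity target {target} outside (0, 1]")
    # solve (4/3) q^2 - 2 q + (1 - t) = 0 for the root in [0, 3/4]
    disc = 4.0 - (16.0 / 3.0) * (1.0 - target)
    if disc < 0:
        raise ConfigError(f"identity target {target} unattainable")
    return (2.0 - np.sqrt(disc)) / (8.0 / 3.0)


_ORDER_POOL = (
    ("Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella", 0.25),
    ("Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminococcus", 0.35),
    ("Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Butyrivibrio", 0.15),
    ("Bacteria;Firmicutes;Negativicutes;Selenomonadales;Selenomonadaceae;Selenomonas", 0.10),
    ("Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Treponemataceae;Treponema", 0.10),
    ("Bacteria;Fibrobacteres;Fibrobacteria;Fibrobacterales;Fibrobacteraceae;Fibrobacter", 0.05),
)

_CLADE_LINEAGE = "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella"


def simulate_sequences(spec: PlantedMicrobiome) -> SequenceSet:
    """Generate one ~250 nt 16S fragment per OTU with a planted tight clade.

    Star-tree model: all background OTUs (and the clade ancestor) diverge
    independently from a global ancestor at the background substitution
    rate; planted OTUs diverge from the clade ancestor at the (lower)
    within-clade rate.  Taxonomy strings are assigned with the planted
    clade enriched for the Bacteroidales order (80% of clade members),
    background lineages drawn from a fixed rumen-like pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E0]))
    bases = np.arange(4, dtype=np.int8)
    length = spec.seq_length
    q_clade = _identity_to_rate(spec.clade_divergence)
    q_back = _identity_to_rate(spec.background_divergence)

    def mutate(seq: np.ndarray, q: float) -> np.ndarray:
        out = seq.copy()
        hit = rng.random(length) < q
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
            out[hit] = (out[hit] + shift) % 4
        return out

    ancestor = rng.integers(0, 4, size=length, dtype=np.int8)
    clade_anc = mutate(ancestor, q_back)

    planted = spec.planted_ids()
    planted_set = set(planted)
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    tax: dict[str, str] = {}
    lineages = [l for l, _ in _ORDER_POOL]
    weights = np.array([w for _, w in _ORDER_POOL])
    for oid in spec.otu_ids():
        if oid in planted_set:
            arr = mutate(clade_anc, q_clade)
            tax[oid] = (
                _CLADE_LINEAGE if rng.random() < 0.8
                else lineages[1]
            )
        else:
            arr = mutate(ancestor, q_back)
            tax[oid] = lineages[int(rng.choice(len(lineages), p=weights / weights.sum()))]
        seqs[oid] = "".join(alphabet[arr])
    return SequenceSet(seqs, pd.Series(tax))


@dataclass
class TraitLinkageSpec:
    """Linear OTU -> trait/index linkage with additive noise.

    ``links`` maps an index name to a list of (otu_id, signed weight)
    pairs; each index column is the weighted sum of the linked OTUs'
    mean-across-days abundances plus N(0, noise_sd^2) noise.
    """

    links: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    @property
    def index_names(self) -> list[str]:
        return list(self.links)


def default_trait_spec(heritable_ids, noise_sd: float = 1.0, seed: int = 0) -> TraitLinkageSpec:
    """A rumen-flavoured set of indices linked to planted OTUs.

    Mimics the structure of metabolite/physiology panels: fermentation
    ratios and acids carry strong mixed-sign loadings on several planted
    OTUs, production traits weaker ones, plus one pure-noise control.
    """
    ids = list(heritable_ids)
    if len(ids) < 4:
        raise ConfigError("need at least four linked OTUs for the default panel")
    pick = lambda *k: [ids[i % len(ids)] for i in k]
    links = {
        "propionate_acetate_ratio": [(o, w) for o, w in zip(pick(0, 1, 2), (3.0, -2.0, 1.5))],
        "methane": [(o, w) for o, w in zip(pick(1, 3), (-2.5, 2.0))],
        "propionate": [(o, w) for o, w in zip(pick(0, 2), (2.0, 2.0))],
        "valerate": [(o, w) for o, w in zip(pick(2, 3), (-1.5, 1.0))],
        "glycine": [(ids[0], 1.5)],
        "milk_protein": [(o, w) for o, w in zip(pick(1, 2), (1.0, 0.8))],
        "rfi": [(ids[3], 1.2)],
        "dmi": [(ids[0], -1.0)],
        "noise_control": [],
    }
    categories = {
        "propionate_acetate_ratio": "VFA",
        "methane": "other metabolite",
        "propionate": "VFA",
        "valerate": "VFA",
        "glycine": "amino acid",
        "milk_protein": "physiological",
        "rfi": "physiological",
        "dmi": "physiological",
        "noise_control": "other metabolite",
    }
    return TraitLinkageSpec(links, categories, noise_sd=noise_sd, seed=seed)


def simulate_traits(abund: AbundanceTable, spec: TraitLinkageSpec) -> pd.DataFrame:
    """Animal x index trait table from linear OTU linkage plus noise.

    Linked abundances are standardized across animals before weighting so
    stated weights are comparable between OTUs of different typical
    abundance; noise is N(0, noise_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    mean_ab = abund.animal_mean()  # otu x animal
    animals = list(mean_ab.columns)
    out = {}
    for index, pairs in spec.links.items():
        col = np.zeros(len(animals))
        for oid, weight in pairs:
            if oid not in mean_ab.index:
                raise InputError(f"index {index!r} links unknown OTU {oid!r}")
            v = mean_ab.loc[oid].to_numpy(dtype=float)
            sd = v.std()
            if sd > 0:
                v = (v - v.mean()) / sd
            col = col + weight * v
        col = col + spec.noise_sd * rng.standard_normal(len(animals))
        out[index] = col
    return pd.DataFrame(out, index=animals)
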