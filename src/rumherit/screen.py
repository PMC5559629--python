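"""Per-day GREML screen of OTU abundances with a three-day consensus call
and a genetics-shuffling permutation null.

An OTU is called heritable only when every sampling day's independent fit
clears both thresholds (h2 above ``h2_min`` and boundary-LRT p below
``alpha``).  The false-discovery calibration reruns the entire consensus
screen under permutations of the genotyped animals' genetic identities —
one shared permutation per iteration across all OTUs and days — and ranks
the observed heritable count among the permuted counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .abundance import AbundanceTable
from .errors import ConfigError, DegenerateDataError, InputError
from .greml import EigenGRM, GREML, eigen_prepare, lrt_pvalue, reml_fit_batch
from .grm import RelatednessMatrix


def presence_filter(
    t: AbundanceTable, genotyped_ids, min_present: int = 12
) -> AbundanceTable:
    """Keep OTUs present in at least ``min_present`` genotyped animals.

    An animal counts as present when the OTU's abundance is nonzero in at
    least one of its day samples.
    """
    genotyped = list(genotyped_ids)
    if min_present > len(genotyped):
        raise ConfigError(
            f"min_present={min_present} exceeds the {len(genotyped)} genotyped animals"
        )
    missing = set(genotyped) - set(t.animals)
    if missing:
        raise InputError(f"genotyped ids not in table: {sorted(missing)[:5]}")
    counts = t.presence_counts(genotyped)
    keep = counts[counts >= min_present].index
    return t.subset_otus(keep)


@dataclass
class ScreenResult:
    """Consensus heritable set plus the per-(OTU, day) fit table."""

    consensus_ids: set[str]
    results: pd.DataFrame = field(repr=False)  # columns otu_id, day, h2, p, ...
    thresholds: tuple  # (h2_min, alpha, required_days)


@dataclass
class PermutationFDRReport:
    """Observed consensus count versus genetics-shuffled reruns."""

    observed_count: int
    permuted_counts: np.ndarray
    fraction_below: float
    n_perm: int
    seed: int | None


class HeritabilityScreen(BaseEstimator):
    """Scikit-learn-style consensus heritability screen.

    Parameters
    ----------
    h2_min : float
        Heritability threshold; a day passes when h2 > h2_min (strict).
    alpha : float
        LRT p-value threshold; a day passes when p < alpha (strict).
    min_animals : int
        Minimum phenotyped animals for any single fit; an (OTU, day) with
        fewer is marked failed and the OTU is excluded from the consensus.
    rint : bool
        Apply a rank-based inverse-normal transform to each phenotype
        before fitting (off by default: raw relative abundance).

    Attributes (after fit)
    ----------------------
    consensus_ids_ : set of OTU ids passing both thresholds on every day
    results_ : per-(OTU, day) DataFrame of variance components
    """

    def __init__(self, h2_min: float = 0.7, alpha: float = 0.05,
                 min_animals: int = 10, rint: bool = False):
        self.h2_min = h2_min
        self.alpha = alpha
        self.min_animals = min_animals
        self.rint = rint

    def fit(self, t: AbundanceTable, a, genotyped_ids=None):
        """Run per-day GREML on every OTU of ``t`` against kernel ``a``.

        ``a`` may be a RelatednessMatrix, a square array or an EigenGRM
        cache; when genotyped_ids is omitted it defaults to the kernel's
        animal ids (RelatednessMatrix) or the table's animals.
        """
        eig, ids = _prepare_kernel(a, genotyped_ids, t)
        rows = []
        consensus: dict[str, bool] = {oid: True for oid in t.otu_ids}
        for day in t.days:
            day_m = t.day_matrix(day)
            have = [c for c in ids if c in day_m.columns]
            if len(have) < len(ids):
                sub_eig, use_ids = _sub_kernel(a, have)
            else:
                sub_eig, use_ids = eig, ids
            y_all = day_m[use_ids].to_numpy(dtype=float).T  # animals x otus
            if self.rint:
                y_all = _rank_inverse_normal(y_all)
            ok = (np.ptp(y_all, axis=0) > 0) & (y_all.shape[0] >= self.min_animals)
            fit_cols = np.flatnonzero(ok)
            fits = (
                reml_fit_batch(sub_eig, y_all[:, fit_cols], min_animals=self.min_animals)
                if fit_cols.size
                else []
            )
            by_col = dict(zip(fit_cols, fits))
            for j, oid in enumerate(t.otu_ids):
                vc = by_col.get(j)
                if vc is None:
                    consensus[oid] = False
                    rows.append(
                        dict(otu_id=oid, day=day, h2=np.nan, sigma_u2=np.nan,
                             sigma_e2=np.nan, lr=np.nan, p_value=np.nan,
                             n_used=len(use_ids), converged=False, failed=True)
                    )
                    continue
                passes = (vc.h2 > self.h2_min) and (vc.p_value < self.alpha)
                consensus[oid] = consensus[oid] and passes
                rows.append(
                    dict(otu_id=oid, day=day, h2=vc.h2, sigma_u2=vc.sigma_u2,
                         sigma_e2=vc.sigma_e2, lr=vc.lr_statistic,
                         p_value=vc.p_value, n_used=vc.n_used,
                         converged=vc.converged, failed=False)
                )
        self.results_ = pd.DataFrame(rows)
        self.consensus_ids_ = {oid for oid, keep in consensus.items() if keep}
        self.n_days_ = len(t.days)
        return self

    def result_(self) -> ScreenResult:
        return ScreenResult(
            set(self.consensus_ids_), self.results_.copy(),
            (self.h2_min, self.alpha, self.n_days_),
        )


def _prepare_kernel(a, genotyped_ids, t: AbundanceTable):
    if isinstance(a, EigenGRM):
        ids = list(genotyped_ids) if genotyped_ids is not None else (
            list(a.animal_ids) if a.animal_ids else list(t.animals)
        )
        if a.n != len(ids):
            raise InputError("kernel size does not match genotyped id count")
        return a, ids
    if isinstance(a, RelatednessMatrix):
        ids = list(genotyped_ids) if genotyped_ids is not None else list(a.animal_ids)
        return eigen_prepare(a.align(ids)), ids
    mat = np.asarray(a, dtype=float)
    ids = list(genotyped_ids) if genotyped_ids is not None else list(t.animals)
    if mat.shape[0] != len(ids):
        raise InputError("kernel size does not match genotyped id count")
    return eigen_prepare(mat), ids


def _sub_kernel(a, ids):
    if isinstance(a, RelatednessMatrix):
        return eigen_prepare(a.align(ids)), ids
    raise InputError(
        "animals missing day samples require a RelatednessMatrix kernel "
        "so the screen can realign"
    )


def _rank_inverse_normal(y: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    from scipy import stats as _st

    n = y.shape[0]
    ranks = _st.rankdata(y, axis=0)
    return _st.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def screen_heritable(
    t: AbundanceTable, a, h2_min: float = 0.7, alpha: float = 0.05,
    genotyped_ids=None, **params,
) -> ScreenResult:
    """Functional wrapper over :class:`HeritabilityScreen`."""
    est = HeritabilityScreen(h2_min=h2_min, alpha=alpha, **params)
    return est.fit(t, a, genotyped_ids=genotyped_ids).result_()


def permutation_fdr(
    t: AbundanceTable,
    a,
    n_perm: int = 100,
    seed: int | None = None,
    h2_min: float = 0.7,
    alpha: float = 0.05,
    genotyped_ids=None,
    **params,
) -> PermutationFDRReport:
    """Calibrate the consensus count by shuffling genetic identities.

    Each iteration draws one permutation of the genotyped animals and
    applies it to the GRM's rows and columns — implemented equivalently by
    permuting every phenotype vector's animal order, identically across all
    OTUs and days — then reruns the full consensus screen.  Reports the
    observed count and the fraction of permutations whose count is strictly
    smaller.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    eig, ids = _prepare_kernel(a, genotyped_ids, t)
    est = HeritabilityScreen(h2_min=h2_min, alpha=alpha, **params)
    observed = len(est.fit(t, eig, genotyped_ids=ids).consensus_ids_)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    n = len(ids)
    for it in range(n_perm):
        perm = rng.permutation(n)
        shuffled = _permute_animals(t, ids, perm)
        counts[it] = len(est.fit(shuffled, eig, genotyped_ids=ids).consensus_ids_)
    frac_below = float((counts < observed).mean())
    return PermutationFDRReport(observed, counts, frac_below, n_perm, seed)


def _permute_animals(t: AbundanceTable, ids: list[str], perm: np.ndarray) -> AbundanceTable:
    """Reassign the genotyped animals' sample columns according to ``perm``
    (animal ids[i] receives the samples of ids[perm[i]])."""
    rename = {}
    for i, target in enumerate(ids):
        source = ids[perm[i]]
        for day in t.days:
            rename[f"{source}_d{day}"] = f"{target}_d{day}"
    data = t.data.rename(columns=rename)
    data = data[t.data.columns]  # restore original column order
    return AbundanceTable(data, t.taxonomy)


def trait_heritability(
    traits: pd.DataFrame, a: RelatednessMatrix, min_animals: int = 10
) -> pd.DataFrame:
    """GREML heritability of each trait column, missing values dropped per trait.

    Constant or all-missing traits are skipped with a warning rather than
    raising, so a full panel can be processed in one call.
    """
    grm_ids = set(a.animal_ids)
    rows = []
    cache: dict[tuple, EigenGRM] = {}
    for name in traits.columns:
        col = pd.to_numeric(traits[name], errors="coerce")
        col = col[col.index.isin(grm_ids)].dropna()
        if len(col) < min_animals:
            warnings.warn(f"trait {name!r}: fewer than {min_animals} usable animals; skipped")
            continue
        if np.ptp(col.to_numpy()) == 0.0:
            warnings.warn(f"trait {name!r} is constant; skipped")
            continue
        key = tuple(col.index)
        if key not in cache:
            cache[key] = eigen_prepare(a.align(list(col.index)))
        est = GREML(min_animals=min_animals).fit(cache[key], col.to_numpy())
        rows.append(
            dict(trait=name, h2=est.h2_, sigma_u2=est.sigma_u2_,
                 sigma_e2=est.sigma_e2_, lr=est.lr_, p_value=est.pvalue_,
                 n_used=est.n_used_, converged=est.converged_)
        )
    return pd.DataFrame(rows)
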