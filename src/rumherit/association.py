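"""Spearman association of OTU abundance with trait/metabolite indices,
permutation calibration of mean correlations, heritable-vs-all comparison,
and the per-index OTU-correlation odds ratio.

Correlation analyses use the per-animal mean abundance across sampling
days over the full cohort (all animals with trait data), pairwise-complete
per (OTU, index).  The odds ratio for an index is (hc/hn)/(nc/nn) where hc
counts heritable OTUs nominally correlated (Spearman p < alpha), hn
heritable OTUs not correlated, and nc/nn the same for non-heritable OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .errors import ConfigError, InputError


def animal_abundance(t: AbundanceTable) -> pd.DataFrame:
    """OTU x animal matrix of mean abundance over each animal's available days."""
    return t.animal_mean()


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r with average ranks and the large-sample two-sided t p-value.

    Returns (nan, nan) when either vector has zero rank variance.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(tstat), df=n - 2))


def spearman_profile(
    abund: pd.DataFrame, traits: pd.DataFrame, min_animals: int = 10
) -> pd.DataFrame:
    """Spearman r and nominal p for every (OTU, index) pair.

    ``abund`` is OTU x animal; ``traits`` is animal x index with missing
    values allowed.  Animal sets are pairwise-complete per index.  Pairs
    with a constant vector are recorded with NaN r and a reason.

    Returns a long DataFrame: otu_id, index, r, p_value, n, reason.
    """
    shared = [a for a in abund.columns if a in traits.index]
    rows = []
    for index in traits.columns:
        col = pd.to_numeric(traits[index], errors="coerce").loc[shared]
        use = col.dropna()
        if len(use) < min_animals:
            raise InputError(
                f"index {index!r}: only {len(use)} non-missing animals "
                f"(minimum {min_animals})"
            )
        y = use.to_numpy(dtype=float)
        sub = abund[use.index].to_numpy(dtype=float)
        for i, oid in enumerate(abund.index):
            r, p = _spearman(sub[i], y)
            rows.append(
                dict(otu_id=oid, index=index, r=r, p_value=p, n=len(use),
                     reason="" if np.isfinite(r) else "constant vector")
            )
    return pd.DataFrame(rows)


@dataclass
class MeanCorrelationNull:
    """Permutation calibration of per-index mean correlations."""

    summary: pd.DataFrame = field(repr=False)
    n_perm: int = 0
    seed: int | None = None


def mean_correlation_null(
    abund: pd.DataFrame,
    traits: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MeanCorrelationNull:
    """Permutation null for the mean correlation of a (heritable) OTU set.

    The observed statistic per index is the mean over OTUs of the signed
    Spearman r, and separately of |r|.  Each iteration independently
    shuffles every OTU's abundance profile across animals and recomputes
    both statistics.  Empirical p-values use the add-one rule:
    on |mean r| for the signed statistic, on mean |r| directly.

    Returns per-index mean_r, mean_abs_r, p_mean_r, p_mean_abs_r, n_otus.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    if abund.shape[0] < 2:
        raise InputError("need at least two OTUs for a mean-correlation null")
    rng = np.random.default_rng(seed)
    shared = [a for a in abund.columns if a in traits.index]

    out = {}
    for index in traits.columns:
        col = pd.to_numeric(traits[index], errors="coerce").loc[shared].dropna()
        y = stats.rankdata(col.to_numpy(dtype=float))
        y = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
        sub = abund[col.index].to_numpy(dtype=float)
        ranks = stats.rankdata(sub, axis=1)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks**2).sum(axis=1))
        ok = norms > 0
        z = ranks[ok] / norms[ok, None]  # otus x animals, unit rank vectors
        if z.shape[0] < 2:
            warnings.warn(f"index {index!r}: fewer than two non-constant OTUs; skipped")
            continue
        r_obs = z @ y
        obs_mean = float(r_obs.mean())
        obs_abs = float(np.abs(r_obs).mean())
        null_mean = np.empty(n_perm)
        null_abs = np.empty(n_perm)
        n_animal = z.shape[1]
        for t in range(n_perm):
            idx = np.argsort(rng.random((z.shape[0], n_animal)), axis=1)
            zp = np.take_along_axis(z, idx, axis=1)
            rp = zp @ y
            null_mean[t] = rp.mean()
            null_abs[t] = np.abs(rp).mean()
        p_mean = (1 + int((np.abs(null_mean) >= abs(obs_mean)).sum())) / (n_perm + 1)
        p_abs = (1 + int((null_abs >= obs_abs).sum())) / (n_perm + 1)
        out[index] = dict(
            mean_r=obs_mean, mean_abs_r=obs_abs, p_mean_r=p_mean,
            p_mean_abs_r=p_abs, n_otus=int(z.shape[0]), n_animals=int(n_animal),
        )
    summary = pd.DataFrame.from_dict(out, orient="index")
    summary.index.name = "index"
    return MeanCorrelationNull(summary, n_perm, seed)


def mean_abs_corr_compare(
    profile: pd.DataFrame, heritable_ids
) -> pd.DataFrame:
    """Welch t-test of |r| between heritable and all other OTUs, per index.

    ``profile`` is the long output of :func:`spearman_profile` covering
    both groups.  Indices where either group has fewer than two finite |r|
    values are skipped with a warning.
    """
    heritable = set(heritable_ids)
    rows = []
    for index, grp in profile.groupby("index", sort=False):
        finite = grp[np.isfinite(grp["r"])]
        h = finite[finite["otu_id"].isin(heritable)]["r"].abs().to_numpy()
        o = finite[~finite["otu_id"].isin(heritable)]["r"].abs().to_numpy()
        if len(h) < 2 or len(o) < 2:
            warnings.warn(f"index {index!r}: a group has fewer than two OTUs; skipped")
            continue
        tstat, p = stats.ttest_ind(h, o, equal_var=False)
        rows.append(
            dict(index=index, mean_abs_r_heritable=h.mean(),
                 mean_abs_r_other=o.mean(), t_statistic=float(tstat),
                 p_value=float(p), n_heritable=len(h), n_other=len(o))
        )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """2x2 correlated-vs-not enrichment of heritable OTUs for one index."""

    index: str
    hc: int
    hn: int
    nc: int
    nn: int
    odds_ratio: float  # inf when hn*nc == 0 and hc*nn > 0; nan when a margin is empty
    fisher_p: float
    bonferroni_significant: bool


def correlation_odds_ratio(
    profile: pd.DataFrame, heritable_ids, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Per-index OTU-correlation odds ratio (hc/hn)/(nc/nn) with Fisher p.

    An OTU counts as correlated with an index when its nominal Spearman p
    is below ``alpha``; missing/undefined correlations count as not
    correlated.  The Bonferroni flag marks Fisher p < 0.05 / (number of
    indices tested).
    """
    heritable = set(heritable_ids)
    if profile.empty:
        raise InputError("empty correlation profile")
    indices = list(dict.fromkeys(profile["index"]))
    n_tests = len(indices)
    results = []
    for index in indices:
        grp = profile[profile["index"] == index]
        corr = (grp["p_value"] < alpha).fillna(False).to_numpy()
        is_h = grp["otu_id"].isin(heritable).to_numpy()
        hc = int((is_h & corr).sum())
        hn = int((is_h & ~corr).sum())
        nc = int((~is_h & corr).sum())
        nn = int((~is_h & ~corr).sum())
        if (hc + hn == 0) or (nc + nn == 0):
            odds = float("nan")
        elif hn * nc == 0:
            odds = float("inf") if hc * nn > 0 else float("nan")
        else:
            odds = (hc / hn) / (nc / nn)
        _, fisher_p = stats.fisher_exact([[hc, hn], [nc, nn]], alternative="two-sided")
        results.append(
            EnrichmentResult(index, hc, hn, nc, nn, odds, float(fisher_p),
                             bool(fisher_p < 0.05 / n_tests))
        )
    return results


def presence_abundance_correlation(
    abund: pd.DataFrame, heritable_ids
) -> tuple[float, float]:
    """Spearman r between presence counts and abundance sums across a set.

    For each OTU in ``heritable_ids``: presence = number of animals with
    nonzero mean abundance, total = sum of abundances across animals.
    """
    ids = list(heritable_ids)
    if len(ids) < 3:
        raise InputError("need at least three OTUs")
    sub = abund.loc[ids]
    presence = (sub > 0).sum(axis=1).to_numpy(dtype=float)
    totals = sub.sum(axis=1).to_numpy(dtype=float)
    r, p = _spearman(presence, totals)
    if not np.isfinite(r):
        raise InputError("presence counts are constant; correlation undefined")
    return r, p
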