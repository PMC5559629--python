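"""OTU relative-abundance table: OTU x (animal, sampling day) with taxonomy.

On disk the table is a TSV with columns ``otu_id``, ``taxonomy`` and one
column per animal-day sample named ``<animal>_d<day>`` (days 1..n).  Each
sample column holds relative abundances summing to at most 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

_SAMPLE_RE = re.compile(r"^(?P<animal>.+)_d(?P<day>\d+)$")


@dataclass
class AbundanceTable:
    """Relative abundances per (OTU, animal, day) plus taxonomy lineages.

    ``data`` is a DataFrame indexed by otu_id with one column per sample
    (``<animal>_d<day>``); ``taxonomy`` is a Series over the same index
    holding ``domain;phylum;class;order;family;genus`` lineage strings.
    """

    data: pd.DataFrame = field(repr=False)
    taxonomy: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.taxonomy.index):
            raise InputError("taxonomy index does not match abundance index")
        if not self.data.index.is_unique:
            raise InputError("duplicate OTU ids")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise InputError("negative abundances")
        sums = vals.sum(axis=0)
        if (sums > 1.0 + 1e-9).any():
            raise InputError("a sample column sums to more than 1")
        self._parse_samples()

    def _parse_samples(self) -> None:
        animals: list[str] = []
        days: set[int] = set()
        self._sample_key: dict[str, tuple[str, int]] = {}
        for col in self.data.columns:
            m = _SAMPLE_RE.match(col)
            if m is None:
                raise FormatError(f"sample column {col!r} is not of form <animal>_d<day>")
            animal, day = m.group("animal"), int(m.group("day"))
            if animal not in animals:
                animals.append(animal)
            days.add(day)
            self._sample_key[col] = (animal, day)
        self.animals: list[str] = animals
        self.days: list[int] = sorted(days)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    def day_matrix(self, day: int) -> pd.DataFrame:
        """OTU x animal matrix for one sampling day (animals without that
        day's sample are absent from the columns)."""
        cols = [c for c, (_, d) in self._sample_key.items() if d == day]
        if not cols:
            raise InputError(f"no samples for day {day}")
        out = self.data[cols].copy()
        out.columns = [self._sample_key[c][0] for c in cols]
        return out

    def animal_mean(self) -> pd.DataFrame:
        """OTU x animal matrix of per-animal means over available days."""
        by_animal: dict[str, list[str]] = {}
        for c, (a, _) in self._sample_key.items():
            by_animal.setdefault(a, []).append(c)
        return pd.DataFrame(
            {a: self.data[cols].mean(axis=1) for a, cols in by_animal.items()}
        )

    def presence_counts(self, animals: list[str] | None = None) -> pd.Series:
        """Animals in which each OTU is nonzero in at least one day sample."""
        present = self.animal_mean() > 0  # mean > 0 iff any day > 0 (nonneg)
        if animals is not None:
            missing = set(animals) - set(present.columns)
            if missing:
                raise InputError(f"animals absent from table: {sorted(missing)[:5]}")
            present = present[list(animals)]
        return present.sum(axis=1)

    def subset_otus(self, otu_ids) -> "AbundanceTable":
        ids = list(otu_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise InputError(f"unknown OTU ids: {sorted(missing)[:5]}")
        return AbundanceTable(self.data.loc[ids].copy(), self.taxonomy.loc[ids].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "taxonomy", self.taxonomy)
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="otu_id")
        if "taxonomy" not in df.columns:
            raise FormatError(f"{path}: missing 'taxonomy' column")
        tax = df.pop("taxonomy").astype(str)
        return cls(df.astype(float), tax)

    @classmethod
    def from_arrays(
        cls,
        otu_ids,
        animals,
        days,
        values: np.ndarray,
        taxonomy=None,
    ) -> "AbundanceTable":
        """Build from a dense (otu, animal, day) array.

        ``values`` has shape (n_otus, n_animals, n_days); sample columns are
        laid out animal-major (all of animal 1's days, then animal 2's, ...).
        """
        values = np.asarray(values, dtype=float)
        n_otu, n_animal, n_day = values.shape
        if n_otu != len(otu_ids) or n_animal != len(animals) or n_day != len(days):
            raise InputError("values shape does not match id lists")
        cols = [f"{a}_d{d}" for a in animals for d in days]
        flat = values.reshape(n_otu, n_animal * n_day)
        data = pd.DataFrame(flat, index=list(otu_ids), columns=cols)
        if taxonomy is None:
            taxonomy = pd.Series("", index=data.index)
        else:
            taxonomy = pd.Series(list(taxonomy), index=data.index)
        return cls(data, taxonomy)
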