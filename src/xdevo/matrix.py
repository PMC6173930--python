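"""Core in-memory containers: expression matrices with sample metadata, and
one-to-one ortholog maps.

An :class:`ExpressionMatrix` is the currency of the whole pipeline: a
genes x samples grid of finite numbers plus a per-sample metadata table
(species, developmental age, platform, replicate group) and a ``scale`` tag
that records where the matrix sits in the normalisation chain
(``raw`` -> ``log`` -> ``log_centered``).  Operations downstream check the
tag so the chain cannot be applied out of order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Columns every sample-metadata table must carry.
META_COLUMNS = ["species", "age_label", "age_order", "platform", "replicate_group"]

#: Allowed values of the ``scale`` tag, in pipeline order.
SCALES = ("raw", "log", "log_centered")

#: Allowed values of the ``platform`` metadata column.
PLATFORMS = ("count", "intensity")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier (unique, upper case by
        convention) with one column per sample.
    meta
        DataFrame indexed by sample_id, same order as ``values.columns``,
        with at least :data:`META_COLUMNS`.
    scale
        One of :data:`SCALES`.
    species_tag
        Species name, or ``"combined"`` for an ortholog-joined matrix.
        Defaults to the single species in ``meta`` when unambiguous.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "raw"
    species_tag: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dups}")
        if list(self.values.columns) != list(self.meta.index):
            raise DataError("sample columns of values and index of meta must match in order")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise DataError(f"sample metadata missing required columns: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                "non-finite expression value at gene "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        bad = set(self.meta["platform"]) - set(PLATFORMS)
        if bad:
            raise DataError(f"unknown platform value(s) {sorted(bad)}; expected {PLATFORMS}")
        if self.species_tag is None:
            species = self.meta["species"].unique()
            self.species_tag = species[0] if len(species) == 1 else "combined"

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def species_list(self) -> list[str]:
        """Species present, in order of first appearance."""
        return list(dict.fromkeys(self.meta["species"]))

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Copy carrying new values (same samples) and optionally a new scale."""
        return ExpressionMatrix(
            values=values,
            meta=self.meta.copy(),
            scale=self.scale if scale is None else scale,
            species_tag=self.species_tag,
        )

    def subset_species(self, species: str) -> "ExpressionMatrix":
        mask = self.meta["species"] == species
        if not mask.any():
            raise DataError(f"no samples for species {species!r}")
        return ExpressionMatrix(
            values=self.values.loc[:, mask.to_numpy()],
            meta=self.meta.loc[mask].copy(),
            scale=self.scale,
            species_tag=species,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:5]}")
        return replace(self, values=self.values.loc[list(genes)], meta=self.meta.copy())

    def sample_groups(self, key: str = "replicate_group") -> dict[str, list[str]]:
        """Sample ids grouped by a metadata column, groups in first-appearance order."""
        if key not in self.meta.columns:
            raise DataError(f"metadata column {key!r} not present")
        groups: dict[str, list[str]] = {}
        for sid, g in self.meta[key].items():
            groups.setdefault(str(g), []).append(sid)
        return groups


@dataclass
class OrthologMap:
    """One-to-one gene identifier pairs between species A and species B."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise DataError("ortholog map is not one-to-one; use OrthologMap.one_to_one")

    @staticmethod
    def one_to_one(pairs: list[tuple[str, str]]) -> "OrthologMap":
        """Build a map dropping every pair whose gene appears in more than
        one candidate pair (on either side)."""
        a_counts: dict[str, int] = {}
        b_counts: dict[str, int] = {}
        for a, b in pairs:
            a_counts[a] = a_counts.get(a, 0) + 1
            b_counts[b] = b_counts.get(b, 0) + 1
        kept = [(a, b) for a, b in pairs if a_counts[a] == 1 and b_counts[b] == 1]
        return OrthologMap(pairs=kept)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes_a(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def genes_b(self) -> list[str]:
        return [b for _, b in self.pairs]
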