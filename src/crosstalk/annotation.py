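"""Gene -> GO-term annotation table (two-column, GAF-like dialect)."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd


class GeneTermAnnotation:
    """Immutable mapping from gene to a set of GO terms.

    Stored and serialized as a two-column table with one (gene, term) row
    per association.
    """

    def __init__(self, gene_to_terms: Mapping[str, Iterable[str]]):
        self._map = {str(g): frozenset(map(str, ts)) for g, ts in gene_to_terms.items()}

    @property
    def genes(self) -> list[str]:
        return sorted(self._map)

    @property
    def terms(self) -> list[str]:
        return sorted({t for ts in self._map.values() for t in ts})

    def terms_for(self, gene: str) -> frozenset[str]:
        """Terms annotating ``gene``; empty set for unknown genes."""
        return self._map.get(str(gene), frozenset())

    def genes_for(self, term: str, universe: Iterable[str] | None = None) -> frozenset[str]:
        pool = self._map.keys() if universe is None else [str(g) for g in universe]
        return frozenset(g for g in pool if term in self._map.get(g, frozenset()))

    def __contains__(self, gene: str) -> bool:
        return str(gene) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneTermAnnotation) and self._map == other._map

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, t) for g in sorted(self._map) for t in sorted(self._map[g])]
        return pd.DataFrame(rows, columns=["gene", "term"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneTermAnnotation":
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(df["gene"], df["term"]):
            mapping.setdefault(str(gene), set()).add(str(term))
        return cls(mapping)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneTermAnnotation":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
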