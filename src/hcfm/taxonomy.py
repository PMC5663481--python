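"""The 4-level taxo-morphological category hierarchy.

Categories are organized as a fixed-depth tree: level 1 is the coarsest
grouping (e.g. a phylum/class-like bin or a particle type), level 4 the
finest taxo-morphological category (often genus level for organisms).
A leaf is identified by its level-4 name and must be reachable by exactly
one parent path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

N_LEVELS = 4


@dataclass
class TaxonomyTree:
    """Four-level hierarchy mapping each leaf to its ancestor path."""

    paths: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)

    @classmethod
    def from_paths(cls, rows: Iterable[Sequence[str]]) -> "TaxonomyTree":
        paths: dict[str, tuple[str, str, str, str]] = {}
        for row in rows:
            row = tuple(str(x) for x in row)
            if len(row) != N_LEVELS:
                raise ValueError(f"taxonomy path must have {N_LEVELS} levels: {row}")
            leaf = row[-1]
            if leaf in paths and paths[leaf] != row:
                raise ValueError(
                    f"leaf {leaf!r} reachable by two distinct parent paths: "
                    f"{paths[leaf][:3]} and {row[:3]}"
                )
            paths[leaf] = row
        return cls(paths)

    # -- structure -------------------------------------------------------
    @property
    def leaves(self) -> list[str]:
        return sorted(self.paths)

    def nodes_at_level(self, level: int) -> set[str]:
        """Distinct node names at a 1-based level."""
        self._check_level(level)
        return {p[level - 1] for p in self.paths.values()}

    def ancestor(self, leaf: str, level: int) -> str:
        """The level-``level`` ancestor (level 4 is the leaf itself)."""
        self._check_level(level)
        if leaf not in self.paths:
            raise KeyError(f"unknown leaf {leaf!r}")
        return self.paths[leaf][level - 1]

    def contains_path(self, path: Sequence[str]) -> bool:
        path = tuple(str(x) for x in path)
        return self.paths.get(path[-1]) == path

    @staticmethod
    def _check_level(level: int) -> None:
        if not 1 <= level <= N_LEVELS:
            raise ValueError(f"level must be in 1..{N_LEVELS}")

    # -- I/O ---------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.paths.values()),
            columns=[f"level{i}" for i in range(1, N_LEVELS + 1)],
        )
        df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read a 4-column TSV of category paths into a TaxonomyTree."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != N_LEVELS:
        raise ValueError(f"taxonomy file must have {N_LEVELS} columns, got {df.shape[1]}")
    return TaxonomyTree.from_paths(df.itertuples(index=False, name=None))
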