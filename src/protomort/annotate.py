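"""Functional classification of screened proteins and network-edge export.

Proteins are assigned to one of seven broad plasma-biology categories
(lipid metabolism, hemostasis, inflammatory mediators / cytokines, the
complement system, adaptive immunity, other immune-related pathways,
and "orphans" for everything else) from a mapping table shipped with
the package. A protein absent from the map falls back to orphan with a
warning. A simple tab-separated node-pair export is provided so the
screened set can be rendered by an external network tool; proteins that
never occur in the supplied edge source are written as singleton nodes.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .screen import DapRecord

CATEGORIES = (
    "lipid-metabolism",
    "hemostasis",
    "cytokine",
    "complement",
    "adaptive-immunity",
    "other-immune",
    "orphan",
)

ORPHAN = "orphan"


class FunctionalMap:
    """protein id -> functional category, loaded from a two/three-column TSV."""

    def __init__(self, mapping: dict[str, str]):
        bad = {p: c for p, c in mapping.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories in map: {bad}")
        self._map = dict(mapping)

    @classmethod
    def from_tsv(cls, path) -> "FunctionalMap":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["protein"], df["category"])))

    @classmethod
    def packaged(cls) -> "FunctionalMap":
        """Default map covering the plasma proteins of interest."""
        ref = resources.files("protomort.data") / "functional_map.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def category(self, protein: str) -> str:
        """Look up a protein; platform tags (``NAME:lcms``) are stripped."""
        base = protein.split(":")[0]
        if base in self._map:
            return self._map[base]
        if protein in self._map:
            return self._map[protein]
        warnings.warn(f"protein {protein!r} not in functional map; "
                      "assigned to 'orphan'", stacklevel=2)
        return ORPHAN

    def __contains__(self, protein: str) -> bool:
        return protein.split(":")[0] in self._map or protein in self._map

    def __len__(self) -> int:
        return len(self._map)


def annotate_daps(daps: list[DapRecord],
                  fmap: FunctionalMap | None = None) -> list[DapRecord]:
    """Attach a functional category to each record (in place) and return it."""
    if fmap is None:
        fmap = FunctionalMap.packaged()
    for rec in daps:
        rec.functional_group = fmap.category(rec.protein)
    return daps


def category_counts(daps: list[DapRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in daps:
        key = rec.functional_group or ORPHAN
        counts[key] = counts.get(key, 0) + 1
    return counts


def export_edges(daps: list[DapRecord], path: str | Path,
                 edges: list[tuple[str, str, float]] | None = None,
                 fmap: FunctionalMap | None = None,
                 min_score: float = 0.4) -> pd.DataFrame:
    """Write a node-pair TSV for external network visualization.

    ``edges`` is an optional precomputed (node1, node2, score) list; pairs
    under ``min_score`` are dropped. Screened proteins that appear in no
    edge are emitted as singleton rows (node2 empty) so every node is
    present in the file.
    """
    if fmap is None:
        fmap = FunctionalMap.packaged()
    nodes = [r.protein for r in daps]
    cat = {n: (fmap.category(n) if n in fmap else (r.functional_group or ORPHAN))
           for n, r in zip(nodes, daps)}
    rows = []
    connected: set[str] = set()
    for n1, n2, score in edges or []:
        if score < min_score:
            continue
        rows.append({"node1": n1, "node2": n2, "score": score,
                     "category1": cat.get(n1, fmap.category(n1)),
                     "category2": cat.get(n2, fmap.category(n2))})
        connected.update((n1, n2))
    for n in nodes:
        if n not in connected:
            rows.append({"node1": n, "node2": "", "score": "",
                         "category1": cat[n], "category2": ""})
    df = pd.DataFrame(rows, columns=["node1", "node2", "score",
                                     "category1", "category2"])
    df.to_csv(path, sep="\t", index=False)
    return df
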