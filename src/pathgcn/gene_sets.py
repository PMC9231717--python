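"""Gene-set collections and GMT (Broad dialect) I/O.

A gene-set collection maps pathway identifiers to ordered lists of gene
symbols.  Pathways may overlap: the same gene symbol can belong to many
sets, and downstream graph construction treats each (pathway, gene) pair
as a distinct node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """Raised when a GMT file is malformed."""


@dataclass
class GeneSetCollection:
    """Ordered mapping ``pathway_id -> gene symbols``.

    Parameters
    ----------
    sets : dict of str -> list of str
        Insertion-ordered mapping from pathway identifier to its member
        gene symbols.  Symbols are unique within a set; a gene may appear
        in several sets.
    source_name : str
        Provenance label (e.g. the GMT file name).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    source_name: str = ""

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {pid!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, pathway_id: str) -> list[str]:
        return self.sets[pathway_id]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def gene_universe(self) -> list[str]:
        """Union of all member genes in first-appearance order."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Genes are de-duplicated within a set, keeping first occurrence.
    Duplicate pathway ids raise; a line with fewer than three fields
    raises with the offending line number.  An empty file yields an
    empty collection with a logged warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid = fields[0]
            if pid in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: set {pid!r} lists no genes")
            sets[pid] = genes
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(sets=sets, source_name=path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    """Write a collection back to GMT, one set per line in collection order."""
    path = Path(path)
    descriptions = descriptions or {}
    with path.open("w") as fh:
        for pid, genes in collection.sets.items():
            desc = descriptions.get(pid, "na")
            fh.write("\t".join([pid, desc, *genes]) + "\n")
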