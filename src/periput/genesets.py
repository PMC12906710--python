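"""Gene-set containers and GMT I/O.

The package ships two built-in collections:

* the putrescine-metabolism sets (biosynthesis, loss, transport) used for
  the S_In / S_Loss / S_Trans enrichment scores, and
* a panel of ten T-cell functional signatures (cytotoxicity, exhaustion,
  tissue residency, ...) with *synthetic placeholder memberships*.  The
  functional panel defines the interface only; for real analyses users
  should substitute their own curated lists via :func:`parse_gmt`.

Gene symbols are uppercased once at construction so that human (CXCR6)
and mouse (Cxcr6) style symbols match the same set member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {"put_biosynthesis", "put_loss", "put_transport", "t_function", "pathway", "other"}
)


def _normalize_symbols(genes: Iterable[str]) -> tuple[str, ...]:
    return tuple(str(g).strip().upper() for g in genes)


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        genes = _normalize_symbols(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"gene set {self.name!r} has duplicate symbols: {dupes}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...]
    universe: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        names = [s.name for s in sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in collection: {dupes}")
        object.__setattr__(self, "sets", sets)
        if self.universe is not None:
            universe = _normalize_symbols(self.universe)
            object.__setattr__(self, "universe", universe)
            uni = set(universe)
            for s in sets:
                missing = [g for g in s.genes if g not in uni]
                if missing:
                    raise ValueError(
                        f"set {s.name!r} has members outside the universe: {missing}"
                    )

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(tuple(self[n] for n in names), universe=self.universe)


#: Putrescine biosynthesis enzymes: ornithine decarboxylase, agmatinase,
#: and the polyamine-oxidase route back to putrescine.
PUT_BIOSYNTHESIS = ("ODC1", "AGMAT", "PAOX")
#: Routes by which free putrescine is consumed or its synthesis suppressed:
#: spermidine synthase, the three ODC antizymes, and NQO1.
PUT_LOSS = ("SRM", "OAZ1", "OAZ2", "OAZ3", "NQO1")
#: Polyamine import/export: organic-cation solute carriers, CAT-1,
#: P5B-type ATPases, and glypican-1.
PUT_TRANSPORT = ("SLC22A1", "SLC22A2", "SLC22A3", "SLC7A1", "ATP13A2", "ATP13A3", "GPC1")


def builtin_put_genesets() -> GeneSetCollection:
    """The three putrescine-metabolism gene sets (biosynthesis/loss/transport)."""
    return GeneSetCollection(
        (
            GeneSet("put_biosynthesis", PUT_BIOSYNTHESIS, "put_biosynthesis"),
            GeneSet("put_loss", PUT_LOSS, "put_loss"),
            GeneSet("put_transport", PUT_TRANSPORT, "put_transport"),
        )
    )


# Placeholder memberships for the ten T-cell functional features.  The
# feature names follow the surveillance framework (cytotoxicity,
# inflammation promotion, chemokines/cytokines and their receptors,
# parainflammation, co-stimulation, co-inhibition, exhaustion, impaired
# persistence, tissue residency); the memberships are plausible synthetic
# stand-ins, not a curated signature.
T_FUNCTIONAL_SETS: dict[str, tuple[str, ...]] = {
    "t_cytotoxicity": ("GZMA", "GZMB", "GZMH", "GZMK", "PRF1", "GNLY", "NKG7", "KLRK1"),
    "t_inflammation_promotion": ("IL1B", "IL6", "CXCL8", "CCL3", "IL18", "PTGS2", "NLRP3", "S100A9"),
    "t_chemokine_cytokine": ("CCL5", "CCL4", "XCL1", "XCL2", "IFNG", "IL2", "TNF", "FLT3LG"),
    "t_chemokine_cytokine_receptor": ("CCR5", "CXCR3", "CXCR4", "CCR7", "IL2RB", "IL7R", "IL15RA", "IL12RB2"),
    "t_parainflammation": ("ICAM1", "PLAUR", "ANXA1", "TIMP1", "CD55", "LGALS3", "SERPINB1", "S100A8"),
    "t_co_stimulation": ("CD28", "ICOS", "TNFRSF9", "TNFRSF4", "TNFRSF18", "CD27", "CD40LG", "SLAMF1"),
    "t_co_inhibition": ("CTLA4", "BTLA", "CD160", "LAIR1", "VSIR", "TIGIT", "CD274", "PDCD1LG2"),
    "t_exhaustion": ("PDCD1", "HAVCR2", "LAG3", "TOX", "ENTPD1", "BATF", "EOMES", "CD38"),
    "t_impaired_persistence": ("BAX", "FAS", "CASP3", "CASP8", "BID", "TP53", "CDKN1A", "ANXA5"),
    "t_tissue_residency": ("CD69", "ITGAE", "ITGA1", "ZNF683", "RGS1", "CRTAM", "RBPJ", "DUSP6"),
}


def builtin_tcell_genesets() -> GeneSetCollection:
    """Ten T-cell functional signatures with synthetic placeholder members.

    Replace with curated lists (via :func:`parse_gmt`) for real data.
    """
    return GeneSetCollection(
        tuple(GeneSet(name, genes, "t_function") for name, genes in T_FUNCTIONAL_SETS.items())
    )


def parse_gmt(path: str | Path, category: str = "other") -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, genes...).

    Duplicate symbols within a line are dropped keeping the first
    occurrence; the description field is discarded.  Raises
    ``ValueError`` on lines with fewer than three fields or on duplicate
    set names.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            genes: list[str] = []
            for g in _normalize_symbols(fields[2:]):
                if g and g not in genes:
                    genes.append(g)
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, tuple(genes), category))
    return GeneSetCollection(tuple(sets))


def write_gmt(coll: GeneSetCollection, path: str | Path, description: str = "na") -> Path:
    """Write a collection to GMT (one line per set; constant description)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")
    return path


def restrict_to_universe(coll: GeneSetCollection, genes: Sequence[str]) -> GeneSetCollection:
    """Intersect every set with ``genes``, preserving member order.

    Sets emptied by the intersection are dropped with a warning; if every
    set empties, a ``ValueError`` is raised.
    """
    if len(genes) == 0:
        raise ValueError("universe must be non-empty")
    universe = _normalize_symbols(genes)
    uni = set(universe)
    kept: list[GeneSet] = []
    for s in coll:
        members = tuple(g for g in s.genes if g in uni)
        if not members:
            logger.warning("gene set %r has no members in the universe; dropped", s.name)
            continue
        kept.append(replace(s, genes=members))
    if not kept:
        raise ValueError("all gene sets were emptied by the universe restriction")
    return GeneSetCollection(tuple(kept), universe=universe)


def packaged_gmt_path(name: str) -> Path:
    """Path of a GMT file bundled with the package (``putrescine_metabolism``
    or ``t_cell_function_synthetic``)."""
    ref = resources.files("periput").joinpath("data", f"{name}.gmt")
    return Path(str(ref))
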