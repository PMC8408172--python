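"""On-disk formats and in-memory containers.

Genotypes use the "A B C -" allele dialect common to SNP-array exports for
outbreeding crops: ``A``/``B`` are the two array alleles, ``C`` is a null
allele (no hybridisation signal; a genuine third allele that matches only
itself) and ``-`` is missing data.  Internally alleles are small ints:
``A=0, B=1, C=2, missing=-1``.

All genetic coordinates are centiMorgans on a genetic map; intervals are
closed ``[start_cM, end_cM]`` and lengths are ``end - start`` (a single
marker spans 0 cM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
ALLELE_CODES = {"A": 0, "B": 1, "C": 2, "-": MISSING}
CODE_ALLELES = {v: k for k, v in ALLELE_CODES.items()}

__all__ = [
    "MISSING",
    "ALLELE_CODES",
    "CODE_ALLELES",
    "GeneticMap",
    "GenotypeMatrix",
    "HaplotypeSet",
    "Pedigree",
    "RelationshipCatalog",
    "SharedSegment",
    "read_genetic_map",
    "read_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_catalog",
    "write_catalog",
    "write_genotypes",
    "write_segments",
    "read_segments",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with chromosome assignment and cM position.

    Markers are stored in map order: chromosomes in order of first
    appearance, positions non-decreasing within each chromosome.  The map is
    the coordinate system for every length this package reports.
    """

    markers: tuple[str, ...]
    chromosome: tuple[str, ...]
    position: np.ndarray  # float cM, aligned with markers

    def __post_init__(self):
        if len(self.markers) != len(self.chromosome) or len(self.markers) != len(self.position):
            raise ValueError("markers, chromosome and position must be aligned")
        if len(set(self.markers)) != len(self.markers):
            raise FormatError("duplicate marker ids in genetic map")
        if np.any(self.position < 0):
            raise FormatError("negative cM positions in genetic map")
        for lo, hi in self.chrom_slices().values():
            if np.any(np.diff(self.position[lo:hi]) < 0):
                raise FormatError("positions must be non-decreasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c)
        return list(seen)

    def chrom_slices(self) -> dict[str, tuple[int, int]]:
        """Half-open index range of each chromosome in map order."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        for i in range(1, len(self.chromosome) + 1):
            if i == len(self.chromosome) or self.chromosome[i] != self.chromosome[start]:
                c = self.chromosome[start]
                if c in out:
                    raise FormatError(f"chromosome {c!r} appears in two separate blocks")
                out[c] = (start, i)
                start = i
        return out

    def span(self, chrom: str) -> float:
        lo, hi = self.chrom_slices()[chrom]
        return float(self.position[hi - 1] - self.position[lo])

    @property
    def total_span(self) -> float:
        return float(sum(self.span(c) for c in self.chromosomes))

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.markers)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        df = df.copy()
        df.columns = ["marker", "chromosome", "position"][: len(df.columns)]
        df["position"] = df["position"].astype(float)
        # preserve chromosome first-appearance order; stable-sort positions within
        order = {c: i for i, c in enumerate(dict.fromkeys(df["chromosome"]))}
        unsorted = (
            df.groupby("chromosome", sort=False)["position"].apply(lambda s: bool((s.diff().dropna() < 0).any())).any()
        )
        if unsorted:
            logger.warning("genetic map positions not sorted within chromosome; sorting")
        df = df.sort_values(
            by=["chromosome", "position"],
            key=lambda s: s.map(order) if s.name == "chromosome" else s,
            kind="stable",
        )
        return cls(
            markers=tuple(df["marker"].astype(str)),
            chromosome=tuple(df["chromosome"].astype(str)),
            position=df["position"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.markers, "chromosome": self.chromosome, "position": self.position}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    """Read a 3-column TSV (marker, chromosome, position_cM); header optional."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse genetic map {path}: {exc}") from exc
    if df.shape[1] != 3:
        raise FormatError(f"genetic map {path} must have 3 columns, found {df.shape[1]}")
    # headerless detection: first row parses as a position number
    try:
        float(df.columns[2])
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except ValueError:
        pass
    df.columns = ["marker", "chromosome", "position"]
    try:
        df["position"] = df["position"].astype(float)
    except ValueError as exc:
        bad = df[pd.to_numeric(df["position"], errors="coerce").isna()].index[0]
        raise FormatError(f"genetic map {path}: non-numeric position at data line {bad + 1}") from exc
    return GeneticMap.from_frame(df)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _encode_allele(sym: str, where: str) -> int:
    try:
        return ALLELE_CODES[sym]
    except KeyError:
        raise FormatError(f"invalid allele symbol {sym!r} at {where}; expected A, B, C or -") from None


@dataclass
class GenotypeMatrix:
    """Unphased two-allele calls per individual x marker, bound to a map.

    ``calls`` has shape (n_individuals, n_markers, 2); the allele pair is
    unordered.  ``C`` (null allele) is an ordinary third allele for matching.
    """

    map: GeneticMap
    individuals: list[str]
    calls: np.ndarray  # int8 (n_ind, n_markers, 2)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), self.map.n_markers, 2):
            raise ValueError("calls shape does not match individuals x markers x 2")
        if self.calls.size and (self.calls.min() < MISSING or self.calls.max() > 2):
            raise FormatError("allele codes outside {A,B,C,-}")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            raise FormatError("duplicate individual ids")

    def __contains__(self, ind: str) -> bool:
        return ind in self._index

    def get(self, ind: str) -> np.ndarray:
        """(n_markers, 2) allele-code view for one individual."""
        return self.calls[self._index[ind]]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list[str]] = {"marker": list(self.map.markers)}
        for i, ind in enumerate(self.individuals):
            cols[f"{ind}"] = [CODE_ALLELES[int(a)] for a in self.calls[i, :, 0]]
            cols[f"{ind}.1"] = [CODE_ALLELES[int(a)] for a in self.calls[i, :, 1]]
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeSet:
    """Phased homolog pair per individual.

    ``haplotypes`` has shape (n_ind, 2, n_markers); axis 1 is homolog-1 /
    homolog-2.  A phased homolog can be viewed as a "doubled" genotype
    (allele ``a`` becomes genotype ``aa``) so the unphased matching
    machinery applies unchanged.
    """

    map: GeneticMap
    individuals: list[str]
    haplotypes: np.ndarray  # int8 (n_ind, 2, n_markers)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.individuals), 2, self.map.n_markers):
            raise ValueError("haplotypes shape does not match individuals x 2 x markers")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    def __contains__(self, ind: str) -> bool:
        return ind in self._index

    def homolog(self, ind: str, hom: int) -> np.ndarray:
        """(n_markers,) allele vector for homolog ``hom`` in {0, 1}."""
        return self.haplotypes[self._index[ind], hom]

    def doubled(self, ind: str, hom: int) -> np.ndarray:
        """Homolog as a doubled genotype: allele a -> {a, a}."""
        h = self.homolog(ind, hom)
        return np.stack([h, h], axis=1)

    def genotype(self, ind: str) -> np.ndarray:
        """Collapse the two homologs into an unphased (n_markers, 2) genotype."""
        return self.haplotypes[self._index[ind]].T.copy()

    def as_genotype_matrix(self) -> GenotypeMatrix:
        calls = np.transpose(self.haplotypes, (0, 2, 1)).copy()
        return GenotypeMatrix(self.map, list(self.individuals), calls)

    def to_tsv(self, path) -> None:
        self.as_genotype_matrix().to_tsv(path)


def read_genotypes(path, gmap: GeneticMap, phased: bool = False):
    """Read an "A B C -" genotype table.

    Layout: markers as rows; two tab-separated allele columns per individual;
    the header row carries individual ids (the second column of a pair may
    repeat the id or carry any suffix).  With ``phased=True`` the two columns
    are homolog-1 / homolog-2 and a :class:`HaplotypeSet` is returned.
    Markers absent from the map are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    if (df.shape[1] - 1) % 2 != 0:
        raise FormatError(f"{path}: expected marker column + 2 columns per individual")
    inds = [str(c) for c in df.columns[1::2]]
    midx = gmap.marker_index()
    rows = df.iloc[:, 0].astype(str)
    keep = rows.isin(midx)
    if not keep.all():
        dropped = (~keep).sum()
        logger.warning("%d markers in %s absent from the map; dropped", dropped, path)
    df = df[keep.to_numpy()]
    rows = df.iloc[:, 0].astype(str)
    n_ind = len(inds)
    calls = np.full((n_ind, gmap.n_markers, 2), MISSING, dtype=np.int8)
    target = np.fromiter((midx[m] for m in rows), dtype=np.int64, count=len(rows))
    for j in range(n_ind):
        for k in (0, 1):
            col = df.iloc[:, 1 + 2 * j + k].astype(str).str.strip()
            codes = np.fromiter(
                (_encode_allele(s, f"{path} individual {inds[j]}") for s in col),
                dtype=np.int8,
                count=len(col),
            )
            calls[j, target, k] = codes
    for j, ind in enumerate(inds):
        if np.all(calls[j] == MISSING):
            warnings.warn(f"individual {ind!r} has all-missing data", stacklevel=2)
    if phased:
        haps = np.transpose(calls, (0, 2, 1)).copy()
        return HaplotypeSet(gmap, inds, haps)
    return GenotypeMatrix(gmap, inds, calls)


def read_genotypes_long(path, gmap: GeneticMap, phased: bool = False):
    """Convenience reader for long-format tables (marker, individual,
    allele1, allele2); converts to the wide layout and delegates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: long format needs marker, individual, allele1, allele2")
    df.columns = ["marker", "individual", "a1", "a2"][: df.shape[1]]
    wide = df.pivot(index="marker", columns="individual", values=["a1", "a2"])
    import io

    buf = io.StringIO()
    inds = list(wide["a1"].columns)
    buf.write("marker\t" + "\t".join(f"{i}\t{i}.1" for i in inds) + "\n")
    for marker, row in wide.iterrows():
        cells = [str(marker)]
        for i in inds:
            cells += [str(row[("a1", i)]), str(row[("a2", i)])]
        buf.write("\t".join(cells) + "\n")
    buf.seek(0)
    return read_genotypes(buf, gmap, phased=phased)


def write_genotypes(data, path) -> None:
    data.to_tsv(path)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """individual -> (parent1 | None, parent2 | None); acyclic ancestry."""

    records: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self):
        # every parent mentioned gets a record so traversal never KeyErrors
        for p1, p2 in list(self.records.values()):
            for p in (p1, p2):
                if p is not None and p not in self.records:
                    self.records[p] = (None, None)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pedigree contains a cycle (an individual is its own ancestor)")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.records)
        for child, (p1, p2) in self.records.items():
            for p in (p1, p2):
                if p is not None:
                    g.add_edge(p, child)
        return g

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.records.get(ind, (None, None))

    def __contains__(self, ind: str) -> bool:
        return ind in self.records


def read_pedigree(path) -> Pedigree:
    """CSV (individual, parent1, parent2); empty cell = unknown parent."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: pedigree needs 3 columns (individual, parent1, parent2)")
    recs: dict[str, tuple[str | None, str | None]] = {}
    for _, row in df.iterrows():
        ind = str(row.iloc[0])
        p1 = row.iloc[1] if pd.notna(row.iloc[1]) and str(row.iloc[1]).strip() else None
        p2 = row.iloc[2] if pd.notna(row.iloc[2]) and str(row.iloc[2]).strip() else None
        recs[ind] = (None if p1 is None else str(p1), None if p2 is None else str(p2))
    return Pedigree(recs)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        [(i, p1 or "", p2 or "") for i, (p1, p2) in ped.records.items()],
        columns=["individual", "parent1", "parent2"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Relationship catalog
# ---------------------------------------------------------------------------

RELATIONSHIP_LABELS = ("FSIB", "HSIB", "GPGC", "HAAM", "OSGP", "NKCR")


@dataclass
class RelationshipCatalog:
    """Labelled pairs (id_a, id_b, label); labels are symmetric in the pair."""

    pairs: pd.DataFrame  # columns id_a, id_b, label

    def __post_init__(self):
        self.pairs = self.pairs.reset_index(drop=True)
        bad = set(self.pairs["label"]) - set(RELATIONSHIP_LABELS)
        if bad:
            raise FormatError(f"unknown relationship labels: {sorted(bad)}")

    def by_label(self, label: str) -> list[tuple[str, str]]:
        sub = self.pairs[self.pairs["label"] == label]
        return list(zip(sub["id_a"], sub["id_b"]))

    @property
    def labels(self) -> list[str]:
        return [l for l in RELATIONSHIP_LABELS if (self.pairs["label"] == l).any()]


def read_catalog(path) -> RelationshipCatalog:
    df = pd.read_csv(path, dtype=str)
    df.columns = ["id_a", "id_b", "label"][: len(df.columns)]
    return RelationshipCatalog(df)


def write_catalog(cat: RelationshipCatalog, path) -> None:
    cat.pairs.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Shared segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SharedSegment:
    """A maximal IBS interval for a pair, bounded by matching markers."""

    id_a: str
    id_b: str
    chromosome: str
    start_cM: float
    end_cM: float
    start_marker: str
    end_marker: str
    segment_class: str = "IBS"  # e.g. IBS / DOUBLE / SINGLE / ROH
    hom_a: int | None = None
    hom_b: int | None = None

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


SEGMENT_COLUMNS = [
    "pair_a",
    "pair_b",
    "chromosome",
    "start_cM",
    "end_cM",
    "length_cM",
    "start_marker",
    "end_marker",
    "class",
]


def segments_to_frame(segments: Iterable[SharedSegment]) -> pd.DataFrame:
    rows = [
        (s.id_a, s.id_b, s.chromosome, s.start_cM, s.end_cM, s.length_cM, s.start_marker, s.end_marker, s.segment_class)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments(segments: Sequence[SharedSegment], path) -> None:
    """BED-like TSV; one row per segment, header included."""
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SharedSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_a": str, "pair_b": str, "chromosome": str})
    out = []
    for _, r in df.iterrows():
        out.append(
            SharedSegment(
                id_a=str(r["pair_a"]),
                id_b=str(r["pair_b"]),
                chromosome=str(r["chromosome"]),
                start_cM=float(r["start_cM"]),
                end_cM=float(r["end_cM"]),
                start_marker=str(r["start_marker"]),
                end_marker=str(r["end_marker"]),
                segment_class=str(r["class"]),
            )
        )
    return out
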