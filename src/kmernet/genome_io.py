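"""Genome, annotation and taxonomy input, and construction of genome views.

A microbial isolate is represented by its sequence components (chromosomes
and plasmids), its gene features (CDS / rRNA, with optional COG category
letters), and a taxonomy assignment.  Four *views* of an isolate's sequence
are analysed downstream:

``whole``
    every component verbatim (chromosomes plus plasmids);
``no_rrna``
    all components with every annotated rRNA interval excised — flanking
    segments are kept separate so no artificial junction k-mers arise;
``rrna_only``
    the annotated rRNA subsequences themselves;
``plasmid_only``
    plasmid components only.

Coordinates are 0-based half-open internally; GFF3 1-based inclusive
coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import AnnotationMissing, FastaParseError, TaxonomyError

MODES = ("whole", "no_rrna", "rrna_only", "plasmid_only")


@dataclass(frozen=True)
class SequenceComponent:
    """One replicon of an isolate (a chromosome or a plasmid)."""

    component_id: str
    role: str  # "chromosome" | "plasmid"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"component {self.component_id!r} has an empty sequence")
        if self.role not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown role {self.role!r} for {self.component_id!r}")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on a component; coordinates 0-based half-open."""

    component_id: str
    start: int
    end: int
    strand: str
    ftype: str  # "CDS" | "rRNA" | "other"
    cog_categories: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.component_id!r}"
            )


@dataclass(frozen=True)
class Taxonomy:
    genus: str
    species: str
    phylum: str
    proteo_class: str = ""

    @property
    def effective_phylum(self) -> str:
        """Phylum label, with Proteobacteria split into its classes."""
        if self.phylum == "Proteobacteria" and self.proteo_class:
            return self.proteo_class
        return self.phylum


@dataclass
class GenomeRecord:
    """An isolate: sequence components, gene features, taxonomy."""

    isolate_id: str
    components: list[SequenceComponent]
    features: list[GeneFeature] = field(default_factory=list)
    taxonomy: Taxonomy | None = None

    def __post_init__(self) -> None:
        known = {c.component_id for c in self.components}
        if len(known) != len(self.components):
            raise FastaParseError(f"duplicate component ids in isolate {self.isolate_id!r}")
        for f in self.features:
            if f.component_id not in known:
                raise ValueError(
                    f"feature on unknown component {f.component_id!r} in {self.isolate_id!r}"
                )
            length = len(self.component(f.component_id).sequence)
            if f.end > length:
                raise ValueError(
                    f"feature [{f.start}, {f.end}) exceeds length {length} of "
                    f"{f.component_id!r}"
                )

    def component(self, component_id: str) -> SequenceComponent:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(component_id)

    @property
    def has_annotation(self) -> bool:
        return bool(self.features)


@dataclass(frozen=True)
class Segment:
    """A concrete subsequence of a component realized in a view."""

    component_id: str
    start: int
    end: int
    sequence: str


@dataclass
class GenomeView:
    isolate_id: str
    mode: str
    segments: list[Segment]

    @property
    def is_empty(self) -> bool:
        return not self.segments

    @property
    def total_length(self) -> int:
        return sum(len(s.sequence) for s in self.segments)


def read_fasta(path: str, role_map: Mapping[str, str] | None = None) -> list[SequenceComponent]:
    """Read a (multi-record) FASTA file into sequence components.

    ``role_map`` maps record ids to "chromosome" / "plasmid"; records absent
    from the map default to chromosome.  Sequences are upper-cased; record
    order is preserved; duplicate ids are an error.
    """
    role_map = dict(role_map or {})
    components: list[SequenceComponent] = []
    seen: set[str] = set()
    for record in SeqIO.parse(path, "fasta"):
        if record.id in seen:
            raise FastaParseError(f"duplicate FASTA record id {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        if not seq:
            raise FastaParseError(f"FASTA record {record.id!r} in {path} has no sequence")
        components.append(
            SequenceComponent(record.id, role_map.get(record.id, "chromosome"), seq)
        )
    return components


def read_features(path: str, cog_attribute: str = "cog") -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    CDS and rRNA rows keep their type; everything else becomes "other".
    COG single-letter categories are read per character from the attribute
    named by ``cog_attribute`` (so ``cog=EC`` yields {E, C}).  GFF3 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneFeature] = []
    for f in db.all_features(order_by=("seqid", "start")):
        ftype = f.featuretype if f.featuretype in ("CDS", "rRNA") else "other"
        letters: set[str] = set()
        for value in f.attributes.get(cog_attribute, []):
            letters.update(ch for ch in value if ch.isalpha())
        out.append(
            GeneFeature(
                component_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                ftype=ftype,
                cog_categories=frozenset(letters),
            )
        )
    return out


def read_roles(path: str) -> dict[str, str]:
    """Read a two-column TSV (component_id, role) into a role map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["component_id"], df["role"]))


def read_taxonomy(path: str) -> dict[str, Taxonomy]:
    """Read a headered TSV: isolate_id, genus, species, phylum, class.

    The class column is used only to split Proteobacteria into classes.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"isolate_id", "genus", "species", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"taxonomy table {path} lacks columns: {sorted(missing)}")
    out: dict[str, Taxonomy] = {}
    for row in df.to_dict("records"):
        iid = row["isolate_id"]
        if iid in out:
            raise TaxonomyError(f"duplicate isolate_id {iid!r} in {path}")
        out[iid] = Taxonomy(
            genus=row["genus"],
            species=row["species"],
            phylum=row["phylum"],
            proteo_class=row.get("class", ""),
        )
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def complement_intervals(intervals: Sequence[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Half-open complement of merged ``intervals`` within [0, length)."""
    out: list[tuple[int, int]] = []
    cursor = 0
    for start, end in intervals:
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < length:
        out.append((cursor, length))
    return out


def make_view(
    genome: GenomeRecord,
    mode: str,
    *,
    chromosomes_only: bool = False,
) -> GenomeView:
    """Build one of the four analysis views of a genome.

    Overlapping rRNA intervals are unioned before excision, and segments
    flanking an excised interval are never re-joined, so the ``no_rrna`` and
    ``rrna_only`` views partition the sequence exactly.  rRNA genes on
    plasmids are excised like chromosomal ones.  ``chromosomes_only``
    restricts whole/no_rrna/rrna_only to chromosome components (by default
    plasmids are included, matching a "complete genome" data set).
    """
    if mode not in MODES:
        raise ValueError(f"unknown view mode {mode!r}; expected one of {MODES}")

    if mode == "plasmid_only":
        comps = [c for c in genome.components if c.role == "plasmid"]
        segments = [Segment(c.component_id, 0, len(c.sequence), c.sequence) for c in comps]
        return GenomeView(genome.isolate_id, mode, segments)

    comps = [
        c for c in genome.components
        if not (chromosomes_only and c.role == "plasmid")
    ]

    if mode == "whole":
        segments = [Segment(c.component_id, 0, len(c.sequence), c.sequence) for c in comps]
        return GenomeView(genome.isolate_id, mode, segments)

    if not genome.has_annotation:
        raise AnnotationMissing(
            f"isolate {genome.isolate_id!r} has no annotation; cannot build {mode!r} view"
        )

    rrna_by_component: dict[str, list[tuple[int, int]]] = {}
    for f in genome.features:
        if f.ftype == "rRNA":
            rrna_by_component.setdefault(f.component_id, []).append((f.start, f.end))

    segments = []
    for c in comps:
        rrna = merge_intervals(rrna_by_component.get(c.component_id, []))
        keep = rrna if mode == "rrna_only" else complement_intervals(rrna, len(c.sequence))
        for start, end in keep:
            segments.append(Segment(c.component_id, start, end, c.sequence[start:end]))
    return GenomeView(genome.isolate_id, mode, segments)
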