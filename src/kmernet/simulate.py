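"""Synthetic genome fixtures with controlled evolutionary structure.

The generator emulates the signal structure the pipeline is designed to
detect: clades of isolates diverged from clade ancestors (which themselves
diverged from a common root), an optional highly conserved block annotated
as rRNA, optional plasmids restricted to a subset of host clades and
evolving at their own rate, and optional lateral transfers that copy a
segment verbatim across clades.  Substitutions are i.i.d. per site and
always change the base, so the closed form

    E[shared ancestral k-mer windows] = (L − k + 1) (1 − rate)^k

holds exactly and every expectation used in tests can be computed by hand.
Output is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_io import (
    GeneFeature,
    GenomeRecord,
    SequenceComponent,
    Taxonomy,
    complement_intervals,
    read_fasta,
    read_features,
    read_roles,
    read_taxonomy,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: COG letters treated as informative (A..Z minus R, S and the unused Y).
INFORMATIVE_COGS = tuple(sorted(set(string.ascii_uppercase) - {"R", "S", "Y"}))


@dataclass(frozen=True)
class ConservedBlock:
    """An rRNA-like locus, near-identical across all clades."""

    length: int = 1500
    sub_rate: float = 5e-4
    position: int = 1000


@dataclass(frozen=True)
class PlasmidParams:
    """Plasmids restricted to ``host_clades``, diverging at their own rate."""

    length: int = 2000
    sub_rate: float = 0.05
    host_clades: tuple[int, ...] = (0,)


@dataclass(frozen=True)
class LgtEvent:
    """Copy ``length`` nt verbatim from a donor-clade genome into a
    recipient-clade genome (post-mutation), replacing the resident segment."""

    donor_clade: int
    recipient_clade: int
    length: int
    donor_genome: int = 0
    recipient_genome: int = 0
    position: Optional[int] = None  # default: just past the conserved block


@dataclass
class SimParams:
    """Study conditions of the synthetic clade model.

    Defaults give three clades of ten 10-kb genomes: within-clade isolates
    differ by ~0.1% of sites (near-clonal, sharing ~95% of 25-mers, S ≈ 9.3)
    while clades differ by ~16% (sharing ~1.5% of 25-mers, S ≈ 0.1, i.e.
    just inside the d = 10 edge filter) — so the similarity scale is spanned
    end to end and the clade partition is recoverable by thresholding.
    """

    seed: int = 0
    n_clades: int = 3
    genomes_per_clade: int = 10
    genome_length: int = 10_000
    within_clade_sub_rate: float = 0.001
    between_clade_sub_rate: float = 0.08
    conserved_block: Optional[ConservedBlock] = None
    plasmid: Optional[PlasmidParams] = None
    lgt_events: tuple[LgtEvent, ...] = ()
    cds_length: int = 900
    cds_gap: int = 100

    def validate(self) -> None:
        for rate in (self.within_clade_sub_rate, self.between_clade_sub_rate):
            if not (0.0 <= rate <= 0.75):
                raise ValueError(f"substitution rate {rate} outside [0, 0.75]")
        if self.n_clades < 1 or self.genomes_per_clade < 1:
            raise ValueError("need at least one clade and one genome per clade")
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        block = self.conserved_block
        if block is not None:
            if not (0.0 <= block.sub_rate <= 0.75):
                raise ValueError("conserved block rate outside [0, 0.75]")
            if block.position + block.length > self.genome_length:
                raise ValueError("conserved block does not fit in the genome")
        if self.plasmid is not None:
            if not (0.0 <= self.plasmid.sub_rate <= 0.75):
                raise ValueError("plasmid rate outside [0, 0.75]")
            for clade in self.plasmid.host_clades:
                if not (0 <= clade < self.n_clades):
                    raise ValueError(f"plasmid host clade {clade} out of range")
        for ev in self.lgt_events:
            if not (0 <= ev.donor_clade < self.n_clades):
                raise ValueError(f"LGT donor clade {ev.donor_clade} out of range")
            if not (0 <= ev.recipient_clade < self.n_clades):
                raise ValueError(f"LGT recipient clade {ev.recipient_clade} out of range")
            if ev.length >= self.genome_length:
                raise ValueError("LGT segment longer than the genome")


@dataclass
class SimTruth:
    """Ground truth needed to recompute expected shared-k-mer structure."""

    clade_of: dict[str, int]
    block: Optional[tuple[int, int]]
    plasmid_hosts: list[str]
    lgt: list[dict]
    root: str
    clade_ancestors: dict[int, str]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "clade_of": self.clade_of,
                    "block": list(self.block) if self.block else None,
                    "plasmid_hosts": self.plasmid_hosts,
                    "lgt": self.lgt,
                    "root": self.root,
                    "clade_ancestors": {str(k): v for k, v in self.clade_ancestors.items()},
                },
                fh,
                sort_keys=True,
            )


def default_three_clade(seed: int = 0) -> SimParams:
    """The baseline three-clade fixture (no conserved block, no plasmids)."""
    return SimParams(seed=seed)


def structured(seed: int = 0) -> SimParams:
    """Three clades plus a conserved rRNA-like block and clade-A plasmids."""
    return SimParams(seed=seed, conserved_block=ConservedBlock(), plasmid=PlasmidParams())


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(codes: np.ndarray, rates: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitutions; a hit always changes the base."""
    out = codes.copy()
    hit = rng.random(len(codes)) < rates
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def expected_shared_kmers(rate: float, length: int, k: int) -> float:
    """Expected ancestral k-mer windows surviving i.i.d. substitution."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate {rate} outside [0, 1]")
    return max(0, length - k + 1) * (1.0 - rate) ** k


def surviving_windows(ancestor: str, derived: str, k: int) -> int:
    """Number of positions whose k-window is unchanged between sequences."""
    if len(ancestor) != len(derived):
        raise ValueError("sequences must have equal length")
    same = np.frombuffer(ancestor.encode(), np.uint8) == np.frombuffer(
        derived.encode(), np.uint8
    )
    n = len(same) - k + 1
    if n <= 0:
        return 0
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        ok &= same[i : i + n]
    return int(ok.sum())


def _tile_cds(
    length: int,
    rrna: list[tuple[int, int]],
    component_id: str,
    params: SimParams,
    probs: np.ndarray,
    rng: np.random.Generator,
) -> list[GeneFeature]:
    """CDS features tiled over the non-rRNA intervals, with COG letters drawn
    from the simulation's category distribution (occasionally adding the
    noninformative R/S so their exclusion is exercised downstream)."""
    feats = []
    for start, end in complement_intervals(rrna, length):
        cursor = start
        while cursor + params.cds_length <= end:
            letters = {INFORMATIVE_COGS[rng.choice(len(INFORMATIVE_COGS), p=probs)]}
            if rng.random() < 0.15:
                letters.add(INFORMATIVE_COGS[rng.choice(len(INFORMATIVE_COGS), p=probs)])
            if rng.random() < 0.10:
                letters.add("R" if rng.random() < 0.5 else "S")
            feats.append(
                GeneFeature(
                    component_id=component_id,
                    start=cursor,
                    end=cursor + params.cds_length,
                    strand="+",
                    ftype="CDS",
                    cog_categories=frozenset(letters),
                )
            )
            cursor += params.cds_length + params.cds_gap
    return feats


def simulate(params: SimParams) -> tuple[list[GenomeRecord], SimTruth]:
    """Generate the genomes and ground truth for one parameter set."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    block = params.conserved_block

    rate_between = np.full(L, params.between_clade_sub_rate)
    rate_within = np.full(L, params.within_clade_sub_rate)
    block_interval: Optional[tuple[int, int]] = None
    if block is not None:
        block_interval = (block.position, block.position + block.length)
        rate_between[block.position : block.position + block.length] = block.sub_rate
        rate_within[block.position : block.position + block.length] = block.sub_rate

    cog_probs = rng.dirichlet(np.full(len(INFORMATIVE_COGS), 2.0))
    root = _random_codes(rng, L)
    ancestors = {c: _mutate(root, rate_between, rng) for c in range(params.n_clades)}

    plasmid_ancestor = None
    if params.plasmid is not None:
        plasmid_ancestor = _random_codes(rng, params.plasmid.length)

    letters = string.ascii_uppercase
    chrom_codes: dict[tuple[int, int], np.ndarray] = {}
    for c in range(params.n_clades):
        for i in range(params.genomes_per_clade):
            chrom_codes[(c, i)] = _mutate(ancestors[c], rate_within, rng)

    lgt_records: list[dict] = []
    for ev in params.lgt_events:
        pos = ev.position
        if pos is None:
            pos = block_interval[1] + 100 if block_interval else 100
        if pos + ev.length > L:
            raise ValueError("LGT segment exceeds the genome length at its position")
        donor = chrom_codes[(ev.donor_clade, ev.donor_genome)]
        recipient = chrom_codes[(ev.recipient_clade, ev.recipient_genome)]
        recipient[pos : pos + ev.length] = donor[pos : pos + ev.length]
        lgt_records.append(
            {
                "donor_clade": ev.donor_clade,
                "recipient_clade": ev.recipient_clade,
                "donor_genome": ev.donor_genome,
                "recipient_genome": ev.recipient_genome,
                "start": pos,
                "end": pos + ev.length,
            }
        )

    genomes: list[GenomeRecord] = []
    clade_of: dict[str, int] = {}
    plasmid_hosts: list[str] = []
    for c in range(params.n_clades):
        letter = letters[c]
        for i in range(params.genomes_per_clade):
            isolate_id = f"{letter}{i:02d}"
            clade_of[isolate_id] = c
            chrom_id = f"{isolate_id}_chr"
            components = [
                SequenceComponent(chrom_id, "chromosome", _to_str(chrom_codes[(c, i)]))
            ]
            rrna_intervals = [block_interval] if block_interval else []
            features: list[GeneFeature] = []
            if block_interval:
                features.append(
                    GeneFeature(chrom_id, block_interval[0], block_interval[1], "+", "rRNA")
                )
            features.extend(
                _tile_cds(L, list(rrna_intervals), chrom_id, params, cog_probs, rng)
            )
            if params.plasmid is not None and c in params.plasmid.host_clades:
                pl_id = f"{isolate_id}_p1"
                pl_codes = _mutate(plasmid_ancestor, params.plasmid.sub_rate, rng)
                components.append(SequenceComponent(pl_id, "plasmid", _to_str(pl_codes)))
                features.extend(
                    _tile_cds(params.plasmid.length, [], pl_id, params, cog_probs, rng)
                )
                plasmid_hosts.append(isolate_id)
            genomes.append(
                GenomeRecord(
                    isolate_id=isolate_id,
                    components=components,
                    features=features,
                    taxonomy=Taxonomy(
                        genus=f"Genus{letter}",
                        species=f"Genus{letter} sp{i + 1}",
                        phylum=f"Phylum{letter}",
                    ),
                )
            )

    truth = SimTruth(
        clade_of=clade_of,
        block=block_interval,
        plasmid_hosts=plasmid_hosts,
        lgt=lgt_records,
        root=_to_str(root),
        clade_ancestors={c: _to_str(a) for c, a in ancestors.items()},
    )
    return genomes, truth


def write_fixture(genomes: Sequence[GenomeRecord], truth: SimTruth, outdir: str) -> None:
    """Write a fixture bundle: per-isolate FASTA + GFF3, roles.tsv,
    taxonomy.tsv, truth.json — the standard-format carrier consumed by the
    genome I/O layer."""
    gdir = os.path.join(outdir, "genomes")
    adir = os.path.join(outdir, "annotations")
    os.makedirs(gdir, exist_ok=True)
    os.makedirs(adir, exist_ok=True)
    roles: list[tuple[str, str]] = []
    with open(os.path.join(outdir, "taxonomy.tsv"), "w") as tfh:
        tfh.write("isolate_id\tgenus\tspecies\tphylum\tclass\n")
        for g in genomes:
            tax = g.taxonomy
            tfh.write(
                f"{g.isolate_id}\t{tax.genus}\t{tax.species}\t{tax.phylum}\t"
                f"{tax.proteo_class}\n"
            )
            with open(os.path.join(gdir, f"{g.isolate_id}.fasta"), "w") as ffh:
                for comp in g.components:
                    ffh.write(f">{comp.component_id}\n")
                    for j in range(0, len(comp.sequence), 80):
                        ffh.write(comp.sequence[j : j + 80] + "\n")
                    roles.append((comp.component_id, comp.role))
            with open(os.path.join(adir, f"{g.isolate_id}.gff3"), "w") as afh:
                afh.write("##gff-version 3\n")
                for idx, f in enumerate(g.features):
                    attrs = f"ID={g.isolate_id}_f{idx}"
                    if f.cog_categories:
                        attrs += ";cog=" + "".join(sorted(f.cog_categories))
                    afh.write(
                        f"{f.component_id}\tkmernet_sim\t{f.ftype}\t{f.start + 1}\t"
                        f"{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                    )
    with open(os.path.join(outdir, "roles.tsv"), "w") as rfh:
        rfh.write("component_id\trole\n")
        for cid, role in roles:
            rfh.write(f"{cid}\t{role}\n")
    truth.to_json(os.path.join(outdir, "truth.json"))


def load_fixture(outdir: str) -> tuple[list[GenomeRecord], dict[str, Taxonomy]]:
    """Load a fixture bundle back through the standard readers."""
    taxonomy = read_taxonomy(os.path.join(outdir, "taxonomy.tsv"))
    roles = read_roles(os.path.join(outdir, "roles.tsv"))
    genomes = []
    for isolate_id in sorted(taxonomy):
        comps = read_fasta(os.path.join(outdir, "genomes", f"{isolate_id}.fasta"), roles)
        gff = os.path.join(outdir, "annotations", f"{isolate_id}.gff3")
        feats = read_features(gff) if os.path.exists(gff) else []
        genomes.append(
            GenomeRecord(
                isolate_id=isolate_id,
                components=comps,
                features=feats,
                taxonomy=taxonomy[isolate_id],
            )
        )
    return genomes, taxonomy
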