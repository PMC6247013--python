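"""k-mer extraction, per-view count tables, and a k-mer location index.

Words over {A,C,G,T} are packed two bits per base into uint64 (so k ≤ 31);
windows containing any other symbol are skipped entirely.  With the default
strand policy ``both`` the reverse complement of each segment is scanned as
an additional strand and counts are summed, making tables invariant to the
arbitrary assembly strand of each isolate.

The location index plays the role of a relational database of k-mers: it
maps each word to its genomic occurrences together with the gene features
overlapping each occurrence by at least one base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import EmptyViewError
from .genome_io import GeneFeature, GenomeRecord, GenomeView, make_view

STRAND_POLICIES = ("forward", "both")

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # tolerate lowercase

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """All valid k-mer codes of ``seq`` in order of position (uint64)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    words = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        window = codes[i : i + n]
        ok &= window != 255
        words = (words << np.uint64(2)) | window.astype(np.uint64)
    return words[ok]


def decode_kmer(word: int, k: int) -> str:
    letters = []
    w = int(word)
    for _ in range(k):
        letters.append(_BASES[w & 3])
        w >>= 2
    return "".join(reversed(letters))


def kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Valid k-mer codes of ``seq`` together with their 0-based offsets."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    words = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        window = codes[i : i + n]
        ok &= window != 255
        words = (words << np.uint64(2)) | window.astype(np.uint64)
    return words[ok], np.nonzero(ok)[0].astype(np.int64)


def extract_kmers(sequence: str, k: int, strand_policy: str = "forward") -> dict[str, int]:
    """Count k-mers of one sequence; returns a plain word → count mapping.

    Convenience form for small inputs and tests; bulk counting goes through
    :func:`count_view`, which keeps words in packed form.
    """
    _check_policy(strand_policy)
    parts = [encode_kmers(sequence, k)]
    if strand_policy == "both":
        parts.append(encode_kmers(revcomp(sequence), k))
    allwords = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    words, counts = np.unique(allwords, return_counts=True)
    return {decode_kmer(w, k): int(c) for w, c in zip(words, counts)}


def _check_policy(strand_policy: str) -> None:
    if strand_policy not in STRAND_POLICIES:
        raise ValueError(f"unknown strand policy {strand_policy!r}")


@dataclass
class KmerCountTable:
    """Sorted packed k-mer counts for one genome view, plus the background.

    ``total_positions`` is the number of scanned window positions (summed per
    strand when the policy is ``both``), including windows skipped for
    ambiguity; ``nt_freqs`` are the empirical A/C/G/T frequencies of the
    scanned text, i.e. the order-0 background model used by the D2S
    statistic.
    """

    isolate_id: str
    mode: str
    k: int
    strand_policy: str
    words: np.ndarray  # uint64, sorted ascending
    counts: np.ndarray  # int64, parallel to words
    total_positions: int
    nt_freqs: np.ndarray  # float64[4], sums to 1

    @property
    def n_distinct(self) -> int:
        return len(self.words)

    def to_counter(self) -> dict[str, int]:
        return {decode_kmer(w, self.k): int(c) for w, c in zip(self.words, self.counts)}

    def same_config(self, other: "KmerCountTable") -> bool:
        return (
            self.k == other.k
            and self.strand_policy == other.strand_policy
            and self.mode == other.mode
        )

    def content_key(self) -> bytes:
        """Hashable fingerprint of the k-mer content (words and counts)."""
        return self.words.tobytes() + b"|" + self.counts.tobytes()

    def write_tsv(self, path: str) -> None:
        """Two-column TSV (word, count) with a sidecar JSON header."""
        with open(path, "w") as fh:
            fh.write("word\tcount\n")
            for w, c in zip(self.words, self.counts):
                fh.write(f"{decode_kmer(w, self.k)}\t{int(c)}\n")
        header = {
            "isolate_id": self.isolate_id,
            "mode": self.mode,
            "k": self.k,
            "strand_policy": self.strand_policy,
            "total_positions": self.total_positions,
            "nt_freqs": [float(x) for x in self.nt_freqs],
        }
        with open(path + ".json", "w") as fh:
            json.dump(header, fh, sort_keys=True, indent=1)

    @classmethod
    def read_tsv(cls, path: str) -> "KmerCountTable":
        with open(path + ".json") as fh:
            header = json.load(fh)
        k = header["k"]
        words = []
        counts = []
        with open(path) as fh:
            next(fh)  # header row
            for line in fh:
                word, count = line.rstrip("\n").split("\t")
                words.append(encode_kmers(word, k)[0])
                counts.append(int(count))
        order = np.argsort(np.asarray(words, dtype=np.uint64), kind="stable")
        return cls(
            isolate_id=header["isolate_id"],
            mode=header["mode"],
            k=k,
            strand_policy=header["strand_policy"],
            words=np.asarray(words, dtype=np.uint64)[order],
            counts=np.asarray(counts, dtype=np.int64)[order],
            total_positions=header["total_positions"],
            nt_freqs=np.asarray(header["nt_freqs"], dtype=float),
        )


def count_view(view: GenomeView, k: int, strand_policy: str = "both") -> KmerCountTable:
    """Count k-mers over all segments of a view.

    Segments are counted independently, so no k-mer ever spans a join (in
    particular none spans an excised rRNA gap).
    """
    _check_policy(strand_policy)
    if view.is_empty:
        raise EmptyViewError(f"view {view.mode!r} of {view.isolate_id!r} has no sequence")

    word_parts: list[np.ndarray] = []
    base_counts = np.zeros(4, dtype=np.int64)
    total_positions = 0
    for segment in view.segments:
        texts = [segment.sequence]
        if strand_policy == "both":
            texts.append(revcomp(segment.sequence))
        for text in texts:
            word_parts.append(encode_kmers(text, k))
            codes = _CODE[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
            base_counts += np.bincount(codes[codes < 4], minlength=4)
            total_positions += max(0, len(text) - k + 1)

    allwords = np.concatenate(word_parts) if word_parts else np.empty(0, np.uint64)
    words, counts = np.unique(allwords, return_counts=True)
    scanned = base_counts.sum()
    freqs = base_counts / scanned if scanned > 0 else np.full(4, 0.25)
    return KmerCountTable(
        isolate_id=view.isolate_id,
        mode=view.mode,
        k=k,
        strand_policy=strand_policy,
        words=words,
        counts=counts.astype(np.int64),
        total_positions=total_positions,
        nt_freqs=freqs,
    )


def count_genome(
    genome: GenomeRecord, mode: str, k: int, strand_policy: str = "both", **view_kwargs
) -> KmerCountTable:
    """Shortcut: build the view and count it."""
    return count_view(make_view(genome, mode, **view_kwargs), k, strand_policy)


@dataclass(frozen=True)
class KmerOccurrence:
    isolate_id: str
    component_id: str
    offset: int  # 0-based, in the scanned (forward) component coordinates
    strand: str  # strand scanned: "+" or "-"
    features: tuple[GeneFeature, ...]  # features overlapping the k-mer by >= 1 base


@dataclass
class KmerLocationIndex:
    """In-process index word → occurrences with overlapping gene features.

    Fills the role of the relational k-mer database: given a word, report
    where it occurs and which genes it touches.
    """

    k: int
    strand_policy: str
    occurrences: dict = field(default_factory=dict)  # int word -> list[KmerOccurrence]

    def query(self, word: int | str) -> list[KmerOccurrence]:
        if isinstance(word, str):
            word = int(encode_kmers(word, self.k)[0])
        return self.occurrences.get(int(word), [])

    def __len__(self) -> int:
        return len(self.occurrences)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("word\tisolate\tcomponent\toffset\tstrand\tftypes\tcogs\n")
            for word in sorted(self.occurrences):
                for occ in self.occurrences[word]:
                    ftypes = ",".join(f.ftype for f in occ.features)
                    cogs = ",".join(
                        sorted({c for f in occ.features for c in f.cog_categories})
                    )
                    fh.write(
                        f"{decode_kmer(word, self.k)}\t{occ.isolate_id}\t"
                        f"{occ.component_id}\t{occ.offset}\t{occ.strand}\t"
                        f"{ftypes}\t{cogs}\n"
                    )


def build_location_index(
    genomes: Sequence[GenomeRecord],
    k: int,
    strand_policy: str = "both",
    vocabulary: Iterable[int] | np.ndarray | None = None,
) -> KmerLocationIndex:
    """Index k-mer occurrences across genomes, carrying overlapping features.

    If ``vocabulary`` (packed words) is given, only those words are indexed —
    this is how core k-mers are annotated without materialising the full
    index.  Reverse-strand occurrences are recorded with the offset of the
    window in forward component coordinates.
    """
    _check_policy(strand_policy)
    vocab: set[int] | None = None
    if vocabulary is not None:
        vocab = {int(w) for w in vocabulary}

    index = KmerLocationIndex(k=k, strand_policy=strand_policy)
    for genome in genomes:
        trees: dict[str, IntervalTree] = {}
        for f in genome.features:
            trees.setdefault(f.component_id, IntervalTree()).addi(f.start, f.end, f)
        for comp in genome.components:
            length = len(comp.sequence)
            scans = [("+", comp.sequence)]
            if strand_policy == "both":
                scans.append(("-", revcomp(comp.sequence)))
            for strand, text in scans:
                words, offsets = kmer_positions(text, k)
                for word, off in zip(words, offsets):
                    word = int(word)
                    if vocab is not None and word not in vocab:
                        continue
                    fwd_off = int(off) if strand == "+" else length - int(off) - k
                    tree = trees.get(comp.component_id)
                    feats: tuple[GeneFeature, ...] = ()
                    if tree is not None:
                        feats = tuple(
                            sorted(
                                (iv.data for iv in tree.overlap(fwd_off, fwd_off + k)),
                                key=lambda f: (f.start, f.end, f.ftype),
                            )
                        )
                    index.occurrences.setdefault(word, []).append(
                        KmerOccurrence(
                            isolate_id=genome.isolate_id,
                            component_id=comp.component_id,
                            offset=fwd_off,
                            strand=strand,
                            features=feats,
                        )
                    )
    return index
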