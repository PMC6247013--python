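"""The D2S statistic, its distance/similarity transforms, and edge lists.

For genomes a and b with k-mer counts X_w, Y_w, window totals n_X, n_Y and
order-0 background base frequencies, counts are centered against their
expectations, X̃_w = X_w − n_X p_w(X) (and likewise Ỹ), and

    D2S   = Σ_w X̃_w Ỹ_w / sqrt(X̃_w² + Ỹ_w²)
    A     = Σ_w X̃_w²    / sqrt(X̃_w² + Ỹ_w²)
    B     = Σ_w Ỹ_w²    / sqrt(X̃_w² + Ỹ_w²)
    dissimilarity = ½ (1 − D2S / sqrt(A·B))  ∈ [0, 1]

The dissimilarity behaves like half of (1 − a correlation): identical k-mer
contents give 0, and genomes sharing no k-mers give ≈ 0.5 (the centered
counts are then essentially uncorrelated).  The distance reported alongside
the networks is a rescaling of this dissimilarity; the default linear
transform d = 20 · dissimilarity places "no shared k-mers" at d ≈ 10, which
is exactly the edge filter boundary: pairs with d > 10 share essentially no
k-mers and are dropped.  Similarity is S = 10 − d, so S ranges from 10
(identical 25-mer contents) down to 0 at the filter.

By default the word sum runs over the union of words observed in either
genome, which is exact up to the product-of-expectations terms of words
absent from both — negligible at k = 25.  ``word_space="exhaustive"`` sums
over all 4^k words (small k only) for oracle-grade agreement.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigMismatch, DomainError
from .kmer_index import KmerCountTable

TRANSFORMS = ("linear", "log")


def _log_word_probs(words: np.ndarray, k: int, freqs: np.ndarray) -> np.ndarray:
    """log p_w under an order-0 model: sum of per-letter log frequencies."""
    with np.errstate(divide="ignore"):
        logf = np.log(freqs.astype(float))
    acc = np.zeros(len(words), dtype=float)
    w = words.copy()
    for _ in range(k):
        acc += logf[(w & np.uint64(3)).astype(np.intp)]
        w = w >> np.uint64(2)
    return acc


def _aligned_counts(table: KmerCountTable, words: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(table.words, words)
    idx_c = np.minimum(idx, max(len(table.words) - 1, 0))
    if len(table.words) == 0:
        return np.zeros(len(words), dtype=float)
    present = (idx < len(table.words)) & (table.words[idx_c] == words)
    return np.where(present, table.counts[idx_c], 0).astype(float)


def centered_counts(table: KmerCountTable, words: np.ndarray) -> np.ndarray:
    """X̃_w = X_w − n · p_w over the given (sorted) word array."""
    observed = _aligned_counts(table, words)
    expected = table.total_positions * np.exp(
        _log_word_probs(words, table.k, table.nt_freqs)
    )
    return observed - expected


def d2s(
    a: KmerCountTable, b: KmerCountTable, word_space: str = "observed"
) -> tuple[float, float]:
    """Compute (raw_D2S, dissimilarity) between two count tables.

    Word order is fixed (sorted packed words), so accumulation order — and
    therefore the result — is reproducible bit-for-bit for a given input.
    """
    if a.k != b.k:
        raise ConfigMismatch(f"k mismatch: {a.k} vs {b.k}")
    if a.strand_policy != b.strand_policy:
        raise ConfigMismatch(
            f"strand policy mismatch: {a.strand_policy} vs {b.strand_policy}"
        )
    if a.mode != b.mode:
        raise ConfigMismatch(f"view mode mismatch: {a.mode} vs {b.mode}")
    if word_space == "observed":
        words = np.union1d(a.words, b.words)
    elif word_space == "exhaustive":
        if a.k > 12:
            raise ValueError("exhaustive word space is limited to k <= 12")
        words = np.arange(4 ** a.k, dtype=np.uint64)
    else:
        raise ValueError(f"unknown word_space {word_space!r}")

    xt = centered_counts(a, words)
    yt = centered_counts(b, words)
    denom = np.sqrt(xt * xt + yt * yt)
    mask = denom > 0
    xt, yt, denom = xt[mask], yt[mask], denom[mask]
    raw = float(np.sum(xt * yt / denom))
    A = float(np.sum(xt * xt / denom))
    B = float(np.sum(yt * yt / denom))
    if A <= 0.0 or B <= 0.0:
        # Degenerate: at least one genome matches its background exactly.
        return raw, 0.5
    dissimilarity = 0.5 * (1.0 - raw / math.sqrt(A * B))
    return raw, float(min(1.0, max(0.0, dissimilarity)))


def to_distance(
    dissimilarity: float,
    transform: str = "linear",
    scale: float = 20.0,
    d_max: float = 100.0,
) -> float:
    """Map a dissimilarity in [0, 1] to the network distance d.

    ``linear``: d = scale · dissimilarity (default scale 20, so that a pair
    sharing no k-mers, dissimilarity ≈ 0.5, lands at the d = 10 edge-filter
    boundary).  ``log``: d = −ln(1 − dissimilarity), capped at ``d_max``.
    Both are strictly increasing with d(0) = 0.
    """
    if not (0.0 <= dissimilarity <= 1.0):
        raise DomainError(f"dissimilarity {dissimilarity} outside [0, 1]")
    if transform == "linear":
        return scale * dissimilarity
    if transform == "log":
        if dissimilarity >= 1.0:
            return d_max
        return min(d_max, -math.log(1.0 - dissimilarity))
    raise ValueError(f"unknown transform {transform!r}")


def to_similarity(d: float) -> float:
    """S = 10 − d (so S = 9.999 at d = 0.001, S = 0.075 at d = 9.925)."""
    if d < 0:
        raise DomainError(f"distance {d} is negative")
    return 10.0 - d


@dataclass(frozen=True)
class DistanceRecord:
    isolate_a: str
    isolate_b: str
    mode: str
    raw_d2s: float
    dissimilarity: float
    d: float
    S: float


@dataclass
class EdgeList:
    """Filtered pairwise similarity records over deduplicated isolates."""

    mode: str
    k: int
    strand_policy: str
    transform: str
    isolates: list[str]
    records: list[DistanceRecord] = field(default_factory=list)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#mode={self.mode}\n#k={self.k}\n")
            fh.write(f"#strand={self.strand_policy}\n#transform={self.transform}\n")
            fh.write(f"#isolates={','.join(self.isolates)}\n")
            fh.write("isolate_a\tisolate_b\traw_d2s\tdissimilarity\td\tS\n")
            for r in self.records:
                fh.write(
                    f"{r.isolate_a}\t{r.isolate_b}\t{r.raw_d2s!r}\t"
                    f"{r.dissimilarity!r}\t{r.d!r}\t{r.S!r}\n"
                )

    @classmethod
    def read_tsv(cls, path: str) -> "EdgeList":
        meta: dict[str, str] = {}
        records: list[DistanceRecord] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].partition("=")
                    meta[key] = value
                    continue
                if line.startswith("isolate_a\t"):
                    continue
                a, b, raw, dis, d, s = line.split("\t")
                records.append(
                    DistanceRecord(
                        a, b, meta["mode"], float(raw), float(dis), float(d), float(s)
                    )
                )
        return cls(
            mode=meta["mode"],
            k=int(meta["k"]),
            strand_policy=meta["strand"],
            transform=meta["transform"],
            isolates=meta["isolates"].split(",") if meta.get("isolates") else [],
            records=records,
        )


def deduplicate(
    tables: list[KmerCountTable],
) -> tuple[list[KmerCountTable], dict[str, list[str]]]:
    """Collapse genomes with identical k-mer contents (D2S distance = 0).

    Within each group of identical count tables the lexicographically
    smallest isolate_id is retained; the returned map records kept → dropped
    links.
    """
    groups: dict[bytes, list[KmerCountTable]] = {}
    for t in tables:
        groups.setdefault(t.content_key(), []).append(t)
    kept: list[KmerCountTable] = []
    dropped: dict[str, list[str]] = {}
    for group in groups.values():
        group = sorted(group, key=lambda t: t.isolate_id)
        kept.append(group[0])
        if len(group) > 1:
            dropped[group[0].isolate_id] = [t.isolate_id for t in group[1:]]
    kept.sort(key=lambda t: t.isolate_id)
    return kept, dropped


def pairwise_edges(
    tables: list[KmerCountTable],
    filter_dmax: float = 10.0,
    transform: str = "linear",
    scale: float = 20.0,
    d_max: float = 100.0,
    word_space: str = "observed",
) -> EdgeList:
    """All-vs-all D2S comparisons, filtered at d > ``filter_dmax``.

    ``tables`` should already be deduplicated.  Records carry S = 10 − d;
    pairs with d above the filter are absent (the paper's rationale: such
    pairs share essentially no k-mers).
    """
    if len(tables) < 2:
        raise ValueError("need at least two count tables for pairwise comparison")
    first = tables[0]
    for t in tables[1:]:
        if not t.same_config(first):
            raise ConfigMismatch(
                f"table {t.isolate_id!r} (k={t.k}, {t.strand_policy}, {t.mode}) "
                f"does not match {first.isolate_id!r}"
            )
    tables = sorted(tables, key=lambda t: t.isolate_id)
    records: list[DistanceRecord] = []
    for ta, tb in itertools.combinations(tables, 2):
        raw, dissimilarity = d2s(ta, tb, word_space=word_space)
        d = to_distance(dissimilarity, transform=transform, scale=scale, d_max=d_max)
        if d > filter_dmax:
            continue
        records.append(
            DistanceRecord(
                isolate_a=ta.isolate_id,
                isolate_b=tb.isolate_id,
                mode=ta.mode,
                raw_d2s=raw,
                dissimilarity=dissimilarity,
                d=d,
                S=to_similarity(d),
            )
        )
    return EdgeList(
        mode=first.mode,
        k=first.k,
        strand_policy=first.strand_policy,
        transform=transform,
        isolates=[t.isolate_id for t in tables],
        records=records,
    )
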