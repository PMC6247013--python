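"""Core k-mers of taxon groups, COG functional profiles, and enrichment.

A core k-mer of a group (genus, phylum, ...) is a word present in every
member genome; K = |core words| / |isolates| summarises how much of the
group's k-mer content is conserved per isolate.  Core words are mapped to
COG functional categories through the CDS features overlapping their
occurrences (per word, not per occurrence, so a word touching CDSs of
categories E and C increments both E and C by one).  Enrichment of a
category in one phylum's annotated core words against the pool of all other
phyla is tested with one-sided Fisher exact tests, Benjamini–Hochberg
corrected across the whole phylum × category family; the noninformative
categories R (general function prediction) and S (function unknown) are
excluded before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigMismatch
from .kmer_index import KmerCountTable, KmerLocationIndex, decode_kmer

DEFAULT_EXCLUDED = frozenset({"R", "S"})


@dataclass
class CoreKmerSet:
    taxon: str
    isolates: list[str]
    k: int
    words: np.ndarray  # uint64, sorted

    @property
    def K(self) -> float:
        """Distinct core k-mers per isolate."""
        return len(self.words) / len(self.isolates)

    def decoded(self) -> list[str]:
        return [decode_kmer(w, self.k) for w in self.words]


@dataclass
class CogProfile:
    taxon: str
    counts: dict[str, int] = field(default_factory=dict)  # COG letter -> n core words
    unannotated: int = 0  # core words with occurrences but no CDS overlap

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def informative_counts(self, excluded: frozenset = DEFAULT_EXCLUDED) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if c not in excluded}


@dataclass(frozen=True)
class EnrichmentResult:
    phylum: str
    category: str
    a: int  # this phylum, in category
    b: int  # this phylum, other categories
    c: int  # other phyla, in category
    d: int  # other phyla, other categories
    p: float
    p_adj: float
    significant: bool


def core_set(tables: Sequence[KmerCountTable], taxon: str) -> CoreKmerSet:
    """Intersect the word sets of all member genomes of a taxon.

    The core may be empty — highly divergent groups legitimately share no
    k-mer of the chosen length.
    """
    if not tables:
        raise ValueError("core_set needs at least one count table")
    first = tables[0]
    for t in tables[1:]:
        if t.k != first.k or t.strand_policy != first.strand_policy:
            raise ConfigMismatch(
                f"table {t.isolate_id!r} built with k={t.k}/{t.strand_policy}, "
                f"expected k={first.k}/{first.strand_policy}"
            )
    words = tables[0].words
    for t in tables[1:]:
        words = np.intersect1d(words, t.words, assume_unique=True)
    return CoreKmerSet(
        taxon=taxon,
        isolates=sorted(t.isolate_id for t in tables),
        k=first.k,
        words=words,
    )


def annotate_core(core: CoreKmerSet, index: KmerLocationIndex) -> CogProfile:
    """COG category counts over a taxon's core words via CDS overlap.

    For each core word the COG letters of every CDS feature overlapping any
    of its occurrences (in any member genome) are collected; each
    (word, letter) pair counts once.  Words whose occurrences overlap only
    rRNA/other features or bare sequence go to the ``unannotated`` tally.
    """
    if index.k != core.k:
        raise ConfigMismatch(f"index k={index.k} does not match core k={core.k}")
    profile = CogProfile(taxon=core.taxon)
    for word in core.words:
        occs = index.query(int(word))
        if not occs:
            raise ConfigMismatch(
                f"core word {decode_kmer(int(word), core.k)} absent from the index; "
                "was the index built with vocabulary=core.words over the same genomes?"
            )
        letters: set[str] = set()
        for occ in occs:
            for feat in occ.features:
                if feat.ftype == "CDS":
                    letters.update(feat.cog_categories)
        if letters:
            for letter in letters:
                profile.counts[letter] = profile.counts.get(letter, 0) + 1
        else:
            profile.unannotated += 1
    return profile


def top_categories(profile: CogProfile, m: int = 5) -> list[str]:
    """The m most frequent categories, ties broken alphabetically."""
    ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [letter for letter, _ in ranked[:m]]


def enrichment(
    per_phylum: Mapping[str, CogProfile],
    alpha: float = 0.05,
    alternative: str = "greater",
    excluded: frozenset = DEFAULT_EXCLUDED,
) -> list[EnrichmentResult]:
    """Per-phylum, per-category Fisher exact enrichment against the pool.

    For each phylum and category the 2×2 table contrasts (in category vs
    not) × (this phylum's annotated core words vs all other phyla pooled).
    One-sided ("greater") by default, since the question is enrichment;
    BH adjustment spans all phylum × category tests as one family.
    """
    profiles = {
        ph: prof.informative_counts(excluded) for ph, prof in per_phylum.items()
    }
    usable = {ph: c for ph, c in profiles.items() if sum(c.values()) > 0}
    skipped = sorted(set(profiles) - set(usable))
    if skipped:
        warnings.warn(f"phyla without annotated core k-mers skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("enrichment needs at least two phyla with annotated core k-mers")

    categories = sorted({c for counts in usable.values() for c in counts})
    totals = {ph: sum(counts.values()) for ph, counts in usable.items()}
    pooled = {
        cat: sum(counts.get(cat, 0) for counts in usable.values()) for cat in categories
    }
    grand_total = sum(totals.values())

    raw: list[EnrichmentResult] = []
    pvalues: list[float] = []
    for ph in sorted(usable):
        for cat in categories:
            a = usable[ph].get(cat, 0)
            b = totals[ph] - a
            c = pooled[cat] - a
            d = (grand_total - totals[ph]) - c
            _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
            raw.append(EnrichmentResult(ph, cat, a, b, c, d, float(p), np.nan, False))
            pvalues.append(float(p))

    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return [
        EnrichmentResult(r.phylum, r.category, r.a, r.b, r.c, r.d, r.p,
                         float(q), bool(sig))
        for r, q, sig in zip(raw, p_adj, reject)
    ]


def core_table(cores: Sequence[CoreKmerSet]) -> pd.DataFrame:
    """Summary frame: taxon, n_isolates, n_core, K (one row per taxon)."""
    return pd.DataFrame(
        {
            "taxon": [c.taxon for c in cores],
            "n_isolates": [len(c.isolates) for c in cores],
            "n_core": [len(c.words) for c in cores],
            "K": [c.K for c in cores],
        }
    )


def profile_table(profiles: Sequence[CogProfile]) -> pd.DataFrame:
    """Taxon × COG-letter count matrix (letters A..Z that occur anywhere)."""
    letters = sorted({c for p in profiles for c in p.counts})
    data = {
        "taxon": [p.taxon for p in profiles],
        **{c: [p.counts.get(c, 0) for p in profiles] for c in letters},
        "unannotated": [p.unannotated for p in profiles],
    }
    return pd.DataFrame(data)


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phylum": [r.phylum for r in results],
            "category": [r.category for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [r.significant for r in results],
        }
    )
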