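"""Fragment-based average nucleotide identity (ANI) and species delimitation.

ANIb-style procedure: the query genome is cut into consecutive non-overlapping
fragments (default 1020 bp, trailing remainder dropped); each fragment is
anchored in the subject by exact k-mer seeding on both strands and aligned
glocally (full fragment against a banded subject window) with edlib; fragments
passing the identity and coverage filters contribute their identity to the
directional ANI.  The symmetric ANI is the mean of the two directions, and two
genomes are called distinct species when 1 - ANI exceeds the 10% whole-genome
difference threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AniError(ValueError):
    pass


@dataclass
class DirectionalAni:
    ani: float | None
    coverage: float
    fragments_total: int
    fragments_passing: int


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: float | None
    aligned_fraction: float
    fragment_count: int
    per_direction: tuple[DirectionalAni, DirectionalAni]

    @property
    def flagged(self) -> bool:
        """True when no fragments passed in at least one direction."""
        return self.ani is None


def _as_records(seq) -> list[str]:
    """Accept a plain sequence or a list of FASTA records (fragmented independently)."""
    if isinstance(seq, str):
        return [seq.upper()]
    return [str(s).upper() for s in seq]


def _fragments(records: list[str], fragment_length: int) -> list[str]:
    frags = []
    for rec in records:
        for start in range(0, len(rec) - fragment_length + 1, fragment_length):
            frags.append(rec[start : start + fragment_length])
    return frags


def _kmer_index(records: list[str], k: int) -> dict[str, list[tuple[int, int, int]]]:
    """kmer -> [(record index, position, strand)], strand 0 = forward, 1 = reverse."""
    index: dict[str, list[tuple[int, int, int]]] = {}
    for ri, rec in enumerate(records):
        for strand, s in ((0, rec), (1, reverse_complement(rec))):
            for p in range(len(s) - k + 1):
                index.setdefault(s[p : p + k], []).append((ri, p, strand))
    return index


def _best_fragment_identity(
    frag: str,
    records: list[str],
    index,
    k: int,
    band: int,
    max_candidates: int = 3,
) -> tuple[float, float]:
    """(identity, coverage) of the best anchored placement; (0, 0) if unanchored."""
    votes: Counter = Counter()
    for q in range(0, len(frag) - k + 1):
        for ri, p, strand in index.get(frag[q : q + k], ()):
            diag = p - q
            votes[(ri, strand, diag // max(band, 1))] += 1
    if not votes:
        return 0.0, 0.0
    best_identity, best_coverage = 0.0, 0.0
    for (ri, strand, bucket), _ in votes.most_common(max_candidates):
        rec = records[ri] if strand == 0 else reverse_complement(records[ri])
        start = max(0, bucket * band - band)
        end = min(len(rec), bucket * band + len(frag) + 2 * band)
        window = rec[start:end]
        if len(window) < k:
            continue
        aln = edlib.align(frag, window, mode="HW", task="distance")
        dist = aln["editDistance"]
        if dist < 0:
            continue
        identity = max(0.0, 1.0 - dist / len(frag))
        if identity > best_identity:
            best_identity = identity
            best_coverage = 1.0  # glocal alignment consumes the whole fragment
    return best_identity, best_coverage


def _directional(
    query: list[str],
    subject: list[str],
    fragment_length: int,
    band: int,
    min_identity: float,
    min_coverage: float,
    seed_k: int,
) -> DirectionalAni:
    frags = _fragments(query, fragment_length)
    if not frags:
        raise AniError(
            f"query shorter than the fragment length ({fragment_length} bp)"
        )
    index = _kmer_index(subject, seed_k)
    identities = []
    for frag in frags:
        identity, coverage = _best_fragment_identity(frag, subject, index, seed_k, band)
        if identity >= min_identity and coverage >= min_coverage:
            identities.append(identity)
    if not identities:
        return DirectionalAni(None, 0.0, len(frags), 0)
    return DirectionalAni(
        ani=sum(identities) / len(identities),
        coverage=len(identities) / len(frags),
        fragments_total=len(frags),
        fragments_passing=len(identities),
    )


def compute_ani(
    a,
    b,
    fragment_length: int = 1020,
    band: int = 60,
    min_fragment_identity: float = 0.3,
    min_fragment_coverage: float = 0.7,
    seed_k: int = 16,
    genome_a: str = "a",
    genome_b: str = "b",
) -> AniResult:
    """Symmetric fragment-based ANI between two genomes.

    ``a`` and ``b`` are sequences or lists of record sequences (multi-record
    genomes are fragmented per record, never concatenated).  When no fragment
    passes the filters in a direction the result is flagged (``ani`` is None).
    """
    ra, rb = _as_records(a), _as_records(b)
    for name, recs in ((genome_a, ra), (genome_b, rb)):
        if max((len(r) for r in recs), default=0) < fragment_length:
            raise AniError(
                f"genome {name!r} has no record of at least {fragment_length} bp"
            )
    d_ab = _directional(
        ra, rb, fragment_length, band, min_fragment_identity, min_fragment_coverage, seed_k
    )
    d_ba = _directional(
        rb, ra, fragment_length, band, min_fragment_identity, min_fragment_coverage, seed_k
    )
    if d_ab.ani is None or d_ba.ani is None:
        ani = None
    else:
        ani = (d_ab.ani + d_ba.ani) / 2.0
    return AniResult(
        genome_a=genome_a,
        genome_b=genome_b,
        ani=ani,
        aligned_fraction=(d_ab.coverage + d_ba.coverage) / 2.0,
        fragment_count=d_ab.fragments_total + d_ba.fragments_total,
        per_direction=(d_ab, d_ba),
    )


SAME_SPECIES = "same_species"
DISTINCT_SPECIES = "distinct_species"


def classify_species_pair(
    result: AniResult, difference_threshold: float = 0.10
) -> str:
    """Distinct species iff the whole-genome difference 1 - ANI exceeds 10%."""
    if result.flagged:
        raise AniError(
            f"ANI undefined for pair ({result.genome_a}, {result.genome_b}): "
            "no fragments passed the filters"
        )
    return DISTINCT_SPECIES if (1.0 - result.ani) > difference_threshold else SAME_SPECIES


def read_fasta(path) -> list[str]:
    """Record sequences from a FASTA file (Biopython SeqIO)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
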