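"""Synonymous coding-sequence recoding and probe-discriminability metrics.

To test whether an mRNA's localization depends on its nucleotide sequence
rather than its protein product, the coding sequence is re-coded to maximize
nucleotide divergence while preserving the amino-acid sequence exactly: each
codon is replaced by the synonymous codon with the largest Hamming distance
to the original, restricted to codons above a usage floor so expression
stays comparable (worm-preferred codons by default).  Ties break toward the
more used codon, then alphabetically, making the recoder deterministic.

Identity metrics (nucleotide %, amino-acid %) and the longest shared
positional run — a proxy for whether hybridization probes can discriminate
the two sequences — are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._codon_usage import CELEGANS_CODON_FRACTIONS

__all__ = [
    "CodingSequence",
    "CodonUsageTable",
    "identity_aa",
    "identity_nt",
    "longest_shared_run",
    "recode",
    "synonymous_families",
]

_BASES = set("ACGT")


@lru_cache(maxsize=None)
def synonymous_families(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    """Codon -> all codons encoding the same amino acid (stops form their own
    family; no recoding crosses families)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)
    fam: dict[str, tuple[str, ...]] = {}
    for codons in by_aa.values():
        codons = tuple(sorted(codons))
        for c in codons:
            fam[c] = codons
    return fam


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence: ACGT alphabet, complete codons, and no
    internal stop codons (a terminal stop is allowed)."""

    sequence: str
    table_id: int = 1

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError("sequence length must be a positive multiple of 3")
        if not set(seq) <= _BASES:
            raise ValueError("sequence must contain only A, C, G, T")
        stops = set(CodonTable.unambiguous_dna_by_id[self.table_id].stop_codons)
        for i in range(0, len(seq) - 3, 3):
            if seq[i:i + 3] in stops:
                raise ValueError(f"internal stop codon at nucleotide {i}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i:i + 3] for i in range(0, len(self.sequence), 3)]

    def translate(self) -> str:
        """Amino-acid sequence; '*' for a terminal stop."""
        return str(Seq(self.sequence).translate(table=self.table_id))


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative usage weight per codon, normalized within each synonymous
    family so every family sums to 1."""

    weights: dict[str, float]
    table_id: int = 1

    def __post_init__(self):
        fam = synonymous_families(self.table_id)
        missing = set(fam) - set(self.weights)
        if missing:
            raise ValueError(f"usage table missing codons: {sorted(missing)}")
        norm: dict[str, float] = {}
        for codon, family in fam.items():
            total = sum(self.weights[c] for c in family)
            if total <= 0:
                raise ValueError(f"family of {codon} has zero total usage")
            norm[codon] = self.weights[codon] / total
        object.__setattr__(self, "weights", norm)

    @classmethod
    def c_elegans(cls) -> "CodonUsageTable":
        return cls(dict(CELEGANS_CODON_FRACTIONS))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def recode(
    cds: CodingSequence,
    usage: CodonUsageTable | None = None,
    min_usage: float = 0.05,
    seed: int = 0,
) -> CodingSequence:
    """Synonymously re-code a CDS for maximal nucleotide divergence.

    Per codon: among synonymous codons with usage >= ``min_usage``, pick the
    one with maximal Hamming distance to the original (ties: higher usage,
    then alphabetical).  The translation of the output equals the input's
    exactly.  Deterministic; ``seed`` is reserved for a future stochastic
    mode and has no effect on the max-distance rule.
    """
    del seed  # deterministic under the max-distance rule
    usage = usage or CodonUsageTable.c_elegans()
    if usage.table_id != cds.table_id:
        raise ValueError("usage table and CDS use different codon tables")
    fam = synonymous_families(cds.table_id)
    out: list[str] = []
    for codon in cds.codons:
        allowed = [c for c in fam[codon] if usage.weights[c] >= min_usage]
        if not allowed:
            raise ValueError(
                f"min_usage={min_usage} leaves no allowed codon in the family of {codon}"
            )
        best = min(allowed, key=lambda c: (-_hamming(codon, c), -usage.weights[c], c))
        out.append(best)
    return CodingSequence("".join(out), table_id=cds.table_id)


def _check_equal_length(a: CodingSequence, b: CodingSequence) -> None:
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ ({len(a)} vs {len(b)})")


def identity_nt(a: CodingSequence, b: CodingSequence) -> float:
    """Percent identical nucleotide positions between equal-length sequences."""
    _check_equal_length(a, b)
    matches = sum(x == y for x, y in zip(a.sequence, b.sequence))
    return 100.0 * matches / len(a)


def identity_aa(a: CodingSequence, b: CodingSequence) -> float:
    """Percent identical residues after translating both sequences."""
    _check_equal_length(a, b)
    ta, tb = a.translate(), b.translate()
    return 100.0 * sum(x == y for x, y in zip(ta, tb)) / len(ta)


def longest_shared_run(a: CodingSequence, b: CodingSequence) -> int:
    """Longest run of consecutive matching nucleotide positions — the longest
    stretch a hybridization probe could not use to discriminate the two."""
    _check_equal_length(a, b)
    best = cur = 0
    for x, y in zip(a.sequence, b.sequence):
        cur = cur + 1 if x == y else 0
        best = max(best, cur)
    return best
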