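"""Codon-level variant library model.

An ORF is represented as a plain nucleotide string partitioned into codons
(1-based residue positions).  A variant library is the set of codon-level
changes screened in a saturation-mutagenesis experiment: silent (synonymous),
missense, nonsense, and frameshift alleles.  Consequence classes follow the
standard genetic code; protein-level substitutions can be expanded to the
single-nucleotide variants (SNVs) that encode them, which is how codon-level
functional scores are joined to SNV-level predictor tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "STOP",
    "FRAMESHIFT",
    "GENETIC_CODE",
    "SYNONYMOUS",
    "PREFERRED_CODON",
    "OrfSequence",
    "Variant",
    "SnvChange",
    "LibraryScheme",
    "translate_codon",
    "classify_substitution",
    "enumerate_library",
    "expand_to_snvs",
    "library_frame",
    "read_orf_fasta",
]

STOP = "*"
FRAMESHIFT = "fs"
_BASES = "ACGT"

# Standard genetic code (NCBI table 1) via Biopython.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
GENETIC_CODE.update({c: STOP for c in _TABLE.stop_codons})

# codon -> set of synonymous codons (same amino acid, excluding the codon itself)
SYNONYMOUS: dict[str, frozenset[str]] = {
    c: frozenset(k for k, v in GENETIC_CODE.items() if v == aa and k != c)
    for c, aa in GENETIC_CODE.items()
}

# Most-used human codon per amino acid (Kazusa human codon-usage table);
# used by the one-codon-per-target-AA missense rule.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
    STOP: "TGA",
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values()) - {STOP}))


def translate_codon(codon: str) -> str:
    """Translate a codon under the standard genetic code ("*" for stop).

    Raises ``ValueError`` for anything that is not a 3-mer over ACGT.
    """
    if not isinstance(codon, str) or len(codon) != 3:
        raise ValueError(f"codon must be a 3-mer, got {codon!r}")
    codon = codon.upper()
    if any(b not in _BASES for b in codon):
        raise ValueError(f"codon contains non-ACGT characters: {codon!r}")
    return GENETIC_CODE[codon]


def classify_substitution(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon substitution as silent, missense, or nonsense."""
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == STOP:
        raise ValueError(f"reference codon {ref_codon} is a stop codon")
    if alt_aa == STOP:
        return "nonsense"
    return "silent" if alt_aa == ref_aa else "missense"


@dataclass(frozen=True)
class OrfSequence:
    """An open reading frame: id, nucleotide sequence, residue count.

    The sequence is the coding region without the terminal stop codon:
    length divisible by 3, ACGT alphabet, no internal stop in frame.
    Residue positions are 1-based (1..n_residues).
    """

    id: str
    nt_sequence: str

    def __post_init__(self) -> None:
        seq = self.nt_sequence.upper()
        object.__setattr__(self, "nt_sequence", seq)
        if len(seq) % 3 != 0:
            raise ValueError(f"ORF length {len(seq)} is not divisible by 3")
        if len(seq) == 0:
            raise ValueError("empty ORF")
        if any(b not in _BASES for b in seq):
            raise ValueError("ORF contains non-ACGT characters")
        for pos in range(1, len(seq) // 3 + 1):
            if translate_codon(self.codon(pos)) == STOP:
                raise ValueError(f"in-frame stop codon at residue {pos}")

    @property
    def n_residues(self) -> int:
        return len(self.nt_sequence) // 3

    def codon(self, position: int) -> str:
        """Reference codon at 1-based residue ``position``."""
        if not 1 <= position <= len(self.nt_sequence) // 3:
            raise IndexError(f"residue position {position} outside ORF")
        return self.nt_sequence[3 * (position - 1): 3 * position]

    @property
    def protein(self) -> str:
        return "".join(
            translate_codon(self.codon(p)) for p in range(1, self.n_residues + 1)
        )


@dataclass(frozen=True)
class Variant:
    """One codon-level library member.

    For substitutions ``alt`` is the alternate codon; for frameshifts it is a
    signed indel length (``"del-1"`` etc.) and ``alt_aa`` is the frameshift
    marker "fs".  IDs follow the field convention R377H / R377* / fs377-1;
    silent IDs carry the alternate codon (K2K.AAG) since several synonymous
    codons can encode the same residue.
    """

    variant_id: str
    position: int
    ref_codon: str
    alt: str
    ref_aa: str
    alt_aa: str
    consequence: str

    def __post_init__(self) -> None:
        if self.consequence not in ("silent", "missense", "nonsense", "frameshift"):
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence == "frameshift":
            if self.alt_aa != FRAMESHIFT:
                raise ValueError("frameshift variant must have alt_aa='fs'")
            return
        expected = classify_substitution(self.ref_codon, self.alt)
        if expected != self.consequence:
            raise ValueError(
                f"{self.variant_id}: {self.ref_codon}->{self.alt} is {expected}, "
                f"not {self.consequence}"
            )


@dataclass(frozen=True)
class SnvChange:
    """A single-nucleotide change within the ORF (1-based CDS coordinates)."""

    cds_position: int
    ref_base: str
    alt_base: str
    parent_variant_id: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")


@dataclass(frozen=True)
class LibraryScheme:
    """Which consequence classes the enumerated library contains and how.

    missense_codon_rule: "one-codon-per-target-AA" (19 entries per residue,
    human-preferred codons) or "all-codons".
    synonymous_rule: "all-synonymous-codons" or "one-per-position".
    frameshift alleles are single-nucleotide deletions at the first base of
    the codon, one per position.
    """

    include_silent: bool = True
    include_nonsense: bool = True
    include_frameshift: bool = True
    missense_codon_rule: str = "one-codon-per-target-AA"
    synonymous_rule: str = "all-synonymous-codons"
    include_missense: bool = True

    def __post_init__(self) -> None:
        if self.missense_codon_rule not in ("one-codon-per-target-AA", "all-codons"):
            raise ValueError(f"unknown missense_codon_rule {self.missense_codon_rule!r}")
        if self.synonymous_rule not in ("all-synonymous-codons", "one-per-position"):
            raise ValueError(f"unknown synonymous_rule {self.synonymous_rule!r}")


def _nonsense_codon(ref_codon: str) -> str:
    """Stop codon for the nonsense allele at this position.

    Prefers a stop reachable by a single nucleotide substitution
    (alphabetical on ties), falling back to TGA.
    """
    reachable = sorted(
        stop for stop in _TABLE.stop_codons
        if sum(a != b for a, b in zip(ref_codon, stop)) == 1
    )
    return reachable[0] if reachable else "TGA"


def enumerate_library(orf: OrfSequence, scheme: LibraryScheme | None = None) -> list[Variant]:
    """Enumerate the codon-level variant library for an ORF.

    Deterministic and position-sorted.  Under the one-codon-per-target-AA
    rule every residue has exactly 19 missense entries; silent entries exist
    only where synonymous codons exist; one nonsense and one frameshift
    (single-base deletion) per position when enabled.
    """
    scheme = scheme or LibraryScheme()
    out: list[Variant] = []
    for pos in range(1, orf.n_residues + 1):
        ref_codon = orf.codon(pos)
        ref_aa = translate_codon(ref_codon)
        if scheme.include_silent:
            syn = sorted(SYNONYMOUS[ref_codon])
            if scheme.synonymous_rule == "one-per-position":
                preferred = PREFERRED_CODON[ref_aa]
                if preferred in syn:
                    syn = [preferred]
                else:
                    syn = syn[:1]
            for alt_codon in syn:
                out.append(Variant(
                    variant_id=f"{ref_aa}{pos}{ref_aa}.{alt_codon}",
                    position=pos, ref_codon=ref_codon, alt=alt_codon,
                    ref_aa=ref_aa, alt_aa=ref_aa, consequence="silent",
                ))
        if scheme.include_missense:
            if scheme.missense_codon_rule == "one-codon-per-target-AA":
                for aa in AMINO_ACIDS:
                    if aa == ref_aa:
                        continue
                    out.append(Variant(
                        variant_id=f"{ref_aa}{pos}{aa}",
                        position=pos, ref_codon=ref_codon,
                        alt=PREFERRED_CODON[aa],
                        ref_aa=ref_aa, alt_aa=aa, consequence="missense",
                    ))
            else:
                for alt_codon in sorted(GENETIC_CODE):
                    aa = GENETIC_CODE[alt_codon]
                    if aa in (ref_aa, STOP):
                        continue
                    out.append(Variant(
                        variant_id=f"{ref_aa}{pos}{aa}.{alt_codon}",
                        position=pos, ref_codon=ref_codon, alt=alt_codon,
                        ref_aa=ref_aa, alt_aa=aa, consequence="missense",
                    ))
        if scheme.include_nonsense:
            out.append(Variant(
                variant_id=f"{ref_aa}{pos}{STOP}",
                position=pos, ref_codon=ref_codon,
                alt=_nonsense_codon(ref_codon),
                ref_aa=ref_aa, alt_aa=STOP, consequence="nonsense",
            ))
        if scheme.include_frameshift:
            out.append(Variant(
                variant_id=f"fs{pos}-1",
                position=pos, ref_codon=ref_codon, alt="del-1",
                ref_aa=ref_aa, alt_aa=FRAMESHIFT, consequence="frameshift",
            ))
    ids = [v.variant_id for v in out]
    if len(set(ids)) != len(ids):
        raise RuntimeError("duplicate variant ids in enumerated library")
    return out


def expand_to_snvs(variant: Variant, orf: OrfSequence) -> list[SnvChange]:
    """All single-nucleotide changes to the reference codon that reproduce
    the variant's (position, alt_aa) consequence.

    Empty when the amino-acid change needs >=2 substitutions.  Frameshift
    variants are not expressible as substitutions and raise ``ValueError``.
    """
    if variant.consequence == "frameshift":
        raise ValueError("frameshift variants cannot be expanded to SNVs")
    ref_codon = orf.codon(variant.position)
    if ref_codon != variant.ref_codon:
        raise ValueError(
            f"{variant.variant_id}: ref codon {variant.ref_codon} does not match "
            f"ORF codon {ref_codon} at position {variant.position}"
        )
    out = []
    for offset in range(3):
        ref_base = ref_codon[offset]
        for alt_base in _BASES:
            if alt_base == ref_base:
                continue
            mutated = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
            if translate_codon(mutated) == variant.alt_aa:
                out.append(SnvChange(
                    cds_position=3 * (variant.position - 1) + offset + 1,
                    ref_base=ref_base, alt_base=alt_base,
                    parent_variant_id=variant.variant_id,
                ))
    return out


def library_frame(library: list[Variant]) -> pd.DataFrame:
    """Tabulate a variant library (one row per variant)."""
    return pd.DataFrame({
        "variant_id": [v.variant_id for v in library],
        "position": [v.position for v in library],
        "ref_codon": [v.ref_codon for v in library],
        "alt_codon_or_fs": [v.alt for v in library],
        "ref_aa": [v.ref_aa for v in library],
        "alt_aa": [v.alt_aa for v in library],
        "consequence": [v.consequence for v in library],
    })


def read_orf_fasta(path, record_id: str | None = None) -> OrfSequence:
    """Read an ORF from FASTA.  Multi-record files require ``record_id``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} has {len(records)} records; specify record_id"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return OrfSequence(id=rec.id, nt_sequence=str(rec.seq))
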