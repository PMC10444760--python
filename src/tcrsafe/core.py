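"""Amino-acid alphabet, peptide types, and peptide arithmetic.

The whole pipeline works on short (8--11-mer) MHC class-I epitopes over the
20 canonical amino acids.  Sequence dissimilarity between equal-length
peptides is counted as the number of positionwise residue exchanges
(Hamming distance); substitution-only distance is deliberate -- single-residue
mimotopes and proteome hits are always compared at equal length.

Internal coordinates are 0-based half-open throughout; user-facing reports
convert to 1-based inclusive (UniProt/PROSITE convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AMINO_ACID_SET: frozenset[str] = frozenset(AMINO_ACIDS)

#: Index of each canonical residue in :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Peptide:
    """A validated peptide over the canonical amino-acid alphabet.

    Sequences are upper-cased on construction.  Ambiguity and non-standard
    codes (B, J, O, U, X, Z) are rejected: a peptide that enters the pipeline
    must be synthesizable and unambiguous.  Proteome sequences, which may
    legitimately contain such letters, are handled as plain strings by the
    scanner and never coerced into this type.
    """

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("peptide sequence must be non-empty")
        bad = sorted(set(seq) - AMINO_ACID_SET)
        if bad:
            raise ValueError(
                f"peptide {seq!r} contains non-canonical residue(s): {', '.join(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, i):
        return self.sequence[i]

    def __iter__(self):
        return iter(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def as_peptide(p: "Peptide | str") -> Peptide:
    """Coerce a string to :class:`Peptide` (validating it), pass peptides through."""
    return p if isinstance(p, Peptide) else Peptide(p)


@dataclass(frozen=True)
class EpitopeContext:
    """An epitope located within its source protein.

    Carries everything needed to report candidate coordinates and to design
    minigene constructs with natural flanking sequence.

    Parameters
    ----------
    protein_accession : str
        Accession of the source protein.
    protein_sequence : str
        Full protein sequence (may contain non-canonical letters outside the
        epitope window).
    epitope : Peptide
        The epitope itself.
    epitope_offset : int
        0-based index of the epitope start within the protein.
    """

    protein_accession: str
    protein_sequence: str
    epitope: Peptide
    epitope_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_sequence", self.protein_sequence.upper())
        object.__setattr__(self, "epitope", as_peptide(self.epitope))
        n, L = len(self.protein_sequence), len(self.epitope)
        if not 0 <= self.epitope_offset <= n - L:
            raise ValueError(
                f"epitope offset {self.epitope_offset} out of range for protein of "
                f"length {n} and epitope of length {L}"
            )
        window = self.protein_sequence[self.epitope_offset : self.epitope_offset + L]
        if window != str(self.epitope):
            raise ValueError(
                f"protein window {window!r} at offset {self.epitope_offset} does not "
                f"match epitope {self.epitope}"
            )


def hamming_distance(a: "Peptide | str", b: "Peptide | str") -> int:
    """Number of positions at which two equal-length peptides differ.

    This is the "edit distance" used throughout candidate reporting: the
    minimal number of single-residue exchanges turning one peptide into the
    other.  Gapped alignment is out of scope by design.

    Raises
    ------
    ValueError
        If the peptides have different lengths.
    """
    sa, sb = str(a), str(b)
    if len(sa) != len(sb):
        raise ValueError(
            f"hamming_distance requires equal lengths, got {len(sa)} and {len(sb)}"
        )
    return sum(x != y for x, y in zip(sa, sb))
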