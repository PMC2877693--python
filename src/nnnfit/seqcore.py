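"""Sequence representation and circular k-mer counting.

The inhibition model treats a short mRNA target (typically a 20-mer) as a
*closed circular* sequence, so that every position contributes exactly one
overlapping triplet and no special end terms are needed.  Circular counts
obey flow-balance constraints — every doublet is entered and exited equally
— which makes only 49 of the 64 triplet directions identifiable.  This
module provides the count vectors, the constraint matrix that encodes that
algebra, and strand bookkeeping between antisense DNA oligomers and their
mRNA targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"

#: All 64 trinucleotides in lexicographic order A < C < G < U (mRNA strand).
TRIPLETS: tuple[str, ...] = tuple("".join(p) for p in product(RNA_ALPHABET, repeat=3))
#: All 16 dinucleotides, same ordering convention.
DOUBLETS: tuple[str, ...] = tuple("".join(p) for p in product(RNA_ALPHABET, repeat=2))

TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}
DOUBLET_INDEX = {d: i for i, d in enumerate(DOUBLETS)}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Residues outside the strict 4-letter nucleotide alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An oriented (5'->3') nucleotide sequence.

    Sequences are stored in the alphabet given by ``alphabet`` ("RNA" or
    "DNA").  Ambiguity codes (N, R, Y, ...) are rejected: the triplet model
    has no defined semantics for them.  ``topology`` selects between the
    closed-circular convention used throughout fitting and scoring and an
    explicit linear mode.
    """

    residues: str
    topology: str = "circular"
    alphabet: str = "RNA"
    id: str = ""

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.alphabet not in ("RNA", "DNA"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise AlphabetError("empty sequence")
        allowed = RNA_ALPHABET if self.alphabet == "RNA" else DNA_ALPHABET
        bad = set(self.residues) - set(allowed)
        if bad:
            raise AlphabetError(
                f"invalid residues {sorted(bad)} for {self.alphabet} sequence"
                " (ambiguity codes are not supported)"
            )

    @classmethod
    def from_string(
        cls,
        raw: str,
        topology: str = "circular",
        alphabet: str = "RNA",
        id: str = "",
    ) -> "NucleotideSequence":
        """Build a sequence from raw text, uppercasing and, for RNA,
        transliterating T -> U (DNA input is accepted for mRNA targets)."""
        s = raw.strip().upper().replace(" ", "")
        if alphabet == "RNA":
            s = s.replace("T", "U")
        else:
            s = s.replace("U", "T")
        return cls(s, topology=topology, alphabet=alphabet, id=id)

    def __len__(self) -> int:
        return len(self.residues)

    def circularized(self) -> "NucleotideSequence":
        if self.topology == "circular":
            return self
        return NucleotideSequence(self.residues, "circular", self.alphabet, self.id)

    def as_rna(self) -> "NucleotideSequence":
        if self.alphabet == "RNA":
            return self
        return NucleotideSequence(
            self.residues.replace("T", "U"), self.topology, "RNA", self.id
        )


def _count_kmers(seq: NucleotideSequence, k: int, index: dict[str, int]) -> np.ndarray:
    if seq.alphabet != "RNA":
        seq = seq.as_rna()
    s = seq.residues
    L = len(s)
    counts = np.zeros(len(index), dtype=np.int64)
    if seq.topology == "circular":
        if L < k:
            raise ValueError(f"circular sequence of length {L} has no {k}-mers")
        ext = s + s[: k - 1]
        for i in range(L):
            counts[index[ext[i : i + k]]] += 1
    else:
        if L < k:
            raise ValueError(f"linear sequence of length {L} has no {k}-mers")
        for i in range(L - k + 1):
            counts[index[s[i : i + k]]] += 1
    return counts


def count_triplets(seq: NucleotideSequence) -> np.ndarray:
    """Overlapping trinucleotide counts of a circular sequence.

    Entry t is the number of positions i where residues i, i+1, i+2
    (mod L) spell triplet t; the 64 entries sum to L.  Linear topology is
    rejected here — the fitting and scoring paths always circularize; use
    :func:`count_kmers_linear` for the explicit linear mode.
    """
    if seq.topology != "circular":
        raise ValueError("count_triplets requires circular topology")
    return _count_kmers(seq, 3, TRIPLET_INDEX)


def count_doublets(seq: NucleotideSequence) -> np.ndarray:
    """Overlapping dinucleotide counts of a circular sequence (16 entries)."""
    if seq.topology != "circular":
        raise ValueError("count_doublets requires circular topology")
    return _count_kmers(seq, 2, DOUBLET_INDEX)


def count_kmers_linear(seq: NucleotideSequence, k: int) -> np.ndarray:
    """L-k+1 window counts of a linear sequence (k = 2 or 3)."""
    index = {2: DOUBLET_INDEX, 3: TRIPLET_INDEX}[k]
    lin = NucleotideSequence(seq.residues, "linear", seq.alphabet, seq.id)
    return _count_kmers(lin, k, index)


def antisense_complement(
    seq: NucleotideSequence, output_alphabet: str = "RNA"
) -> NucleotideSequence:
    """Map a 5'->3' strand to its 5'->3' base-pairing partner.

    This is the reverse complement with T<->U transliteration, e.g. the
    antisense DNA 5'-TCCC-3' pairs with the mRNA site 5'-GGGA-3'.  Applying
    it twice with matching alphabets is the identity.
    """
    if output_alphabet not in ("RNA", "DNA"):
        raise AlphabetError(f"unknown output alphabet {output_alphabet!r}")
    table = _RNA_COMPLEMENT if seq.alphabet == "RNA" else _DNA_COMPLEMENT
    comp = seq.residues.translate(table)[::-1]
    if output_alphabet == "RNA":
        comp = comp.replace("T", "U")
    else:
        comp = comp.replace("U", "T")
    return NucleotideSequence(comp, seq.topology, output_alphabet, seq.id)


def constraint_matrix(order: str = "triplet") -> np.ndarray:
    """Flow-balance constraints satisfied by every circular count vector.

    Triplet case: for each doublet XY, the number of triplets that begin
    with XY equals the number that end with XY (sum_Z n(XYZ) = sum_W n(WXY)),
    giving a 16 x 64 integer matrix of rank 15.  Doublet case: per-base
    out-minus-in balance, 4 x 16 of rank 3.
    """
    if order == "triplet":
        M = np.zeros((16, 64), dtype=np.int64)
        for r, xy in enumerate(DOUBLETS):
            for z in RNA_ALPHABET:
                M[r, TRIPLET_INDEX[xy + z]] += 1
            for w in RNA_ALPHABET:
                M[r, TRIPLET_INDEX[w + xy]] -= 1
        return M
    if order == "doublet":
        M = np.zeros((4, 16), dtype=np.int64)
        for r, x in enumerate(RNA_ALPHABET):
            for z in RNA_ALPHABET:
                M[r, DOUBLET_INDEX[x + z]] += 1
            for w in RNA_ALPHABET:
                M[r, DOUBLET_INDEX[w + x]] -= 1
        return M
    raise ValueError(f"unknown order {order!r}")


def circular_count_space(order: str = "triplet") -> np.ndarray:
    """Orthonormal rows spanning the space of circular count vectors.

    The count vectors of circular sequences fill the null space of the
    flow-balance constraints: 49 dimensions for triplets, 13 for doublets.
    Useful as the row-space reference for estimability checks.
    """
    from scipy.linalg import null_space

    C = constraint_matrix(order).astype(float)
    return null_space(C).T


def read_fasta(path, topology: str = "linear", alphabet: str = "RNA") -> list[NucleotideSequence]:
    """Read sequences from FASTA; the description line is kept as the id."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            NucleotideSequence.from_string(
                str(rec.seq), topology=topology, alphabet=alphabet, id=rec.description
            )
        )
    return out


def write_fasta(sequences, path) -> None:
    """Write sequences as uppercase RNA FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id or 'seq'}\n{seq.as_rna().residues}\n")
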