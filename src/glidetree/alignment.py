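"""Nucleotide alignments as compressed site patterns.

A site pattern is one alignment column (one symbol per taxon); identical
columns are merged and counted, which is the standard way to avoid
recomputing identical partial-likelihood columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STATES = "ACGT"

# IUPAC codes map to the set of compatible nucleotides; fully unknown
# symbols get an all-ones partial vector (treated as missing data)
_PARTIALS = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1),
}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass
class Alignment:
    """Taxon-indexed site patterns with multiplicities.

    Attributes
    ----------
    taxa : list of str
        Unique taxon labels, in input order.
    patterns : list of str
        Distinct alignment columns; ``patterns[p][i]`` is the symbol for
        taxon ``i`` at pattern ``p``.
    pattern_weights : ndarray of int
        Number of alignment sites exhibiting each pattern.
    site_count : int
        Total number of sites; equals ``sum(pattern_weights)``.
    """

    taxa: list
    patterns: list
    pattern_weights: np.ndarray
    site_count: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.pattern_weights = np.asarray(self.pattern_weights, dtype=int)
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        for p in self.patterns:
            if len(p) != len(self.taxa):
                raise AlignmentError("pattern length does not match taxon count")
        if int(self.pattern_weights.sum()) != self.site_count:
            raise AlignmentError("pattern weights do not sum to site count")
        self._index = {name: i for i, name in enumerate(self.taxa)}

    @classmethod
    def from_sequences(cls, taxa, sequences) -> "Alignment":
        """Compress equal-length sequences into weighted site patterns."""
        if len(taxa) != len(sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon labels")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        (n_sites,) = lengths
        if n_sites == 0:
            raise AlignmentError("empty alignment")
        counts: dict = {}
        order = []
        seqs = [s.upper() for s in sequences]
        for site in range(n_sites):
            col = "".join(s[site] for s in seqs)
            if col not in counts:
                counts[col] = 0
                order.append(col)
            counts[col] += 1
        return cls(list(taxa), order, np.array([counts[c] for c in order]), n_sites)

    def sequences(self) -> list:
        """Expand patterns back to full sequences (column order is the
        pattern discovery order, not the original site order)."""
        out = []
        for i in range(len(self.taxa)):
            parts = []
            for p, w in zip(self.patterns, self.pattern_weights):
                parts.append(p[i] * int(w))
            out.append("".join(parts))
        return out

    def tip_partials(self, taxon: str) -> np.ndarray:
        """(n_patterns, 4) indicator/ambiguity partial vectors for a taxon."""
        i = self._index[taxon]
        arr = np.empty((len(self.patterns), 4))
        for p, col in enumerate(self.patterns):
            sym = col[i]
            try:
                arr[p] = _PARTIALS[sym]
            except KeyError:
                raise AlignmentError(f"unknown state symbol {sym!r} for taxon {taxon}")
        return arr


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into a compressed :class:`Alignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    taxa = [r.id for r in records]
    return Alignment.from_sequences(taxa, [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(aln.taxa, aln.sequences())
    ]
    SeqIO.write(records, str(path), "fasta")
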