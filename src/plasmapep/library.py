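"""Non-redundant protein library with gene-symbol annotation.

The library is the lookup structure for everything downstream of the search
engines: accession -> gene symbol mapping, and the fully tryptic peptide
space used to validate peptide-spectrum matches.  Endogenous "tryptic"
peptides are defined by cleavage after K/R: a peptide is fully tryptic in a
protein when its in-protein context is preceded by K, R or the protein
N-terminus and it ends in K, R or at the protein C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class UnknownAccessionError(KeyError):
    """An accession was not found in the protein library."""


@dataclass(frozen=True)
class ProteinLibraryEntry:
    """One protein chain: accession, owning gene symbol and sequence."""

    accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        bad = set(self.sequence) - _AA20
        if bad:
            raise ValueError(
                f"accession {self.accession!r}: non-standard residues {sorted(bad)}"
            )


def tryptic_peptides(
    sequence: str,
    *,
    min_len: int = 6,
    max_len: int = 30,
    missed_cleavages: int = 2,
) -> Iterator[str]:
    """Yield fully tryptic peptides of ``sequence`` (cleavage after K/R).

    Peptides are emitted in order of their start position, allowing up to
    ``missed_cleavages`` internal K/R sites, restricted to the length window
    ``[min_len, max_len]``.  Duplicates are possible when the protein repeats
    a peptide; callers wanting a set should collect into one.
    """
    cuts = [0] + [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            pep = sequence[cuts[i] : cuts[j]]
            if min_len <= len(pep) <= max_len:
                yield pep


class ProteinLibrary:
    """A set of :class:`ProteinLibraryEntry` indexed by accession.

    One gene symbol may own several accessions (splice/assembly variants);
    accessions are unique.
    """

    def __init__(self, entries: Iterable[ProteinLibraryEntry]) -> None:
        self._entries = list(entries)
        self._by_accession: dict[str, ProteinLibraryEntry] = {}
        for e in self._entries:
            if e.accession in self._by_accession:
                raise ValueError(f"duplicate accession {e.accession!r}")
            self._by_accession[e.accession] = e
        self._peptide_index: dict[str, tuple[str, ...]] | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ProteinLibraryEntry]:
        return iter(self._entries)

    @property
    def entries(self) -> list[ProteinLibraryEntry]:
        return list(self._entries)

    def __getitem__(self, accession: str) -> ProteinLibraryEntry:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise UnknownAccessionError(
                f"accession {accession!r} not in protein library"
            ) from None

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def gene_symbols(self) -> list[str]:
        return sorted({e.gene_symbol for e in self._entries})

    def symbol_of(self, accession: str) -> str:
        return self[accession].gene_symbol

    def accessions_for(self, gene_symbol: str) -> list[str]:
        return [e.accession for e in self._entries if e.gene_symbol == gene_symbol]

    # -- tryptic peptide space ------------------------------------------------

    def peptide_index(
        self,
        *,
        min_len: int = 6,
        max_len: int = 30,
        missed_cleavages: int = 2,
    ) -> dict[str, tuple[str, ...]]:
        """Map every fully tryptic peptide to the accessions containing it.

        Cached on first call with the default parameters.
        """
        default = (min_len, max_len, missed_cleavages) == (6, 30, 2)
        if default and self._peptide_index is not None:
            return self._peptide_index
        index: dict[str, set[str]] = {}
        for e in self._entries:
            for pep in tryptic_peptides(
                e.sequence,
                min_len=min_len,
                max_len=max_len,
                missed_cleavages=missed_cleavages,
            ):
                index.setdefault(pep, set()).add(e.accession)
        frozen = {p: tuple(sorted(a)) for p, a in index.items()}
        if default:
            self._peptide_index = frozen
        return frozen

    def is_fully_tryptic(self, peptide: str, accession: str) -> bool:
        """True when ``peptide`` occurs in ``accession`` with tryptic context."""
        seq = self[accession].sequence
        start = seq.find(peptide)
        while start != -1:
            end = start + len(peptide)
            nterm_ok = start == 0 or seq[start - 1] in "KR"
            cterm_ok = end == len(seq) or peptide[-1] in "KR"
            if nterm_ok and cterm_ok:
                return True
            start = seq.find(peptide, start + 1)
        return False

    # -- FASTA ----------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Write the library as FASTA with ``>ACCESSION GN=SYMBOL`` headers."""
        records = [
            SeqRecord(Seq(e.sequence), id=e.accession, description=f"GN={e.gene_symbol}")
            for e in self._entries
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinLibrary":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            symbol = rec.id
            for token in rec.description.split():
                if token.startswith("GN="):
                    symbol = token[3:]
                    break
            entries.append(
                ProteinLibraryEntry(
                    accession=rec.id, gene_symbol=symbol, sequence=str(rec.seq)
                )
            )
        return cls(entries)
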