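"""Six-frame open-reading-frame mining with a small-peptide size filter.

Pheromone precursor genes in basidiomycete *B* loci are short, intron-free
ORFs (tens of codons), so candidate discovery is a plain six-frame scan:
every ATG-initiated, first-in-frame-stop-terminated span whose translated
peptide falls inside a size window is reported.  No nested/overlapping ORF
suppression is applied — downstream motif filters do the selecting, and for
locus curation recall matters more than parsimony.

Coordinates are 1-based inclusive on the forward strand of the contig
(physical-map dialect); the coding orientation is carried by ``strand``.
The genomic span includes the stop codon, so ``(end - start + 1)/3`` equals
the peptide length plus one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_DNA_RE = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return dna.translate(_COMPLEMENT)[::-1]


def _validate_dna(dna: str, *, what: str = "sequence") -> str:
    dna = dna.upper()
    if not _DNA_RE.match(dna):
        bad = sorted(set(dna) - set("ACGTN"))
        raise ValueError(
            f"{what} contains non-DNA symbols {bad}; allowed alphabet is A,C,G,T,N"
        )
    return dna


@dataclass(frozen=True)
class Contig:
    """A genomic contig (e.g. a sequenced fosmid insert).

    ``source`` records provenance (file name, accession, or 'synthetic').
    """

    id: str
    sequence: str
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_dna(self.sequence, what=f"contig {self.id}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """A translated ORF with forward-strand genomic coordinates.

    ``start <= end`` always; ``frame`` is the 0-based reading offset on the
    ORF's own strand.  ``peptide`` excludes the terminal stop.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    peptide: str

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


def translate(dna: str, code: str | int = "Standard") -> str:
    """Translate DNA to protein under the given genetic code.

    Stop codons map to ``*``.  Codons containing N map to ``X`` unless the
    ambiguity is silent (e.g. GCN → A).  A trailing partial codon (1–2 nt)
    is silently dropped; the empty string translates to the empty string.
    Symbols outside {A,C,G,T,N} are rejected.
    """
    dna = _validate_dna(dna, what="input")
    usable = len(dna) - (len(dna) % 3)
    if usable == 0:
        return ""
    return str(Seq(dna[:usable]).translate(table=code))


def six_frame_orfs(contig: Contig, min_aa: int = 10, max_aa: int = 100) -> list[Orf]:
    """All ATG→first-stop ORFs on both strands with peptide length in [min_aa, max_aa].

    Every in-frame ATG upstream of a stop is reported as its own candidate
    (no nested-ORF suppression).  ORFs running off the contig end without a
    stop codon are not reported.  Peptide length counts the initiator Met
    and excludes the stop.
    """
    if not 1 <= min_aa <= max_aa:
        raise ValueError(f"require 1 <= min_aa <= max_aa, got [{min_aa}, {max_aa}]")
    seq = contig.sequence
    L = len(seq)
    out: list[Orf] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            pep = translate(s[frame:])
            block_start = 0
            for t, ch in enumerate(pep):
                if ch != "*":
                    continue
                for p in range(block_start, t):
                    if pep[p] != "M":
                        continue
                    aa_len = t - p
                    if not min_aa <= aa_len <= max_aa:
                        continue
                    s0 = frame + 3 * p            # 0-based on this strand
                    e0 = frame + 3 * (t + 1) - 1  # includes stop codon
                    if strand == "+":
                        start, end = s0 + 1, e0 + 1
                    else:
                        start, end = L - e0, L - s0
                    out.append(Orf(contig.id, start, end, strand, frame, pep[p:t]))
                block_start = t + 1
    out.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return out


def read_fasta_contigs(path: str | Path, source: str | None = None) -> list[Contig]:
    """Load contigs from a (multi-record, wrapped or unwrapped) FASTA file."""
    path = Path(path)
    src = source if source is not None else path.name
    records = [Contig(r.id, str(r.seq), source=src) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def orf_table(orfs: Iterable[Orf]) -> pd.DataFrame:
    """Tabulate ORFs as contig_id,start,end,strand,frame,length_aa,peptide."""
    rows = [
        (o.contig_id, o.start, o.end, o.strand, o.frame, o.length_aa, o.peptide)
        for o in orfs
    ]
    return pd.DataFrame(
        rows, columns=["contig_id", "start", "end", "strand", "frame", "length_aa", "peptide"]
    )


def write_orf_table(orfs: Iterable[Orf], path: str | Path) -> None:
    orf_table(orfs).to_csv(path, index=False)


def write_protein_fasta(named_peptides: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, peptide) pairs as an unwrapped protein FASTA."""
    with open(path, "w") as fh:
        for name, pep in named_peptides:
            fh.write(f">{name}\n{pep}\n")
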