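"""Physical-map assembly: contig merging, feature placement, span metrics.

A ~60-kb mating-type locus carried on two overlapping large-insert clones
is reconstructed by exact suffix/prefix overlap (same genome, so no
mismatch tolerance), typed gene features are placed on the merged
assembly, the span of the mating genes (pheromones + receptors only) is
measured, and the marker amplicon is localised by exact in-silico PCR.

All public coordinates are 1-based inclusive (the dialect of printed gene
tables); the BED writer converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from b3locus.orfs import Contig, reverse_complement

MATING_KINDS = frozenset({"pheromone", "receptor"})
VALID_KINDS = frozenset({"pheromone", "receptor", "other"})


@dataclass(frozen=True)
class LocusAssembly:
    """Two contigs merged over an exact overlap.

    ``contig_offsets`` maps contig id to its 1-based placement on the
    merged sequence; ``len(merged) = len(a) + len(b) - overlap_len``.
    """

    sequence: str
    contig_offsets: dict[str, int]
    overlap_len: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    name: str
    kind: str
    start: int
    end: int
    strand: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {sorted(VALID_KINDS)}, got {self.kind!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad coordinates {self.start}-{self.end} for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class LocusMap:
    """An ordered set of typed features on an assembly (or bare length)."""

    features: tuple[GeneFeature, ...]
    assembly: LocusAssembly | None = None
    assembly_len: int | None = None
    scar_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        length = self.length
        if length is not None:
            for f in self.features:
                if f.end > length:
                    raise ValueError(
                        f"feature {f.name} ({f.start}-{f.end}) outside assembly of length {length}"
                    )

    @property
    def length(self) -> int | None:
        if self.assembly is not None:
            return len(self.assembly)
        return self.assembly_len

    @property
    def mating_span_nt(self) -> int:
        return mating_span(self.features)


def merge_contigs(a: Contig, b: Contig, min_overlap: int = 100) -> LocusAssembly:
    """Merge by the longest exact suffix(a)/prefix(b) match >= min_overlap.

    Both orientations of ``b`` are tried.  Raises with the best candidate
    overlap found if none reaches ``min_overlap``.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("both contigs must be non-empty")
    best_len, best_seq_b = 0, None
    for seq_b in (b.sequence, reverse_complement(b.sequence)):
        ov = _longest_suffix_prefix(a.sequence, seq_b)
        if ov > best_len:
            best_len, best_seq_b = ov, seq_b
    if best_len < min_overlap:
        raise ValueError(
            f"no suffix/prefix overlap >= {min_overlap} nt between {a.id} and {b.id} "
            f"(best candidate: {best_len} nt)"
        )
    merged = a.sequence + best_seq_b[best_len:]
    return LocusAssembly(
        sequence=merged,
        contig_offsets={a.id: 1, b.id: len(a.sequence) - best_len + 1},
        overlap_len=best_len,
    )


def _longest_suffix_prefix(a: str, b: str) -> int:
    """Longest L such that a[-L:] == b[:L] (exact)."""
    max_l = min(len(a), len(b))
    # seed-and-verify: any suffix/prefix match of length >= 12 must place
    # b's first 12-mer inside a; shorter overlaps checked directly.
    seed_len = min(12, max_l)
    seed = b[:seed_len]
    best = 0
    start = 0
    while True:
        pos = a.find(seed, start)
        if pos == -1:
            break
        L = len(a) - pos
        if L <= max_l and a[pos:] == b[:L]:
            best = max(best, L)
        start = pos + 1
    if best == 0 and seed_len < 12:
        for L in range(max_l, 0, -1):
            if a[-L:] == b[:L]:
                return L
    return best


def mating_span(features: Iterable[GeneFeature]) -> int:
    """Inclusive nt span over pheromone + receptor features only.

    Order-invariant; non-mating features are ignored.  Raises if no
    mating-typed feature is present.
    """
    mating = [f for f in features if f.kind in MATING_KINDS]
    if not mating:
        raise ValueError("no pheromone/receptor features to span")
    return max(f.end for f in mating) - min(f.start for f in mating) + 1


@dataclass(frozen=True)
class AmpliconResult:
    """In-silico PCR products; ``interval`` is the outermost product."""

    interval: tuple[int, int]
    products: tuple[tuple[int, int], ...]
    multiple: bool


def locate_amplicon(
    primer_fwd: str, primer_rev: str, assembly: LocusAssembly | str
) -> AmpliconResult | None:
    """Exact-match in-silico PCR on the merged assembly.

    The forward primer anneals on the + strand and the reverse primer's
    reverse complement must occur downstream on the + strand (the
    mirrored orientation, forward primer on the - strand, is also tried).
    Returns the outermost product interval (1-based inclusive, primer
    ends included); multiple products are all returned and flagged.  No
    mismatches are tolerated.  Returns None if there is no product.
    """
    seq = assembly.sequence if isinstance(assembly, LocusAssembly) else assembly
    fwd = primer_fwd.upper()
    rev = primer_rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    products: set[tuple[int, int]] = set()
    for p_left, p_right in ((fwd, reverse_complement(rev)), (rev, reverse_complement(fwd))):
        lefts = _find_all(seq, p_left)
        rights = _find_all(seq, p_right)
        for ls in lefts:
            for rs in rights:
                prod_end = rs + len(p_right)  # 0-based exclusive
                if ls < rs and prod_end > ls + len(p_left):
                    products.add((ls + 1, prod_end))  # 1-based inclusive
    if not products:
        return None
    ordered = tuple(sorted(products))
    outer = (min(p[0] for p in ordered), max(p[1] for p in ordered))
    return AmpliconResult(outer, ordered, len(ordered) > 1)


def _find_all(hay: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        pos = hay.find(needle, start)
        if pos == -1:
            return out
        out.append(pos)
        start = pos + 1


# ---------------------------------------------------------------------------
# annotation IO: GFF3 (1-based inclusive), BED (0-based half-open), CSV

def write_annotation(
    locus_map: LocusMap, path: str | Path, fmt: str, seqid: str = "B3_locus"
) -> None:
    """Write the feature map as GFF3, BED or CSV.

    Coordinate conversion is handled only here: GFF3 and CSV carry the
    1-based inclusive coordinates verbatim; BED converts to 0-based
    half-open.  Features outside the assembly are refused at LocusMap
    construction.  An empty feature list yields a valid header-only file.
    """
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            if locus_map.length is not None:
                fh.write(f"##sequence-region {seqid} 1 {locus_map.length}\n")
            for f in locus_map.features:
                attrs = f"ID={f.name};kind={f.kind}"
                if f.note:
                    attrs += f";note={f.note.replace(';', ',')}"
                fh.write(
                    f"{seqid}\tb3locus\t{f.kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )
    elif fmt == "BED":
        with open(path, "w") as fh:
            for f in locus_map.features:
                fh.write(f"{seqid}\t{f.start - 1}\t{f.end}\t{f.name}\t0\t{f.strand}\n")
    elif fmt == "CSV":
        pd.DataFrame(
            [
                {"name": f.name, "kind": f.kind, "start": f.start, "end": f.end,
                 "strand": f.strand, "note": f.note}
                for f in locus_map.features
            ],
            columns=["name", "kind", "start", "end", "strand", "note"],
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (use GFF3, BED or CSV)")


def read_annotation(path: str | Path, fmt: str) -> list[GeneFeature]:
    """Read features back; the GFF3/CSV round trip is lossless, BED loses kind/note."""
    fmt = fmt.upper()
    path = Path(path)
    features: list[GeneFeature] = []
    if fmt == "GFF3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                features.append(
                    GeneFeature(
                        name=attrs.get("ID", cols[2]),
                        kind=cols[2],
                        start=int(cols[3]),
                        end=int(cols[4]),
                        strand=cols[6],
                        note=attrs.get("note", ""),
                    )
                )
    elif fmt == "BED":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                features.append(
                    GeneFeature(
                        name=cols[3], kind="other",
                        start=int(cols[1]) + 1, end=int(cols[2]), strand=cols[5],
                    )
                )
    elif fmt == "CSV":
        df = pd.read_csv(path, keep_default_na=False)
        for row in df.itertuples(index=False):
            features.append(
                GeneFeature(row.name, row.kind, int(row.start), int(row.end),
                            row.strand, str(row.note))
            )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return features


def load_table2_features() -> list[GeneFeature]:
    """The packaged locus gene table (printed physical-map coordinates).

    Eight mating genes (four pheromones, four receptors) plus flanking
    homolog ORFs; strands are not given in the printed table and default
    to '+'.
    """
    ref = resources.files("b3locus").joinpath("data/table2_features.csv")
    with resources.as_file(ref) as path:
        return read_annotation(path, "CSV")


def read_primers_csv(path: str | Path) -> tuple[str, str]:
    """Read a 2-column primer CSV (name,sequence); returns (fwd, rev)."""
    with open(path) as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    seqs = [r[1].strip().upper() for r in rows if len(r) >= 2 and r[1].strip()]
    seqs = [s for s in seqs if set(s) <= set("ACGTN")]
    if len(seqs) < 2:
        raise ValueError(f"expected two primer sequences in {path}")
    return seqs[0], seqs[1]
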