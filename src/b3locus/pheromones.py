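"""Pheromone precursor classification and mature-peptide prediction.

Basidiomycete mating pheromones are made as short precursors (here 57–61
aa) that end in a CaaX prenylation motif: the Cys four residues from the
C-terminus is farnesylated and the three terminal residues are removed.
The mature lipopeptide is excised further upstream at a processing site
marked by an ER or TR doublet, with a conserved Pro four residues and an
Asp/Asn two residues N-terminal of the doublet's Arg.  The mature peptide
runs from just after the doublet through the farnesylated Cys and is
typically 12–13 residues (9–15 across related species).

Conventions
-----------
* Offsets from the C-terminus count the terminal residue as 1, so the CaaX
  Cys sits at offset 4.
* ``doublet_end_offset`` is the offset of the doublet's *second* residue
  (the R); the predicted mature length is ``doublet_end_offset - 4``.
* Context positions are counted from the R: Pro at R−4, Asp/Asn at R−2.
* The two "a" positions of CaaX are unconstrained (CXXX usage: CVCH, CVRG,
  CVVA are all accepted), so only the Cys at offset 4 is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from b3locus.orfs import Orf

#: doublet_end_offset search window giving mature lengths 9–15
DEFAULT_WINDOW: tuple[int, int] = (13, 19)
#: accepted mature-peptide lengths (aa)
DEFAULT_ACCEPT_LEN: tuple[int, int] = (9, 15)
#: small-ORF size filter (aa, Met included, stop excluded)
DEFAULT_SIZE_RANGE: tuple[int, int] = (10, 100)
#: full consensus grammar: doublet + Pro(R-4) + D/N(R-2)
DEFAULT_MIN_SCORE: int = 3


@dataclass(frozen=True)
class CaaxMotif:
    motif: str
    cys_offset: int = 4

    def __post_init__(self) -> None:
        if len(self.motif) != 4 or self.motif[0] != "C" or self.cys_offset != 4:
            raise ValueError(f"invalid CaaX motif {self.motif!r}")


@dataclass(frozen=True)
class CleavageSite:
    doublet: str                # 'ER' or 'TR'
    doublet_end_offset: int     # offset of the R from the C-terminus
    has_pro_minus4: bool
    has_dn_minus2: bool
    score: int

    def __post_init__(self) -> None:
        if self.doublet_end_offset <= 4:
            raise ValueError("cleavage must precede the CaaX Cys (offset > 4)")


@dataclass(frozen=True)
class PheromonePrecursor:
    orf: Orf
    caax: CaaxMotif
    sites: tuple[CleavageSite, ...]
    chosen_site: CleavageSite | None = None
    mature_peptide: str | None = None

    @property
    def mature_length(self) -> int | None:
        return None if self.mature_peptide is None else len(self.mature_peptide)


def find_caax(peptide: str) -> CaaxMotif | None:
    """Return the C-terminal CaaX motif, or None.

    Only the Cys at the 4th position from the C-terminus is required.
    """
    if len(peptide) < 4:
        return None
    tail = peptide[-4:]
    return CaaxMotif(tail) if tail[0] == "C" else None


def enumerate_cleavage_sites(
    peptide: str, window: tuple[int, int] = DEFAULT_WINDOW
) -> list[CleavageSite]:
    """All ER/TR doublets whose R lies in the offset window, scored.

    Score = 1 for the doublet plus 1 each for Pro at R−4 and Asp/Asn at
    R−2.  Sorted by descending score, ties toward the smaller offset
    (shortest mature peptide first).
    """
    lo, hi = window
    if lo <= 4:
        raise ValueError("window must keep the cut upstream of the CaaX Cys (offset > 4)")
    n = len(peptide)
    sites: list[CleavageSite] = []
    for d in range(lo, hi + 1):
        i_r = n - d  # 0-based index of the doublet's second residue
        if i_r < 1:
            continue
        if peptide[i_r] != "R" or peptide[i_r - 1] not in "ET":
            continue
        pro = i_r - 4 >= 0 and peptide[i_r - 4] == "P"
        dn = i_r - 2 >= 0 and peptide[i_r - 2] in "DN"
        doublet = peptide[i_r - 1] + "R"
        sites.append(CleavageSite(doublet, d, pro, dn, 1 + int(pro) + int(dn)))
    sites.sort(key=lambda s: (-s.score, s.doublet_end_offset))
    return sites


def predict_mature(
    precursor: PheromonePrecursor,
    accept_len: tuple[int, int] = DEFAULT_ACCEPT_LEN,
) -> PheromonePrecursor:
    """Choose the cleavage site and fill in the mature peptide.

    The top-scoring site whose mature length (doublet_end_offset − 4)
    falls in ``accept_len`` wins; the mature peptide is the residues
    strictly after the doublet through the CaaX Cys inclusive, so it
    always ends in Cys.  If no site yields an acceptable length the
    precursor is returned with chosen_site and mature_peptide unset.
    """
    if not precursor.sites:
        raise ValueError("precursor has no cleavage sites to choose from")
    pep = precursor.orf.peptide
    lo, hi = accept_len
    for site in precursor.sites:  # already sorted (score desc, offset asc)
        m = site.doublet_end_offset - 4
        if lo <= m <= hi:
            i_r = len(pep) - site.doublet_end_offset
            mature = pep[i_r + 1 : len(pep) - 3]
            assert mature.endswith("C") and len(mature) == m
            return replace(precursor, chosen_site=site, mature_peptide=mature)
    return replace(precursor, chosen_site=None, mature_peptide=None)


def classify_pheromone(
    orf: Orf,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    window: tuple[int, int] = DEFAULT_WINDOW,
    accept_len: tuple[int, int] = DEFAULT_ACCEPT_LEN,
    strict: bool = True,
    min_site_score: int = DEFAULT_MIN_SCORE,
) -> PheromonePrecursor | None:
    """Classify an ORF as a pheromone precursor, or return None.

    Requirements: peptide length inside ``size_range`` and a C-terminal
    CaaX motif.  In strict mode a chosen cleavage site with score >=
    ``min_site_score`` is also required (the default demands the full
    consensus: doublet plus both context residues; ``min_site_score=1``
    accepts any in-window doublet).  Permissive mode reports CaaX-only
    candidates with whatever cleavage evidence exists.
    """
    pep = orf.peptide
    if not size_range[0] <= len(pep) <= size_range[1]:
        return None
    caax = find_caax(pep)
    if caax is None:
        return None
    sites = tuple(enumerate_cleavage_sites(pep, window))
    precursor = PheromonePrecursor(orf, caax, sites)
    if sites:
        precursor = predict_mature(precursor, accept_len)
    if strict:
        if precursor.chosen_site is None or precursor.chosen_site.score < min_site_score:
            return None
    return precursor


def align_precursors(precursors: Sequence[PheromonePrecursor]) -> str:
    """C-terminal-anchored text alignment of precursor peptides.

    A display aid (not an MSA): rows are right-aligned so the CaaX columns
    coincide; the mature segment of each row is upper-case with the rest
    lower-case, and a ruler marks the doublet and Cys columns of the first
    row.  Requires at least two precursors.
    """
    if len(precursors) < 2:
        raise ValueError("need at least 2 precursors to align")
    peps = [p.orf.peptide for p in precursors]
    names = [f"{p.orf.contig_id}:{p.orf.start}-{p.orf.end}" for p in precursors]
    width = max(len(p) for p in peps)
    name_w = max(len(n) for n in names)
    lines = []
    for p, pep, name in zip(precursors, peps, names):
        row = pep.rjust(width)
        if p.chosen_site is not None:
            # mature segment upper-case, remainder lower-case
            i_r = len(pep) - p.chosen_site.doublet_end_offset
            body = pep[: i_r + 1].lower() + pep[i_r + 1 : len(pep) - 3] + pep[len(pep) - 3 :].lower()
            row = body.rjust(width)
        lines.append(f"{name.ljust(name_w)}  {row}")
    ruler = [" "] * width
    ruler[width - 4] = "^"  # CaaX Cys column
    first = precursors[0]
    if first.chosen_site is not None:
        d = first.chosen_site.doublet_end_offset
        ruler[width - d] = "*"       # doublet R
        ruler[width - d - 1] = "*"   # doublet E/T
    lines.append(" " * name_w + "  " + "".join(ruler))
    return "\n".join(lines)


def precursor_table(precursors: Iterable[PheromonePrecursor]) -> pd.DataFrame:
    """Report table: ORF coordinates, motif, doublet, offsets, mature peptide."""
    rows = []
    for p in precursors:
        s = p.chosen_site
        rows.append(
            {
                "contig_id": p.orf.contig_id,
                "start": p.orf.start,
                "end": p.orf.end,
                "strand": p.orf.strand,
                "length_aa": p.orf.length_aa,
                "caax": p.caax.motif,
                "doublet": s.doublet if s else None,
                "doublet_end_offset": s.doublet_end_offset if s else None,
                "site_score": s.score if s else None,
                "mature_peptide": p.mature_peptide,
                "mature_length": p.mature_length,
            }
        )
    return pd.DataFrame(rows)
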