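"""Truth-labelled synthetic locus generator.

Emulates the structure of a basidiomycete *B* mating-type locus as used
throughout the test suite: a ~60-kb region carried on two overlapping
contigs (40.4 kb + 32.7 kb sharing a 13.1-kb exact overlap), four
intron-free pheromone precursor genes (57–61 codons with the full
CaaX/cleavage grammar), four receptor genes whose translations carry
exactly seven 21-residue hydrophobic stretches with configurable
C-terminal tail lengths, grammar-ablated decoy ORFs in the flanks, a
marker amplicon with its primer pair, and replicate qRT-PCR Ct tables
with injected fold effects and Gaussian cycle noise.

Background sequence is i.i.d. at a configurable GC content; repeats,
introns and sequencing error are deliberately not modelled.  Two
compositional constraints keep the embedded truth unambiguous: precursor
peptides contain no internal Met (so each gene yields a single
ATG-initiated candidate per termination site) and the mature body
contains no Arg (so the truth doublet is the unique in-window cleavage
site).  All randomness flows from a single seeded generator, so a given
spec + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from b3locus.expression import CtRecord
from b3locus.locusmap import GeneFeature, LocusMap, write_annotation
from b3locus.orfs import Contig, reverse_complement

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_STANDARD.stop_codons)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_POOL_NO_M = [a for a in _AA20 if a != "M"]
_POOL_NO_MR = [a for a in _AA20 if a not in "MR"]
_POOL_NO_MC = [a for a in _AA20 if a not in "MC"]
_POOL_NO_MRC = [a for a in _AA20 if a not in "MRC"]
_HYDROPHOBIC = list("ILVFAM")
_HYDROPHILIC = list("RKDESTNQGP")

#: mating-gene layout: (name, kind, start, strand); printed physical-map
#: start coordinates of the four pheromone and four receptor genes
DEFAULT_LAYOUT: tuple[tuple[str, str, int, str], ...] = (
    ("PEphb3.1", "pheromone", 26325, "+"),
    ("PEphb3.2", "pheromone", 27056, "-"),
    ("PESTE3.3.1", "receptor", 28186, "+"),
    ("PEphb3.3", "pheromone", 29629, "+"),
    ("PESTE3.3.2", "receptor", 30416, "-"),
    ("PESTE3.3.3", "receptor", 32405, "+"),
    ("PEphb3.4", "pheromone", 35693, "-"),
    ("PESTE3.3.4", "receptor", 36579, "+"),
)

#: receptor protein lengths (aa) and C-tail lengths (aa), per gene
DEFAULT_RECEPTOR_LENS: tuple[int, ...] = (328, 420, 558, 470)
DEFAULT_RECEPTOR_TAILS: tuple[int, ...] = (34, 100, 150, 120)

#: injected monokaryon/dikaryon folds; the 1.0 is a null gene whose
#: expression does not differ between nuclear states
DEFAULT_FOLD_MAP: dict[str, float] = {
    "PEphb3.1": 1.5,
    "PEphb3.2": 31.4,
    "PEphb3.3": 5.0,
    "PEphb3.4": 8.0,
    "PESTE3.3.1": 3.8,
    "PESTE3.3.2": 1.0,
    "PESTE3.3.3": 9.0,
    "PESTE3.3.4": 12.2,
}


@dataclass(frozen=True)
class LocusSpec:
    """Generation parameters; defaults are the study conditions."""

    layout: tuple[tuple[str, str, int, str], ...] = DEFAULT_LAYOUT
    precursor_len_range: tuple[int, int] = (57, 61)
    mature_len_range: tuple[int, int] = (12, 13)
    tm_count: int = 7
    tm_len: int = 21
    receptor_lens: tuple[int, ...] = DEFAULT_RECEPTOR_LENS
    receptor_tail_lens: tuple[int, ...] = DEFAULT_RECEPTOR_TAILS
    locus_len: int = 60_000
    contig_split: tuple[int, int, int] = (40_400, 32_700, 13_100)  # len_a, len_b, overlap
    background_gc: float = 0.50
    decoy_count: int = 6
    fold_map: tuple[tuple[str, float], ...] = tuple(DEFAULT_FOLD_MAP.items())
    ct_noise_sd: float = 0.1
    ct_replicates: int = 3
    efficiency: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        len_a, len_b, overlap = self.contig_split
        if len_a + len_b - overlap != self.locus_len:
            raise ValueError(
                f"contig split {self.contig_split} inconsistent with locus length {self.locus_len}"
            )
        if overlap >= min(len_a, len_b):
            raise ValueError("overlap must be shorter than both contigs")


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for every embedded gene."""

    features: tuple[GeneFeature, ...]
    decoy_features: tuple[GeneFeature, ...]
    precursor_peptides: dict[str, str]
    mature_peptides: dict[str, str]
    tm_segments: dict[str, tuple[tuple[int, int], ...]]  # protein coords, 1-based
    tail_lens: dict[str, int]
    fold_map: dict[str, float]


@dataclass(frozen=True)
class SyntheticLocus:
    spec: LocusSpec
    assembly_seq: str
    contig_a: Contig
    contig_b: Contig
    truth: TruthSet
    primer_fwd: str
    primer_rev: str
    amplicon: tuple[int, int]
    ct_records: tuple[CtRecord, ...]


def _codons_for(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide
    )


def _draw(rng: np.random.Generator, pool: Sequence[str], n: int) -> str:
    return "".join(pool[i] for i in rng.integers(len(pool), size=n))


def generate_precursor_gene(
    rng: np.random.Generator,
    length_range: tuple[int, int] = (57, 61),
    mature_range: tuple[int, int] = (12, 13),
    window: tuple[int, int] = (13, 19),
) -> tuple[str, dict]:
    """One intron-free pheromone precursor gene (CDS incl. stop) + truth.

    Peptide layout (N→C): Met, filler, Pro, x, Asp/Asn, Glu/Thr, Arg,
    mature body, Cys, a, a, X — i.e. the full consensus grammar with the
    doublet placed so the mature peptide (doublet-adjacent through the
    CaaX Cys) has a length drawn from ``mature_range``.  No internal Met
    anywhere; no Arg in the mature body or at in-window context spots, so
    the truth site is the unique in-window doublet.
    """
    L = int(rng.integers(length_range[0], length_range[1] + 1))
    m = int(rng.integers(mature_range[0], mature_range[1] + 1))
    if not window[0] <= m + 4 <= window[1]:
        raise ValueError(f"mature length {m} puts the doublet outside window {window}")
    filler_len = L - 9 - m
    if filler_len < 0:
        raise ValueError(f"precursor length {L} cannot host a {m}-aa mature peptide")
    # filler residues whose C-terminal offset falls inside the doublet
    # search window (or just above it) must avoid Arg
    filler = []
    for k in range(filler_len):
        offset = L - 1 - k  # C-terminal offset of this filler residue
        pool = _POOL_NO_MR if offset <= window[1] + 1 else _POOL_NO_M
        filler.append(_draw(rng, pool, 1))
    doublet_first = "ET"[rng.integers(2)]
    dn = "DN"[rng.integers(2)]
    mature_body = _draw(rng, _POOL_NO_MR, m - 1)
    caax_tail = _draw(rng, _POOL_NO_MR, 3)
    peptide = (
        "M" + "".join(filler)
        + "P" + _draw(rng, _POOL_NO_MR, 1) + dn + doublet_first + "R"
        + mature_body + "C" + caax_tail
    )
    assert len(peptide) == L
    mature = mature_body + "C"
    dna = _codons_for(rng, peptide) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    truth = {
        "peptide": peptide,
        "mature_peptide": mature,
        "mature_length": m,
        "doublet": doublet_first + "R",
        "doublet_end_offset": m + 4,
        "caax": peptide[-4:],
    }
    return dna, truth


def generate_receptor_gene(
    rng: np.random.Generator,
    length_aa: int,
    c_tail_len: int,
    n_tail_len: int = 20,
    tm_len: int = 21,
    tm_count: int = 7,
    min_loop: int = 12,
) -> tuple[str, dict]:
    """One intron-free receptor CDS (incl. stop) + truth TM coordinates.

    The translation is Met + hydrophilic N-tail, ``tm_count`` hydrophobic
    stretches of ``tm_len`` residues (I/L/V/F/A/M) separated by
    hydrophilic loops (R/K/D/E/S/T/N/Q/G/P), and a hydrophilic C-tail of
    ``c_tail_len`` residues.  Loop lengths absorb the length budget.
    """
    if c_tail_len < 0:
        raise ValueError("tail length must be >= 0")
    n_loops = tm_count - 1
    budget = length_aa - n_tail_len - tm_count * tm_len - c_tail_len
    if budget < n_loops * min_loop:
        raise ValueError(
            f"receptor of {length_aa} aa cannot host {tm_count}x{tm_len} TM "
            f"with tails {n_tail_len}/{c_tail_len} and loops >= {min_loop}"
        )
    base, rem = divmod(budget, n_loops)
    loop_lens = [base + 1] * rem + [base] * (n_loops - rem)
    parts = ["M" + _draw(rng, _HYDROPHILIC, n_tail_len - 1)]
    segments = []
    pos = n_tail_len
    for i in range(tm_count):
        segments.append((pos + 1, pos + tm_len))
        parts.append(_draw(rng, _HYDROPHOBIC, tm_len))
        pos += tm_len
        if i < n_loops:
            parts.append(_draw(rng, _HYDROPHILIC, loop_lens[i]))
            pos += loop_lens[i]
    parts.append(_draw(rng, _HYDROPHILIC, c_tail_len))
    peptide = "".join(parts)
    assert len(peptide) == length_aa
    dna = _codons_for(rng, peptide) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    truth = {
        "peptide": peptide,
        "tm_segments": tuple(segments),
        "c_tail_len": c_tail_len,
        "n_tail_len": n_tail_len,
    }
    return dna, truth


def _decoy_caax_no_doublet(rng: np.random.Generator, length: int) -> str:
    """Small peptide with a CaaX motif but no E/T–R pair anywhere."""
    return "M" + _draw(rng, _POOL_NO_MR, length - 5) + "C" + _draw(rng, _POOL_NO_MR, 3)


def _decoy_doublet_no_caax(rng: np.random.Generator, length: int) -> str:
    """Small peptide with a well-placed scored doublet but no Cys at -4."""
    m = 12
    filler = _draw(rng, _POOL_NO_MR, length - 9 - m)
    body = _draw(rng, _POOL_NO_MRC, m - 1)
    return "M" + filler + "P" + _draw(rng, _POOL_NO_MR, 1) + "D" + "ER" + body + \
        _draw(rng, [a for a in _POOL_NO_MR if a != "C"], 1) + _draw(rng, _POOL_NO_MR, 3)


def _decoy_oversized(rng: np.random.Generator, length: int = 120) -> str:
    """Full grammar but above the small-ORF size window."""
    filler = _draw(rng, _POOL_NO_MR, length - 9 - 12)
    return "M" + filler + "P" + _draw(rng, _POOL_NO_MR, 1) + "N" + "ER" + \
        _draw(rng, _POOL_NO_MR, 11) + "C" + _draw(rng, _POOL_NO_MR, 3)


def generate_ct_table(
    rng: np.random.Generator,
    fold_map: dict[str, float],
    noise_sd: float = 0.1,
    replicates: int = 3,
    efficiency: float = 2.0,
    calibrator: str = "monokaryon",
    comparison: str = "dikaryon",
    ref_ct: float = 15.0,
    base_dct: float = 8.0,
) -> list[CtRecord]:
    """Duplex Ct table with injected calibrator/comparison fold effects.

    ``fold_map`` gives the calibrator-over-comparison expression ratio per
    gene, so the comparison condition's ΔCt is shifted up by
    log_efficiency(fold).  Reference wells sit at a constant Ct; Gaussian
    cycle noise (sd in cycles) is added independently to every well.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    records: list[CtRecord] = []
    log_eff = np.log(efficiency)
    for gene, fold in fold_map.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene} must be > 0")
        shift = float(np.log(fold) / log_eff)
        for condition, dct in ((calibrator, base_dct), (comparison, base_dct + shift)):
            for rep in range(1, replicates + 1):
                ref = ref_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                tgt = ref_ct + dct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                records.append(CtRecord(gene, condition, rep, tgt, ref))
    return records


def generate_locus(spec: LocusSpec = LocusSpec()) -> SyntheticLocus:
    """Build the full synthetic locus from a spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.locus_len
    gc = spec.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=n, p=p)

    features: list[GeneFeature] = []
    precursor_peptides: dict[str, str] = {}
    mature_peptides: dict[str, str] = {}
    tm_segments: dict[str, tuple[tuple[int, int], ...]] = {}
    tail_lens: dict[str, int] = {}

    receptor_idx = 0
    occupied: list[tuple[int, int]] = []
    for name, kind, start, strand in spec.layout:
        if kind == "pheromone":
            dna, truth = generate_precursor_gene(
                rng, spec.precursor_len_range, spec.mature_len_range
            )
            precursor_peptides[name] = truth["peptide"]
            mature_peptides[name] = truth["mature_peptide"]
        elif kind == "receptor":
            dna, truth = generate_receptor_gene(
                rng,
                spec.receptor_lens[receptor_idx],
                spec.receptor_tail_lens[receptor_idx],
                tm_len=spec.tm_len,
                tm_count=spec.tm_count,
            )
            tm_segments[name] = truth["tm_segments"]
            tail_lens[name] = truth["c_tail_len"]
            receptor_idx += 1
        else:
            raise ValueError(f"layout kind must be pheromone or receptor, got {kind!r}")
        end = start + len(dna) - 1
        if end > n:
            raise ValueError(f"feature {name} extends past the locus end")
        for s0, e0 in occupied:
            if start <= e0 and end >= s0:
                raise ValueError(f"feature {name} overlaps a previous feature")
        occupied.append((start, end))
        insert = dna if strand == "+" else reverse_complement(dna)
        seq[start - 1 : end] = list(insert)
        features.append(GeneFeature(name, kind, start, end, strand, note="truth"))

    # grammar-ablated decoy small ORFs in the flanks
    decoy_builders = (
        ("caax_no_doublet", lambda: _decoy_caax_no_doublet(rng, int(rng.integers(40, 81)))),
        ("doublet_no_caax", lambda: _decoy_doublet_no_caax(rng, int(rng.integers(40, 81)))),
        ("oversized", lambda: _decoy_oversized(rng)),
    )
    anchors = [2_000 + 3_000 * i for i in range(8)] + [42_000 + 2_500 * i for i in range(7)]
    decoys: list[GeneFeature] = []
    for i in range(spec.decoy_count):
        label, build = decoy_builders[i % len(decoy_builders)]
        pep = build()
        dna = _codons_for(rng, pep) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        start = anchors[i % len(anchors)]
        end = start + len(dna) - 1
        strand = "+" if i % 2 == 0 else "-"
        insert = dna if strand == "+" else reverse_complement(dna)
        seq[start - 1 : end] = list(insert)
        decoys.append(GeneFeature(f"decoy_{i + 1}", "other", start, end, strand,
                                  note=f"decoy:{label}"))

    assembly = "".join(seq)

    # marker amplicon in the clone-overlap region, mid-locus
    amp_start, amp_end = 29_400, 30_400  # 1-based inclusive product
    primer_fwd = assembly[amp_start - 1 : amp_start + 19]
    primer_rev = reverse_complement(assembly[amp_end - 20 : amp_end])

    len_a, len_b, _overlap = spec.contig_split
    contig_a = Contig("cA_synthetic", assembly[:len_a], source="synthetic")
    contig_b = Contig("cB_synthetic", assembly[n - len_b :], source="synthetic")

    fold_map = dict(spec.fold_map)
    ct_records = tuple(
        generate_ct_table(
            rng, fold_map, spec.ct_noise_sd, spec.ct_replicates, spec.efficiency
        )
    )

    truth = TruthSet(
        features=tuple(features),
        decoy_features=tuple(decoys),
        precursor_peptides=precursor_peptides,
        mature_peptides=mature_peptides,
        tm_segments=tm_segments,
        tail_lens=tail_lens,
        fold_map=fold_map,
    )
    return SyntheticLocus(
        spec, assembly, contig_a, contig_b, truth,
        primer_fwd, primer_rev, (amp_start, amp_end), ct_records,
    )


def write_outputs(locus: SyntheticLocus, out_dir: str | Path) -> dict[str, Path]:
    """Write contig FASTA, truth GFF3, mature FASTA, Ct CSV and a spec echo.

    The seed is recorded in every header so runs are self-documenting;
    identical spec + seed gives byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = locus.spec.seed
    paths: dict[str, Path] = {}

    fasta = out / "contigs.fasta"
    with open(fasta, "w") as fh:
        for c in (locus.contig_a, locus.contig_b):
            fh.write(f">{c.id} synthetic seed={seed}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")
    paths["contigs"] = fasta

    gff = out / "truth.gff3"
    lm = LocusMap(
        features=locus.truth.features + locus.truth.decoy_features,
        assembly_len=locus.spec.locus_len,
        scar_interval=locus.amplicon,
    )
    write_annotation(lm, gff, "GFF3")
    with open(gff, "a") as fh:
        fh.write(f"##seed {seed}\n")
        fh.write(f"##scar-amplicon {locus.amplicon[0]} {locus.amplicon[1]}\n")
    paths["truth_gff3"] = gff

    faa = out / "mature_peptides.faa"
    with open(faa, "w") as fh:
        for name, pep in locus.truth.mature_peptides.items():
            fh.write(f">{name}_mature seed={seed}\n{pep}\n")
    paths["mature_fasta"] = faa

    ct = out / "ct_table.csv"
    with open(ct, "w") as fh:
        fh.write(f"# synthetic qRT-PCR Ct table, seed={seed}\n")
        fh.write("gene,condition,replicate,ct_target,ct_reference\n")
        for r in locus.ct_records:
            fh.write(f"{r.gene},{r.condition},{r.replicate},{r.ct_target:.6f},{r.ct_reference:.6f}\n")
    paths["ct_table"] = ct

    primers = out / "primers.csv"
    with open(primers, "w") as fh:
        fh.write(f"# SCAR-like primer pair, seed={seed}\n")
        fh.write(f"fwd,{locus.primer_fwd}\nrev,{locus.primer_rev}\n")
    paths["primers"] = primers

    cfg = out / "spec_echo.txt"
    with open(cfg, "w") as fh:
        for key, value in asdict(locus.spec).items():
            fh.write(f"{key} = {value!r}\n")
    paths["spec_echo"] = cfg
    return paths
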