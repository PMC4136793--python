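"""STE3 receptor topology prediction and pairwise global identity.

Pheromone receptors of the STE3 family are G-protein-coupled proteins with
seven transmembrane (TM) helices, an extracellular N-terminus and a
cytoplasmic C-terminal tail.  Tail length varies wildly across fungi
(hundreds of residues in *Schizophyllum commune*, ~26–54 in *Lentinula
edodes* and *Ustilago maydis*); a 7-TM protein with an unusually short
cytoplasmic tail is flagged here as "receptor-like".

TM calling is a single-sequence hydropathy method: Kyte–Doolittle profile
(window 19), candidate cores where the smoothed profile reaches the
canonical 1.6 cutoff, and each core expanded to the maximal surrounding
run of residues with positive raw hydropathy.  Expansion compensates for
the boundary erosion a 19-residue window inflicts on a ~21-residue helix;
minimum segment length and gap merging are applied to the expanded
segments.  All knobs are configurable since consensus server predictions
(Phobius/HMMTOP/TMHMM style) are deliberately not emulated in detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 15
DEFAULT_MERGE_GAP = 3
DEFAULT_EXPAND_THRESHOLD = 0.0
DEFAULT_TAIL_THRESHOLD = 50


@dataclass(frozen=True)
class TmSegment:
    """A predicted TM helix, 1-based inclusive residue coordinates."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReceptorModel:
    protein_id: str
    length_aa: int
    segments: tuple[TmSegment, ...]
    n_tail_len: int
    c_tail_len: int
    topology: tuple[str, ...]   # per-segment crossing, e.g. 'out->in'
    receptor_like: bool


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    matches: int
    aligned_columns: int
    identity_pct: float


def _raw_hydropathy(peptide: str) -> np.ndarray:
    vals = np.empty(len(peptide))
    unknown = set()
    for i, aa in enumerate(peptide):
        try:
            vals[i] = KYTE_DOOLITTLE[aa]
        except KeyError:
            unknown.add(aa)
            vals[i] = 0.0
    if unknown:
        warnings.warn(
            f"unknown residue symbols {sorted(unknown)} treated as hydropathy 0.0"
        )
    return vals


def hydropathy_profile(peptide: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered sliding-window mean of the Kyte–Doolittle scale.

    Edge residues average over the truncated window that fits inside the
    sequence.  Unknown residues contribute 0.0 with a warning.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    n = len(peptide)
    if window > n:
        raise ValueError(f"window {window} exceeds peptide length {n}")
    raw = _raw_hydropathy(peptide)
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm_segments(
    peptide: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
    expand_threshold: float = DEFAULT_EXPAND_THRESHOLD,
) -> list[TmSegment]:
    """Deterministic TM-segment calls from the hydropathy profile.

    Maximal runs of profile >= ``threshold`` seed candidate cores; each
    core is expanded outward over residues whose raw hydropathy exceeds
    ``expand_threshold``.  Overlapping expansions are unioned, segments
    separated by fewer than ``merge_gap`` residues are merged, and
    segments shorter than ``min_len`` are dropped.
    """
    if len(peptide) < min_len or len(peptide) < window:
        return []
    profile = hydropathy_profile(peptide, window)
    raw = _raw_hydropathy(peptide)
    n = len(peptide)

    # candidate cores: maximal runs with smoothed profile >= threshold
    above = profile >= threshold
    cores: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            cores.append((i, j))
            i = j + 1
        else:
            i += 1

    # expand cores over hydrophobic residues (raw scale > expand_threshold)
    expanded: list[tuple[int, int]] = []
    for s, e in cores:
        while s > 0 and raw[s - 1] > expand_threshold:
            s -= 1
        while e + 1 < n and raw[e + 1] > expand_threshold:
            e += 1
        expanded.append((s, e))

    # union overlaps, then merge near-adjacent segments
    merged: list[list[int]] = []
    for s, e in sorted(expanded):
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    return [
        TmSegment(s + 1, e + 1, float(raw[s : e + 1].mean()))
        for s, e in merged
        if e - s + 1 >= min_len
    ]


def build_receptor_model(
    protein_id: str,
    peptide: str,
    tail_threshold: int = DEFAULT_TAIL_THRESHOLD,
    **tm_kwargs,
) -> ReceptorModel:
    """Assemble the receptor model: segments, tails, topology, flag.

    Topology follows the STE3 convention of an extracellular N-terminus,
    so odd-numbered TMs cross out→in and even-numbered in→out; with seven
    segments the C-tail is cytoplasmic.  ``receptor_like`` is True iff
    exactly seven segments are found and the C-tail is shorter than
    ``tail_threshold`` residues; any other segment count raises a
    topology warning and clears the flag.
    """
    segments = tuple(predict_tm_segments(peptide, **tm_kwargs))
    n = len(peptide)
    if segments:
        n_tail = segments[0].start - 1
        c_tail = n - segments[-1].end
    else:
        n_tail = c_tail = n
    topology = tuple(
        "out->in" if i % 2 == 0 else "in->out" for i in range(len(segments))
    )
    if len(segments) != 7:
        warnings.warn(
            f"{protein_id}: {len(segments)} TM segments predicted (expected 7); "
            "topology labels may not follow the STE3 convention"
        )
        receptor_like = False
    else:
        receptor_like = c_tail < tail_threshold
    return ReceptorModel(
        protein_id, n, segments, n_tail, c_tail, topology, receptor_like
    )


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    *,
    id_a: str = "a",
    id_b: str = "b",
    mode: str = "full",
    truncate_len: int | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Needleman–Wunsch percent identity between two proteins.

    Identity is 100 × matches / aligned columns with gapped columns
    included in the denominator ("full-length" convention).  In
    ``mode='truncated'`` the longer sequence is first cut to
    ``truncate_len`` residues (default: the length of the shorter
    sequence) — the convention used when one paralog carries a
    non-corresponding C-terminal extension.  The pair is aligned in a
    canonical order so the result is symmetric in (a, b).
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if mode not in ("full", "truncated"):
        raise ValueError(f"mode must be 'full' or 'truncated', got {mode!r}")
    a, b = seq_a, seq_b
    if mode == "truncated":
        cut = truncate_len if truncate_len is not None else min(len(a), len(b))
        if len(a) >= len(b):
            a = a[:cut]
        else:
            b = b[:cut]
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    # canonical order: co-optimal alignments can differ in match count,
    # so align the sorted pair to make identity symmetric by construction
    x, y = sorted((a, b))
    aln = aligner.align(x, y)[0]
    row_x, row_y = str(aln[0]), str(aln[1])
    matches = sum(1 for ca, cb in zip(row_x, row_y) if ca == cb and ca != "-")
    columns = len(row_x)
    return AlignmentResult(id_a, id_b, matches, columns, 100.0 * matches / columns)


def identity_matrix(
    proteins: Sequence[tuple[str, str]], **kwargs
) -> pd.DataFrame:
    """Symmetric pairwise identity matrix for (id, sequence) pairs."""
    ids = [p[0] for p in proteins]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            r = global_identity(
                proteins[i][1], proteins[j][1],
                id_a=ids[i], id_b=ids[j], **kwargs,
            )
            mat.iloc[i, j] = mat.iloc[j, i] = r.identity_pct
    return mat


def receptor_table(models: Iterable[ReceptorModel]) -> pd.DataFrame:
    """Report table mirroring a TM-motif supplementary layout."""
    rows = []
    for m in models:
        rows.append(
            {
                "protein_id": m.protein_id,
                "length_aa": m.length_aa,
                "n_segments": len(m.segments),
                "segments": ";".join(f"{s.start}-{s.end}" for s in m.segments),
                "n_tail_len": m.n_tail_len,
                "c_tail_len": m.c_tail_len,
                "receptor_like": m.receptor_like,
            }
        )
    return pd.DataFrame(rows)
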