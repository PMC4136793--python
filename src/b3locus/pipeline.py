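"""End-to-end pipeline: merge → ORF scan → classification → map → expression.

One ``RunConfig`` carries every stage parameter (defaults match the
module-level defaults), and ``run_pipeline`` wires the stages into the
locus-characterisation workflow, returning a machine-readable summary:
gene counts, mating span, pairwise receptor identities and calibrated
folds.  A config echo and summary JSON are written alongside outputs so
a run is reproducible from its manifest.

Candidate ORFs sharing a termination site are collapsed to one gene call:
for pheromones the best-scoring then shortest precursor (the most
parsimonious ATG above the grammar), for receptors the longest 7-TM
translation (the maximal ORF).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from b3locus import pheromones as ph
from b3locus import receptors as rc
from b3locus.expression import CtRecord, fold_ratio, relative_expression
from b3locus.locusmap import (
    GeneFeature,
    LocusMap,
    locate_amplicon,
    mating_span,
    merge_contigs,
    write_annotation,
)
from b3locus.orfs import Contig, six_frame_orfs

log = logging.getLogger("b3locus")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for the whole pipeline (all config knobs in one place)."""

    # small-ORF mining
    min_aa: int = 10
    max_aa: int = 100
    # pheromone grammar
    cleavage_window: tuple[int, int] = ph.DEFAULT_WINDOW
    accept_len: tuple[int, int] = ph.DEFAULT_ACCEPT_LEN
    strict: bool = True
    min_site_score: int = ph.DEFAULT_MIN_SCORE
    # receptor topology
    receptor_size_range: tuple[int, int] = (150, 800)
    tm_window: int = rc.DEFAULT_WINDOW
    tm_threshold: float = rc.DEFAULT_THRESHOLD
    tm_min_len: int = rc.DEFAULT_MIN_LEN
    tm_merge_gap: int = rc.DEFAULT_MERGE_GAP
    tail_threshold: int = rc.DEFAULT_TAIL_THRESHOLD
    # alignment scoring
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    # expression
    calibrator: str = "monokaryon"
    efficiency: float = 2.0
    # assembly
    min_overlap: int = 100
    # reproducibility
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML manifest; keyword overrides take precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        for key in ("cleavage_window", "accept_len", "receptor_size_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _dedupe_precursors(precursors: Sequence[ph.PheromonePrecursor]) -> list[ph.PheromonePrecursor]:
    best: dict[tuple, ph.PheromonePrecursor] = {}
    for p in precursors:
        o = p.orf
        key = (o.contig_id, o.strand, o.end if o.strand == "+" else o.start)
        cur = best.get(key)
        score = p.chosen_site.score if p.chosen_site else 0
        cur_score = cur.chosen_site.score if cur and cur.chosen_site else 0
        if cur is None or (score, -o.length_aa) > (cur_score, -cur.orf.length_aa):
            best[key] = p
    return sorted(best.values(), key=lambda p: (p.orf.contig_id, p.orf.start))


def _dedupe_receptors(models: Sequence[tuple]) -> list[tuple]:
    # items are (orf, model); keep the longest translation per stop
    best: dict[tuple, tuple] = {}
    for orf, model in models:
        key = (orf.contig_id, orf.strand, orf.end if orf.strand == "+" else orf.start)
        cur = best.get(key)
        if cur is None or orf.length_aa > cur[0].length_aa:
            best[key] = (orf, model)
    return sorted(best.values(), key=lambda t: (t[0].contig_id, t[0].start))


def run_pipeline(
    contigs: Sequence[Contig],
    config: RunConfig = RunConfig(),
    ct_records: Sequence[CtRecord] | None = None,
    primers: tuple[str, str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full workflow and return the summary dict.

    With two contigs the locus is first merged; a single contig is used
    as-is.  Ct records and a primer pair are optional add-ons.  When
    ``out_dir`` is given, reports (summary JSON, config echo, feature
    GFF3, precursor/receptor CSVs) are written there.
    """
    if not contigs:
        raise StageError("input", "no contigs provided")
    for c in contigs:
        if len(c) == 0:
            raise StageError("input", f"contig {c.id} is empty")

    # --- merge ------------------------------------------------------------
    if len(contigs) == 2:
        try:
            assembly = merge_contigs(contigs[0], contigs[1], config.min_overlap)
        except ValueError as e:
            raise StageError("merge", str(e)) from e
        locus = Contig("B3_locus", assembly.sequence, source="merged")
        overlap = assembly.overlap_len
    elif len(contigs) == 1:
        assembly = None
        locus = contigs[0]
        overlap = None
    else:
        raise StageError("merge", f"expected 1 or 2 contigs, got {len(contigs)}")

    # --- small-ORF scan and pheromone classification ----------------------
    small_orfs = six_frame_orfs(locus, config.min_aa, config.max_aa)
    classified = [
        p
        for o in small_orfs
        if (
            p := ph.classify_pheromone(
                o,
                size_range=(config.min_aa, config.max_aa),
                window=config.cleavage_window,
                accept_len=config.accept_len,
                strict=config.strict,
                min_site_score=config.min_site_score,
            )
        )
        is not None
    ]
    precursors = _dedupe_precursors(classified)
    log.info("pheromone scan: %d small ORFs, %d precursors", len(small_orfs), len(precursors))

    # --- receptor scan ----------------------------------------------------
    big_orfs = six_frame_orfs(locus, *config.receptor_size_range)
    tm_kwargs = dict(
        window=config.tm_window,
        threshold=config.tm_threshold,
        min_len=config.tm_min_len,
        merge_gap=config.tm_merge_gap,
    )
    import warnings as _warnings

    candidates = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for o in big_orfs:
            model = rc.build_receptor_model(
                f"{o.contig_id}:{o.start}-{o.end}({o.strand})",
                o.peptide,
                tail_threshold=config.tail_threshold,
                **tm_kwargs,
            )
            if len(model.segments) == 7:
                candidates.append((o, model))
    receptor_calls = _dedupe_receptors(candidates)
    log.info("receptor scan: %d large ORFs, %d 7-TM receptors", len(big_orfs), len(receptor_calls))

    # --- physical map -----------------------------------------------------
    features = [
        GeneFeature(f"pheromone_{i + 1}", "pheromone", p.orf.start, p.orf.end, p.orf.strand)
        for i, p in enumerate(precursors)
    ] + [
        GeneFeature(f"receptor_{i + 1}", "receptor", o.start, o.end, o.strand)
        for i, (o, _m) in enumerate(receptor_calls)
    ]
    features.sort(key=lambda f: f.start)
    span = mating_span(features) if features else None

    amplicon = None
    if primers is not None:
        hit = locate_amplicon(primers[0], primers[1], locus.sequence)
        amplicon = None if hit is None else {
            "interval": list(hit.interval),
            "products": [list(p) for p in hit.products],
            "multiple": hit.multiple,
        }

    # --- pairwise receptor identities ------------------------------------
    identity = {}
    if len(receptor_calls) >= 2:
        prots = [(m.protein_id, o.peptide) for o, m in receptor_calls]
        mat = rc.identity_matrix(
            prots, matrix=config.matrix, gap_open=config.gap_open, gap_extend=config.gap_extend
        )
        identity = {a: {b: round(float(mat.loc[a, b]), 1) for b in mat.columns} for a in mat.index}

    # --- expression -------------------------------------------------------
    expression = None
    if ct_records:
        rel = relative_expression(ct_records, config.calibrator, config.efficiency)
        ratios = fold_ratio(ct_records, numerator=config.calibrator, efficiency=config.efficiency)
        expression = {
            "folds": {
                f"{r.gene}/{r.condition}": round(float(r.fold), 4)
                for r in rel.itertuples(index=False)
            },
            "calibrator_over_comparison": {g: round(float(v), 4) for g, v in ratios.items()},
        }

    summary = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_contigs": len(contigs),
        "assembly_len": len(locus),
        "overlap_len": overlap,
        "n_small_orfs": len(small_orfs),
        "pheromones": len(precursors),
        "receptors": len(receptor_calls),
        "receptor_like": sum(1 for _o, m in receptor_calls if m.receptor_like),
        "mating_span_nt": span,
        "mature_lengths": [p.mature_length for p in precursors],
        "identity_pct": identity,
        "amplicon": amplicon,
        "expression": expression,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        ph.precursor_table(precursors).to_csv(out / "precursors.csv", index=False)
        rc.receptor_table([m for _o, m in receptor_calls]).to_csv(
            out / "receptors.csv", index=False
        )
        if features:
            lm = LocusMap(features=tuple(features), assembly_len=len(locus))
            write_annotation(lm, out / "features.gff3", "GFF3")
    return summary
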