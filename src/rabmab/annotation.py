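"""Variable-domain annotation for rabbit VH/VL amino-acid sequences.

Each sequenced B-cell clone contributes a cognate VH/VL pair.  Annotation
proceeds in three steps:

1. *Germline assignment* — global alignment of the query against a panel of
   germline V references (e.g. the rabbit heavy-chain allotypes VH1a1 and
   VH1a3); the reference with the fewest amino-acid replacements wins.
2. *Region delineation* — CDR3 is anchored on the conserved framework-3
   cysteine and the J-segment motif (``W-G-x-G`` for heavy chains,
   ``F-G-x-G`` for kappa); CDR1/CDR2 come from fixed Kabat-style intervals
   on the germline, mapped onto the query through the alignment.
3. *Replacement counting* — substitutions (aligned columns with differing
   residues) are tallied per region; indel columns are never counted.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

HEAVY_J_MOTIF = re.compile(r"WG.G")
KAPPA_J_MOTIF = re.compile(r"FG.G")

#: Default Kabat-style CDR1/CDR2 intervals on germline coordinates
#: (0-based half-open), used when a germline carries no intervals of its own.
DEFAULT_CDR_INTERVALS = {
    "heavy": {"cdr1": (25, 35), "cdr2": (49, 65)},
    "kappa": {"cdr1": (23, 34), "cdr2": (49, 56)},
}

REGION_ORDER = ("fr1", "cdr1", "fr2", "cdr2", "fr3", "cdr3", "fr4")


class AnnotationError(ValueError):
    """Raised when a sequence cannot be annotated (missing anchors etc.)."""


def _validate_sequence(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if not seq:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class GermlineReference:
    """A germline V-segment reference sequence.

    ``cdr1``/``cdr2`` are optional interval annotations on the germline's own
    coordinates; when absent the chain-level Kabat-style defaults apply.
    """

    id: str
    chain: str  # "heavy" | "kappa"
    sequence: str
    cdr1: tuple[int, int] | None = None
    cdr2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.chain not in ("heavy", "kappa"):
            raise ValueError(f"unknown chain {self.chain!r}")
        _validate_sequence(self.sequence)

    def cdr_intervals(self) -> dict[str, tuple[int, int]]:
        defaults = DEFAULT_CDR_INTERVALS[self.chain]
        return {
            "cdr1": self.cdr1 or defaults["cdr1"],
            "cdr2": self.cdr2 or defaults["cdr2"],
        }


@dataclass(frozen=True)
class RegionAnnotation:
    """FR/CDR boundaries of one variable domain (0-based half-open)."""

    boundaries: dict[str, tuple[int, int]]
    cdr3_sequence: str

    def __post_init__(self) -> None:
        prev_end = None
        for name in REGION_ORDER:
            start, end = self.boundaries[name]
            if start > end:
                raise ValueError(f"inverted interval for {name}")
            if prev_end is not None and start != prev_end:
                raise ValueError("region intervals must be contiguous")
            prev_end = end
        if not 1 <= len(self.cdr3_sequence) <= 40:
            raise ValueError("CDR3 length outside 1..40")

    def region_of(self, pos: int) -> str | None:
        for name in REGION_ORDER:
            start, end = self.boundaries[name]
            if start <= pos < end:
                return name
        return None

    @property
    def cdr3(self) -> tuple[int, int]:
        return self.boundaries["cdr3"]


@dataclass
class AnnotatedClone:
    """One B-cell clone's VH/VL pair with annotation results and metadata."""

    clone_id: str
    animal: str = ""
    bleed: int = 0
    vh: str = ""
    vl: str = ""
    sort_arm: str = ""
    vh_germline: str | None = None
    vl_germline: str | None = None
    vh_regions: RegionAnnotation | None = None
    vl_regions: RegionAnnotation | None = None
    vh_replacements_fr: int | None = None
    vh_replacements_cdr: int | None = None
    vl_replacements_fr: int | None = None
    vl_replacements_cdr: int | None = None
    annotation_ok: bool = True
    annotation_error: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def cdr3_h(self) -> str | None:
        if self.vh_regions is not None:
            return self.vh_regions.cdr3_sequence
        return self.extra.get("cdr3_h")

    @property
    def cdr3_l(self) -> str | None:
        if self.vl_regions is not None:
            return self.vl_regions.cdr3_sequence
        return self.extra.get("cdr3_l")

    @property
    def vh_replacements_total(self) -> int | None:
        if self.vh_replacements_fr is None or self.vh_replacements_cdr is None:
            return None
        return self.vh_replacements_fr + self.vh_replacements_cdr

    @property
    def vl_replacements_total(self) -> int | None:
        if self.vl_replacements_fr is None or self.vl_replacements_cdr is None:
            return None
        return self.vl_replacements_fr + self.vl_replacements_cdr


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    open_gap: float = -5.0,
    extend_gap: float = -1.0,
) -> Align.PairwiseAligner:
    """Global protein aligner with the package's default scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _aligned_columns(alignment) -> list[tuple[int, int]]:
    """(reference_pos, query_pos) pairs for all aligned (non-indel) columns."""
    cols: list[tuple[int, int]] = []
    ref_blocks, query_blocks = alignment.aligned
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        cols.extend(zip(range(rs, re_), range(qs, qe)))
    return cols


def align_to_germline(query: str, germline: GermlineReference, aligner=None):
    """Globally align *query* to *germline* and return the best alignment."""
    if aligner is None:
        aligner = make_aligner()
    return aligner.align(germline.sequence, query)[0]


def _replacements_in_alignment(alignment, germline_seq: str, query: str) -> int:
    return sum(
        1
        for gpos, qpos in _aligned_columns(alignment)
        if germline_seq[gpos] != query[qpos]
    )


def assign_germline(
    query: str,
    references: Sequence[GermlineReference],
    chain: str | None = None,
    aligner=None,
):
    """Assign the closest germline to *query*.

    Returns ``(germline, alignment, n_replacements)`` where the winning
    reference minimises the amino-acid replacement count under global
    alignment.  Ties break deterministically by reference order.
    """
    _validate_sequence(query)
    if chain is not None:
        references = [r for r in references if r.chain == chain]
    if not references:
        raise ValueError("no germline references supplied")
    if len(query) < 60:
        raise ValueError("query shorter than 60 residues")
    if aligner is None:
        aligner = make_aligner()
    best = None
    for ref in references:
        alignment = align_to_germline(query, ref, aligner)
        n = _replacements_in_alignment(alignment, ref.sequence, query)
        if best is None or n < best[2]:
            best = (ref, alignment, n)
    return best


def _locate_cdr3(query: str, motif: re.Pattern) -> tuple[int, int]:
    """Return (cys_index, j_start): CDR3 spans (cys_index, j_start) exclusive."""
    for m in motif.finditer(query):
        cys = query.rfind("C", 0, m.start())
        if cys != -1 and m.start() - cys > 1:
            return cys, m.start()
    raise AnnotationError("missing Cys/J-motif anchors")


def delineate_regions(
    query: str,
    chain: str,
    germline: GermlineReference | None = None,
    aligner=None,
) -> RegionAnnotation:
    """Delineate FR1..FR4 and CDR1..CDR3 on *query*.

    CDR3 is the stretch strictly between the last cysteine preceding the
    J motif and the first J-motif residue (W of ``W-G-x-G`` for heavy, F of
    ``F-G-x-G`` for kappa).  CDR1/CDR2 use the germline's Kabat-style
    intervals mapped through the global alignment; without a germline the
    chain defaults apply directly to query coordinates.
    """
    _validate_sequence(query)
    if chain not in ("heavy", "kappa"):
        raise ValueError(f"unknown chain {chain!r}")
    motif = HEAVY_J_MOTIF if chain == "heavy" else KAPPA_J_MOTIF
    cys, j_start = _locate_cdr3(query, motif)
    cdr3 = (cys + 1, j_start)

    intervals = (
        germline.cdr_intervals()
        if germline is not None
        else {k: tuple(v) for k, v in DEFAULT_CDR_INTERVALS[chain].items()}
    )
    if germline is not None:
        alignment = align_to_germline(query, germline, aligner)
        g2q = dict(_aligned_columns(alignment))

        def map_pos(gpos: int, fallback: int) -> int:
            return g2q.get(gpos, fallback)

        cdr1 = (
            map_pos(intervals["cdr1"][0], intervals["cdr1"][0]),
            map_pos(intervals["cdr1"][1] - 1, intervals["cdr1"][1] - 1) + 1,
        )
        cdr2 = (
            map_pos(intervals["cdr2"][0], intervals["cdr2"][0]),
            map_pos(intervals["cdr2"][1] - 1, intervals["cdr2"][1] - 1) + 1,
        )
    else:
        cdr1 = intervals["cdr1"]
        cdr2 = intervals["cdr2"]

    if not (cdr1[1] <= cdr2[0] <= cdr2[1] <= cdr3[0]):
        raise AnnotationError("CDR1/CDR2 intervals collide with CDR3 anchors")

    boundaries = {
        "fr1": (0, cdr1[0]),
        "cdr1": cdr1,
        "fr2": (cdr1[1], cdr2[0]),
        "cdr2": cdr2,
        "fr3": (cdr2[1], cdr3[0]),
        "cdr3": cdr3,
        "fr4": (j_start, len(query)),
    }
    return RegionAnnotation(boundaries=boundaries, cdr3_sequence=query[cdr3[0] : cdr3[1]])


def count_replacements(
    query: str,
    germline: GermlineReference,
    regions: RegionAnnotation,
    aligner=None,
    include_cdr3: bool = False,
) -> tuple[int, int, int]:
    """Count amino-acid replacement mutations per region class.

    Returns ``(fr_count, cdr_count, total)``.  Only substitutions at aligned
    columns count; indel columns are excluded.  FR4 is J-encoded and never
    counted.  CDR3 is junction-derived rather than germline-encoded, so it is
    excluded by default; pass ``include_cdr3=True`` to count it against the
    germline's CDR3 stretch anyway.
    """
    alignment = align_to_germline(query, germline, aligner)
    fr = cdr = 0
    for gpos, qpos in _aligned_columns(alignment):
        if germline.sequence[gpos] == query[qpos]:
            continue
        region = regions.region_of(qpos)
        if region in ("fr1", "fr2", "fr3"):
            fr += 1
        elif region in ("cdr1", "cdr2"):
            cdr += 1
        elif region == "cdr3" and include_cdr3:
            cdr += 1
    return fr, cdr, fr + cdr


def annotate_clone(
    clone_id: str,
    vh: str,
    vl: str,
    references: Sequence[GermlineReference],
    animal: str = "",
    bleed: int = 0,
    sort_arm: str = "",
    aligner=None,
) -> AnnotatedClone:
    """Annotate one VH/VL pair; annotation failures are flagged, not raised."""
    clone = AnnotatedClone(
        clone_id=clone_id, animal=animal, bleed=bleed, vh=vh, vl=vl, sort_arm=sort_arm
    )
    try:
        for chain, seq in (("heavy", vh), ("kappa", vl)):
            germ, _, _ = assign_germline(seq, references, chain=chain, aligner=aligner)
            regions = delineate_regions(seq, chain, germline=germ, aligner=aligner)
            fr, cdr, _ = count_replacements(seq, germ, regions, aligner=aligner)
            if chain == "heavy":
                clone.vh_germline = germ.id
                clone.vh_regions = regions
                clone.vh_replacements_fr = fr
                clone.vh_replacements_cdr = cdr
            else:
                clone.vl_germline = germ.id
                clone.vl_regions = regions
                clone.vl_replacements_fr = fr
                clone.vl_replacements_cdr = cdr
    except (AnnotationError, ValueError) as exc:
        clone.annotation_ok = False
        clone.annotation_error = str(exc)
    return clone


def annotate_repertoire(
    records: Iterable[dict],
    references: Sequence[GermlineReference],
) -> list[AnnotatedClone]:
    """Annotate a repertoire given per-clone record dicts.

    Each record needs ``clone_id``, ``vh``, ``vl`` and may carry ``animal``,
    ``bleed``, ``sort_arm``.  Clones failing annotation are retained with
    ``annotation_ok=False``.
    """
    aligner = make_aligner()
    clones = []
    for rec in records:
        clones.append(
            annotate_clone(
                str(rec["clone_id"]),
                rec["vh"],
                rec["vl"],
                references,
                animal=str(rec.get("animal", "")),
                bleed=int(rec.get("bleed", 0)),
                sort_arm=str(rec.get("sort_arm", "")),
                aligner=aligner,
            )
        )
    return clones


def simple_clone(
    clone_id: str,
    cdr3_h: str,
    cdr3_l: str,
    animal: str = "",
    bleed: int = 0,
    vh: str = "",
    vl: str = "",
    **extra,
) -> AnnotatedClone:
    """Lightweight clone carrying CDR3s directly (no region objects).

    Useful for clustering/statistics on pre-annotated tables where only the
    CDR3 sequences and metadata are available.
    """
    return AnnotatedClone(
        clone_id=clone_id,
        animal=animal,
        bleed=bleed,
        vh=vh,
        vl=vl,
        extra={"cdr3_h": cdr3_h, "cdr3_l": cdr3_l, **extra},
    )


def clones_from_frame(frame) -> list[AnnotatedClone]:
    """Rebuild lightweight annotated clones from a flattened annotation table."""
    clones = []
    for _, row in frame.iterrows():
        clone = AnnotatedClone(
            clone_id=str(row["clone_id"]),
            animal=str(row.get("animal", "")),
            bleed=int(row.get("bleed", 0)),
            sort_arm=str(row.get("sort_arm", "")),
            vh=str(row.get("vh", "") or ""),
            vl=str(row.get("vl", "") or ""),
            vh_germline=row.get("vh_germline"),
            vl_germline=row.get("vl_germline"),
            annotation_ok=bool(row.get("annotation_ok", True)),
        )
        if clone.annotation_ok:
            clone.extra["cdr3_h"] = row.get("cdr3_h")
            clone.extra["cdr3_l"] = row.get("cdr3_l")
            for col in (
                "vh_replacements_fr",
                "vh_replacements_cdr",
                "vl_replacements_fr",
                "vl_replacements_cdr",
            ):
                if col in frame.columns and row[col] == row[col]:  # not NaN
                    setattr(clone, col, int(row[col]))
        clones.append(clone)
    return clones


def clones_to_frame(clones: Sequence[AnnotatedClone]):
    """Flatten annotated clones into a pandas DataFrame (one row per clone)."""
    import pandas as pd

    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "animal": c.animal,
                "bleed": c.bleed,
                "sort_arm": c.sort_arm,
                "vh": c.vh,
                "vl": c.vl,
                "vh_germline": c.vh_germline,
                "vl_germline": c.vl_germline,
                "cdr3_h": c.cdr3_h,
                "cdr3_l": c.cdr3_l,
                "vh_replacements_fr": c.vh_replacements_fr,
                "vh_replacements_cdr": c.vh_replacements_cdr,
                "vh_replacements_total": c.vh_replacements_total,
                "vl_replacements_fr": c.vl_replacements_fr,
                "vl_replacements_cdr": c.vl_replacements_cdr,
                "vl_replacements_total": c.vl_replacements_total,
                "annotation_ok": c.annotation_ok,
                "annotation_error": c.annotation_error,
            }
        )
    return pd.DataFrame(rows)
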