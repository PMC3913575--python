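"""Repertoire diversity and maturation statistics.

Summaries over an annotated repertoire: CDR-H3 length distribution,
somatic replacement-mutation distribution (overall and stratified by
animal, bleed, germline and V-region), and Kyte–Doolittle hydropathy
(GRAVY) of the CDR3 loops.

Dispersion defaults to the population standard deviation (n denominator);
the sample version is available via ``ddof=1``.  Strata with fewer than two
clones report their sd as undefined (rendered ``nd`` in reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedClone

#: Kyte & Doolittle residue hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy(seq: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean per-residue hydropathy of *seq*."""
    if not seq:
        raise ValueError("empty sequence")
    scale = scale or KYTE_DOOLITTLE
    try:
        return float(np.mean([scale[res] for res in seq]))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float | None  # None when n < 2 ("nd" in reports)
    minimum: float
    maximum: float

    @property
    def range(self) -> tuple[float, float]:
        return (self.minimum, self.maximum)


def _summary(values: Sequence[float], ddof: int = 0) -> SummaryStats:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    sd = float(np.std(arr, ddof=ddof)) if arr.size >= 2 else None
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def _annotated(clones: Sequence[AnnotatedClone]) -> list[AnnotatedClone]:
    ok = [c for c in clones if c.annotation_ok and c.cdr3_h is not None]
    if not ok:
        raise ValueError("no annotated clones")
    return ok


def cdr3_length_stats(
    clones: Sequence[AnnotatedClone],
    strata: Sequence[str] = (),
    chain: str = "heavy",
    ddof: int = 0,
) -> dict:
    """CDR3 length histogram and mean +/- sd, overall and per stratum.

    ``strata`` may name any of ``animal``, ``bleed``, ``germline``.
    """
    ok = _annotated(clones)
    get = (lambda c: len(c.cdr3_h)) if chain == "heavy" else (lambda c: len(c.cdr3_l))
    lengths = [get(c) for c in ok]
    histogram = dict(sorted(pd.Series(lengths).value_counts().items()))
    result = {
        "histogram": histogram,
        "overall": _summary(lengths, ddof=ddof),
        "per_stratum": _per_stratum(ok, get, strata, ddof=ddof),
    }
    return result


def replacement_stats(
    clones: Sequence[AnnotatedClone],
    strata: Sequence[str] = (),
    chain: str = "heavy",
    ddof: int = 0,
) -> dict:
    """Replacement-mutation histogram, mean +/- sd and range per stratum.

    When ``region`` is among the strata, framework and CDR counts are
    reported separately; otherwise totals (FR1-3 + CDR1-2) are used.
    """
    ok = _annotated(clones)
    if chain == "heavy":
        total = lambda c: c.vh_replacements_total
        fr = lambda c: c.vh_replacements_fr
        cdr = lambda c: c.vh_replacements_cdr
    else:
        total = lambda c: c.vl_replacements_total
        fr = lambda c: c.vl_replacements_fr
        cdr = lambda c: c.vl_replacements_cdr
    ok = [c for c in ok if total(c) is not None]
    if not ok:
        raise ValueError("no clones with replacement counts")

    totals = [total(c) for c in ok]
    result = {
        "histogram": dict(sorted(pd.Series(totals).value_counts().items())),
        "overall": _summary(totals, ddof=ddof),
    }
    plain = [s for s in strata if s != "region"]
    if "region" in strata:
        result["framework"] = {
            "overall": _summary([fr(c) for c in ok], ddof=ddof),
            "per_stratum": _per_stratum(ok, fr, plain, ddof=ddof),
        }
        result["cdr"] = {
            "overall": _summary([cdr(c) for c in ok], ddof=ddof),
            "per_stratum": _per_stratum(ok, cdr, plain, ddof=ddof),
        }
    result["per_stratum"] = _per_stratum(ok, total, plain, ddof=ddof)
    return result


def _stratum_key(clone: AnnotatedClone, strata: Sequence[str]):
    parts = []
    for s in strata:
        if s == "animal":
            parts.append(clone.animal)
        elif s == "bleed":
            parts.append(clone.bleed)
        elif s == "germline":
            parts.append(clone.vh_germline)
        else:
            raise ValueError(f"unknown stratum {s!r}")
    return tuple(parts)


def _per_stratum(clones, getter, strata, ddof=0) -> dict:
    if not strata:
        return {}
    groups: dict[tuple, list] = {}
    for c in clones:
        groups.setdefault(_stratum_key(c, strata), []).append(getter(c))
    return {k: _summary(v, ddof=ddof) for k, v in sorted(groups.items(), key=str)}


def gravy_by_clone(
    clones: Sequence[AnnotatedClone], chain: str = "heavy"
) -> dict[str, float]:
    """CDR3 hydropathy per clone id."""
    ok = _annotated(clones)
    seq = (lambda c: c.cdr3_h) if chain == "heavy" else (lambda c: c.cdr3_l)
    return {c.clone_id: gravy(seq(c)) for c in ok if seq(c)}


def summary_frame(stats: dict, name: str) -> pd.DataFrame:
    """Flatten a stats dict into a report DataFrame with 'nd' for tiny strata."""
    rows = [
        {
            "stratum": "overall",
            "statistic": name,
            "n": stats["overall"].n,
            "mean": stats["overall"].mean,
            "sd": stats["overall"].sd if stats["overall"].sd is not None else "nd",
            "min": stats["overall"].minimum,
            "max": stats["overall"].maximum,
        }
    ]
    for key, s in stats.get("per_stratum", {}).items():
        rows.append(
            {
                "stratum": "/".join(str(k) for k in key),
                "statistic": name,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd if s.sd is not None else "nd",
                "min": s.minimum,
                "max": s.maximum,
            }
        )
    return pd.DataFrame(rows)


def plot_histograms(stats_length: dict, stats_repl: dict, path: str) -> None:
    """Side-by-side CDR-H3 length and replacement-count histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, stats, title, xlabel in (
        (axes[0], stats_length, "CDR-H3 length", "length (aa)"),
        (axes[1], stats_repl, "VH replacements", "replacements"),
    ):
        hist = stats["histogram"]
        ax.bar(list(hist.keys()), list(hist.values()), color="0.4")
        ax.set_title(title)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("clones")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
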