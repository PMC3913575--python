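"""Readers, writers and the end-to-end campaign pipeline.

Exchange formats are deliberately plain: FASTA for sequences (one record
per chain, id pattern ``clone{N}_VH`` / ``clone{N}_VL``), CSV for the
metadata/annotation/panel/competition tables, YAML for configuration and
calibrated thresholds.  Every writer round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import annotation, binning, clonotypes, funnel as funnel_mod, repstats, synthetic

log = logging.getLogger("rabmab")


# ---------------------------------------------------------------- FASTA I/O

def read_fasta(path: str) -> list[tuple[str, str, str]]:
    """Read FASTA records as (id, description, sequence) tuples.

    Duplicate ids and empty records are rejected; an empty file yields an
    empty list.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        if not rec.seq:
            raise ValueError(f"empty FASTA record: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, rec.description, str(rec.seq)))
    return records


def write_fasta(records, path: str) -> None:
    """Write (id, description, sequence) tuples, wrapped at 60 columns."""
    seqs = []
    seen: set[str] = set()
    for rec_id, description, seq in records:
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id: {rec_id}")
        seen.add(rec_id)
        seqs.append(SeqRecord(Seq(seq), id=rec_id, description=description))
    SeqIO.write(seqs, path, "fasta")


def write_repertoire_fasta(repertoire: pd.DataFrame, path: str) -> None:
    """One record per chain: ids ``{clone_id}_VH`` and ``{clone_id}_VL``."""
    records = []
    for _, row in repertoire.iterrows():
        records.append((f"{row['clone_id']}_VH", "", row["vh"]))
        records.append((f"{row['clone_id']}_VL", "", row["vl"]))
    write_fasta(records, path)


def read_repertoire_fasta(fasta_path: str, metadata: pd.DataFrame) -> list[dict]:
    """Pair ``_VH``/``_VL`` records with their metadata rows."""
    chains: dict[str, dict[str, str]] = {}
    for rec_id, _, seq in read_fasta(fasta_path):
        if not (rec_id.endswith("_VH") or rec_id.endswith("_VL")):
            raise ValueError(f"record id {rec_id!r} lacks _VH/_VL suffix")
        clone_id, chain = rec_id.rsplit("_", 1)
        chains.setdefault(clone_id, {})[chain] = seq
    records = []
    meta = metadata.set_index(metadata["clone_id"].astype(str))
    for clone_id, pair in chains.items():
        if set(pair) != {"VH", "VL"}:
            raise ValueError(f"clone {clone_id} missing a chain")
        rec = {"clone_id": clone_id, "vh": pair["VH"], "vl": pair["VL"]}
        if clone_id in meta.index:
            row = meta.loc[clone_id]
            rec.update(
                animal=str(row.get("animal", "")),
                bleed=int(row.get("bleed", 0)),
                sort_arm=str(row.get("sort_arm", "")),
            )
        records.append(rec)
    return records


def germlines_from_fasta(path: str) -> list[annotation.GermlineReference]:
    """Load germline references; chain inferred from the id prefix.

    Ids starting with ``VH`` are heavy; ``VK``/``VL`` are kappa.  A
    ``chain=heavy|kappa`` token in the description overrides the prefix.
    """
    refs = []
    for rec_id, description, seq in read_fasta(path):
        chain = None
        for token in description.split():
            if token.startswith("chain="):
                chain = token.split("=", 1)[1]
        if chain is None:
            upper = rec_id.upper()
            chain = "heavy" if upper.startswith("VH") else "kappa"
        refs.append(annotation.GermlineReference(id=rec_id, chain=chain, sequence=seq))
    return refs


def germlines_to_fasta(refs, path: str) -> None:
    write_fasta([(r.id, f"chain={r.chain}", r.sequence) for r in refs], path)


# ----------------------------------------------------------------- CSV I/O

def write_panel_csv(panel: pd.DataFrame, path: str, long_format: bool = True) -> None:
    """Write the well table; canonical exchange is long (well_id, assay, value)."""
    if not long_format:
        panel.to_csv(path, index=False)
        return
    meta_cols = [c for c in panel.columns if c.startswith(("well_id", "animal", "bleed", "sort_arm", "true_"))]
    value_cols = [c for c in panel.columns if c not in meta_cols]
    long = panel.melt(
        id_vars=meta_cols, value_vars=value_cols, var_name="assay", value_name="value"
    )
    long.to_csv(path, index=False)


def read_panel_csv(path: str) -> pd.DataFrame:
    """Read a panel CSV in either long or wide format into the wide form."""
    frame = pd.read_csv(path)
    if "assay" in frame.columns and "value" in frame.columns:
        meta_cols = [c for c in frame.columns if c not in ("assay", "value")]
        wide = frame.pivot_table(
            index=meta_cols, columns="assay", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        if "well_id" in wide.columns:
            wide = wide.sort_values("well_id").reset_index(drop=True)
        return wide
    return frame


def write_competition_csv(matrix: binning.CompetitionMatrix, path: str) -> None:
    pd.DataFrame(
        matrix.values, index=matrix.antibody_ids, columns=matrix.antibody_ids
    ).to_csv(path)


def read_competition_csv(path: str) -> binning.CompetitionMatrix:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("competition CSV must have matching row/column ids")
    return binning.CompetitionMatrix(
        antibody_ids=[str(i) for i in frame.index], values=frame.to_numpy(dtype=float)
    )


def dendrogram_to_newick(dendrogram: binning.Dendrogram, leaf_names) -> str:
    """Nested-text (Newick) rendering of the merge tree with merge heights."""
    nodes: dict[int, str] = {i: str(name) for i, name in enumerate(leaf_names)}
    for step, (left, right, height, _) in enumerate(dendrogram.merges):
        nodes[dendrogram.n_leaves + step] = (
            f"({nodes[left]},{nodes[right]}):{height:.6g}"
        )
    return nodes[dendrogram.n_leaves + len(dendrogram.merges) - 1] + ";"


# ------------------------------------------------------------ configuration

@dataclass
class CampaignConfig:
    """Paths, thresholds and seeds for one end-to-end campaign run."""

    germline_fasta: str
    sequences_fasta: str
    metadata_csv: str
    panel_csv: str
    outdir: str
    competition_csv: str | None = None
    clustering_threshold: int = 2
    outlier_k: float = 6.0
    quantile: float = 0.99
    calibrate_channels: tuple[str, ...] = ("od_hu", "od_cyno", "od_mu", "od_huFc")
    funnel: funnel_mod.FunnelConfig = field(default_factory=funnel_mod.FunnelConfig)
    use_calibrated_thresholds: bool = True
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["calibrate_channels"] = list(self.calibrate_channels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "CampaignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "funnel" in data and isinstance(data["funnel"], dict):
            data["funnel"] = funnel_mod.FunnelConfig(**data["funnel"])
        if "calibrate_channels" in data:
            data["calibrate_channels"] = tuple(data["calibrate_channels"])
        return cls(**data)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["calibrate_channels"] = list(self.calibrate_channels)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class CampaignStageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


# -------------------------------------------------------------- the pipeline

def run_campaign(config: CampaignConfig) -> dict:
    """Execute calibrate -> funnel -> annotate -> clonotype -> stats -> epibin.

    Every artifact lands under ``config.outdir``; ``provenance.json``
    records the config hash, seed and package version, making repeat runs
    with identical inputs byte-identical.  Any stage failure aborts with a
    stage-tagged error.
    """
    for attr in ("germline_fasta", "sequences_fasta", "metadata_csv", "panel_csv"):
        path = getattr(config, attr)
        if not os.path.exists(path):
            raise CampaignStageError("inputs", FileNotFoundError(path))
    if config.competition_csv and not os.path.exists(config.competition_csv):
        raise CampaignStageError("inputs", FileNotFoundError(config.competition_csv))

    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    results: dict = {}

    from importlib.metadata import version as pkg_version

    try:
        ver = pkg_version("rabmab")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    with open(out("provenance.json"), "w") as fh:
        json.dump(
            {"config_hash": config.config_hash(), "seed": config.seed, "version": ver},
            fh,
            indent=2,
        )

    # --- calibrate -----------------------------------------------------
    try:
        panel = read_panel_csv(config.panel_csv)
        thresholds = {}
        for channel in config.calibrate_channels:
            cal = funnel_mod.calibrate_threshold(
                panel[channel].to_numpy(), k=config.outlier_k, quantile=config.quantile
            )
            thresholds[channel] = cal
        with open(out("thresholds.yaml"), "w") as fh:
            yaml.safe_dump(
                {ch: float(c.threshold) for ch, c in thresholds.items()}, fh
            )
        results["thresholds"] = {ch: c.threshold for ch, c in thresholds.items()}
    except Exception as exc:
        raise CampaignStageError("calibrate", exc) from exc

    # --- funnel ---------------------------------------------------------
    try:
        fc = config.funnel
        if config.use_calibrated_thresholds:
            fc = dataclasses.replace(
                fc,
                hu_pos=results["thresholds"].get("od_hu", fc.hu_pos),
                cyno_pos=results["thresholds"].get("od_cyno", fc.cyno_pos),
                mu_pos=results["thresholds"].get("od_mu", fc.mu_pos),
                huFc_neg_max=results["thresholds"].get("od_huFc", fc.huFc_neg_max),
            )
        report = funnel_mod.apply_funnel(panel, fc)
        report.stages.to_csv(out("funnel_stages.csv"), index=False)
        with open(out("funnel_report.txt"), "w") as fh:
            fh.write(report.to_text() + "\n")
        results["funnel"] = report
    except Exception as exc:
        raise CampaignStageError("funnel", exc) from exc

    # --- annotate -------------------------------------------------------
    try:
        germlines = germlines_from_fasta(config.germline_fasta)
        metadata = pd.read_csv(config.metadata_csv)
        records = read_repertoire_fasta(config.sequences_fasta, metadata)
        clones = annotation.annotate_repertoire(records, germlines)
        annotation.clones_to_frame(clones).to_csv(out("annotation.csv"), index=False)
        results["clones"] = clones
    except Exception as exc:
        raise CampaignStageError("annotate", exc) from exc

    # --- clonotype ------------------------------------------------------
    try:
        clustering = clonotypes.cluster_clonotypes(
            clones, threshold=config.clustering_threshold
        )
        labels = clustering.label_of()
        pd.DataFrame(
            {"clone_id": list(labels), "cluster": [labels[c] for c in labels]}
        ).sort_values("clone_id").to_csv(out("clusters.csv"), index=False)
        cats = clonotypes.categorize(clustering, clones)
        cats["table"].to_csv(out("diversity_summary.csv"), index=False)
        results["clustering"] = clustering
        results["categories"] = cats
    except Exception as exc:
        raise CampaignStageError("clonotype", exc) from exc

    # --- stats ----------------------------------------------------------
    try:
        length_stats = repstats.cdr3_length_stats(clones, strata=("animal", "bleed"))
        repl_stats = repstats.replacement_stats(clones, strata=("animal", "bleed"))
        pd.concat(
            [
                repstats.summary_frame(length_stats, "cdr3_h_length"),
                repstats.summary_frame(repl_stats, "vh_replacements"),
            ]
        ).to_csv(out("repertoire_stats.csv"), index=False)
        repstats.plot_histograms(length_stats, repl_stats, out("repertoire_hist.png"))
        results["length_stats"] = length_stats
        results["replacement_stats"] = repl_stats
    except Exception as exc:
        raise CampaignStageError("stats", exc) from exc

    # --- epitope binning -------------------------------------------------
    if config.competition_csv:
        try:
            matrix = read_competition_csv(config.competition_csv)
            groups = binning.bin_epitopes(matrix)
            pd.DataFrame(
                {"antibody": groups.antibody_ids, "group": groups.labels}
            ).to_csv(out("epitope_groups.csv"), index=False)
            norm = binning.normalize_matrix(matrix)
            dendro = binning.ward_cluster(norm)
            pd.DataFrame(
                dendro.merges, columns=["left", "right", "height", "size"]
            ).to_csv(out("epitope_merges.csv"), index=False)
            with open(out("epitope_dendrogram.nwk"), "w") as fh:
                fh.write(dendrogram_to_newick(dendro, matrix.antibody_ids) + "\n")
            coords, ratios, _ = binning.pca_confirm(norm, groups.labels)
            pca_frame = pd.DataFrame(
                coords, columns=[f"pc{i + 1}" for i in range(coords.shape[1])]
            )
            pca_frame.insert(0, "antibody", groups.antibody_ids)
            pca_frame.to_csv(out("epitope_pca.csv"), index=False)
            pd.DataFrame(
                groups.asymmetric_pairs, columns=["first_antibody", "second_antibody"]
            ).to_csv(out("epitope_asymmetric.csv"), index=False)
            plot_competition_heatmap(norm, out("epitope_heatmap.png"))
            results["epitopes"] = groups
        except Exception as exc:
            raise CampaignStageError("epibin", exc) from exc
    else:
        log.info("no competition matrix supplied; skipping epitope binning")

    return results


def plot_competition_heatmap(matrix: binning.CompetitionMatrix, path: str) -> None:
    """Heatmap with a 3-level scale: strong / mid / weak competition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap(["green", "black", "red"])
    norm = BoundaryNorm([0.0, 1 / 3, 2 / 3, 1.0], cmap.N)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.imshow(matrix.values, cmap=cmap, norm=norm)
    ax.set_xticks(range(matrix.n), matrix.antibody_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.n), matrix.antibody_ids, fontsize=6)
    ax.set_xlabel("second antibody (pre-complexed)")
    ax.set_ylabel("first antibody (captured)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ------------------------------------------------------- simulation bundles

def write_simulated_campaign(
    outdir: str,
    repertoire_config: synthetic.RepertoireSimConfig | None = None,
    panel_config: synthetic.PanelSimConfig | None = None,
    competition_config: synthetic.CompetitionSimConfig | None = None,
    seed: int | None = None,
) -> CampaignConfig:
    """Generate a full synthetic campaign on disk and return its config."""
    os.makedirs(outdir, exist_ok=True)
    if seed is not None:
        repertoire_config = repertoire_config or synthetic.RepertoireSimConfig(seed=seed)
        panel_config = panel_config or synthetic.PanelSimConfig(seed=seed + 1)
        competition_config = competition_config or synthetic.CompetitionSimConfig(seed=seed + 2)
    repertoire_config = repertoire_config or synthetic.RepertoireSimConfig()
    panel_config = panel_config or synthetic.PanelSimConfig()
    competition_config = competition_config or synthetic.CompetitionSimConfig()

    germlines = synthetic.generate_germline_set(seed=repertoire_config.seed)
    germlines_to_fasta(germlines, os.path.join(outdir, "germlines.fasta"))

    repertoire = synthetic.generate_repertoire(repertoire_config, germlines)
    write_repertoire_fasta(repertoire, os.path.join(outdir, "repertoire.fasta"))
    meta_cols = [c for c in repertoire.columns if c not in ("vh", "vl")]
    repertoire[meta_cols].to_csv(os.path.join(outdir, "metadata.csv"), index=False)

    panel = synthetic.generate_panel(panel_config)
    write_panel_csv(panel, os.path.join(outdir, "panel.csv"))

    matrix, truth = synthetic.generate_competition(competition_config)
    write_competition_csv(matrix, os.path.join(outdir, "competition.csv"))
    np.savetxt(
        os.path.join(outdir, "competition_truth.csv"), truth, fmt="%d", delimiter=","
    )

    return CampaignConfig(
        germline_fasta=os.path.join(outdir, "germlines.fasta"),
        sequences_fasta=os.path.join(outdir, "repertoire.fasta"),
        metadata_csv=os.path.join(outdir, "metadata.csv"),
        panel_csv=os.path.join(outdir, "panel.csv"),
        competition_csv=os.path.join(outdir, "competition.csv"),
        outdir=os.path.join(outdir, "reports"),
        seed=repertoire_config.seed,
    )
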