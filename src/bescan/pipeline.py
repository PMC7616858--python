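"""End-to-end orchestration: simulate -> annotate -> score -> map -> report.

A run is fully described by a :class:`RunConfig`; every parameter that
changes a number lands in the emitted ``run_manifest.yaml`` together with
the package version and a config hash, so re-running from a manifest
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .edits import (
    annotate_guides,
    predictions_to_frame,
    read_manifest,
    validate_manifest,
    write_manifest,
)
from .gene_model import load_gene_model, write_gene_model
from .residues import build_residue_map, domain_enrichment, screen_concordance
from .scoring import ScoringParams, ScreenCounts, control_qc, score_screen
from .simulate import (
    SimulationConfig,
    default_domain_track,
    simulate_gene_and_library,
    simulate_screen_counts,
)

log = logging.getLogger("bescan")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed validation; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a full run depends on."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    window: tuple[int, int] = (4, 8)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    hit_z: float = -2.0
    aggregate: str = "min"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        scoring = raw.pop("scoring", None)
        cfg = cls(**raw)
        if sim is not None:
            if "window" in sim:
                sim["window"] = tuple(sim["window"])
            if "editors" in sim:
                sim["editors"] = tuple(sim["editors"])
            if "cell_lines" in sim:
                sim["cell_lines"] = tuple(sim["cell_lines"])
            cfg.simulation = SimulationConfig(**sim)
        if scoring is not None:
            cfg.scoring = ScoringParams(**scoring)
        cfg.window = tuple(cfg.window)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            if isinstance(sim.get("essential_residues"), frozenset):
                sim["essential_residues"] = sorted(sim["essential_residues"])
            d["simulation"] = sim
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # paths do not alter any number
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full simulated-study pipeline into ``config.out_dir``.

    Outputs: gene FASTA/GFF3, manifest, counts + sample sheet, truth,
    predictions, per-screen scores, QC report, residue maps, domain
    enrichment, cross-line concordance and the run manifest.  Partial
    outputs are removed on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = False
    try:
        sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
        if sim_cfg.seed != config.seed:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        config = dataclasses.replace(config, simulation=sim_cfg)
        chash = config.config_hash()
        hdr = [f"bescan {__version__}", f"config_hash {chash}"]

        # -- simulate -----------------------------------------------------
        try:
            model, manifest, truth = simulate_gene_and_library(sim_cfg)
            counts = simulate_screen_counts(manifest, truth, sim_cfg)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        created = True
        write_gene_model(model, str(out / "gene.fasta"), str(out / "gene.gff3"))
        write_manifest(manifest, str(out / "manifest.tsv"), model.contig_id)
        counts.counts.to_csv(out / "counts.tsv", sep="\t")
        counts.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        _write_tsv(truth.guides, out / "truth.tsv", hdr)
        log.info("simulated %d guides, %d samples", len(manifest),
                 len(counts.samples))

        # -- annotate -----------------------------------------------------
        try:
            report = validate_manifest(manifest, model)
            preds = {
                spec.name: annotate_guides(manifest, spec, model)
                for spec in sim_cfg.editor_specs()
            }
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc
        pred_frame = pd.concat(
            [predictions_to_frame(p) for p in preds.values()], ignore_index=True
        )
        _write_tsv(pred_frame, out / "predictions.tsv", hdr)
        log.info("manifest categories: %s", report["category_counts"])

        # -- score --------------------------------------------------------
        scores: dict[tuple[str, str], pd.DataFrame] = {}
        qc_rows = []
        try:
            for cell_line in sim_cfg.cell_lines:
                for editor in sim_cfg.editors:
                    s = score_screen(counts, config.scoring, cell_line, editor)
                    scores[(cell_line, editor)] = s
                    n_pass = int(s["pass_filter"].sum())
                    log.info(
                        "screen %s/%s: %d/%d guides pass the T0 read floor",
                        cell_line, editor, n_pass, len(s),
                    )
                    qc = control_qc(s, manifest)
                    qc_rows.append(
                        {
                            "cell_line": cell_line,
                            "editor": editor,
                            "n_pass": n_pass,
                            "essential_vs_nonessential_auroc":
                                qc["essential_vs_nonessential_auroc"],
                            **{
                                f"median_z_{k}": v
                                for k, v in qc["median_z"].items()
                            },
                        }
                    )
        except Exception as exc:
            raise PipelineError("score", str(exc)) from exc
        for (cell_line, editor), s in scores.items():
            _write_tsv(s, out / f"scores_{cell_line}_{editor}.tsv", hdr)
        _write_tsv(pd.DataFrame(qc_rows), out / "qc.tsv", hdr)

        # -- map ----------------------------------------------------------
        protein_length = len(model.protein)
        track = default_domain_track(protein_length)
        track.to_file(str(out / "domains.tsv"))
        enr_rows = []
        try:
            for cell_line in sim_cfg.cell_lines:
                # build one map per editor, then merge contribution tables
                rmaps = [
                    build_residue_map(
                        scores[(cell_line, spec.name)], preds[spec.name],
                        protein_length, hit_z=config.hit_z,
                        aggregate=config.aggregate,
                    )
                    for spec in sim_cfg.editor_specs()
                ]
                combined = _combine_maps(rmaps, protein_length, config)
                combined.annotate_domains(track)
                _write_tsv(
                    combined.table.reset_index(),
                    out / f"residue_map_{cell_line}.tsv",
                    hdr,
                )
                enr = domain_enrichment(combined, track)
                enr.insert(0, "cell_line", cell_line)
                enr_rows.append(enr)
        except Exception as exc:
            raise PipelineError("map", str(exc)) from exc
        _write_tsv(pd.concat(enr_rows, ignore_index=True),
                   out / "enrichment.tsv", hdr)

        # -- concordance --------------------------------------------------
        conc_rows = []
        targeting_ids = {g.guide_id for g in manifest if g.category == "targeting"}
        try:
            if len(sim_cfg.cell_lines) >= 2:
                a, b = sim_cfg.cell_lines[:2]
                for editor in sim_cfg.editors:
                    sa = scores[(a, editor)]
                    sb = scores[(b, editor)]
                    sa = sa[sa["guide_id"].isin(targeting_ids)]
                    sb = sb[sb["guide_id"].isin(targeting_ids)]
                    r, r2, n = screen_concordance(sa, sb)
                    conc_rows.append(
                        {"editor": editor, "screen_a": a, "screen_b": b,
                         "r": r, "r2": r2, "n_shared": n}
                    )
        except Exception as exc:
            raise PipelineError("concordance", str(exc)) from exc
        _write_tsv(pd.DataFrame(conc_rows), out / "concordance.tsv", hdr)

        # -- run manifest ---------------------------------------------------
        manifest_doc = {
            "package": "bescan",
            "version": __version__,
            "config_hash": chash,
            "config": config.to_dict(),
        }
        with open(out / "run_manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest_doc, fh, sort_keys=True)
        return out
    except Exception:
        if created:
            for p in sorted(out.glob("*")):
                p.unlink()
        raise


def _combine_maps(rmaps, protein_length, config):
    """Merge per-editor residue maps into one per-cell-line map."""
    from .residues import ResidueMap

    contrib = pd.concat([r.contributions for r in rmaps], ignore_index=True)
    import numpy as np

    index = pd.RangeIndex(1, protein_length + 1, name="residue")
    if contrib.empty:
        agg = pd.Series(np.nan, index=index)
        n = pd.Series(0, index=index)
        guides = pd.Series("", index=index)
    else:
        grouped = contrib.groupby("residue")["z"]
        agg = (grouped.min() if config.aggregate == "min"
               else grouped.mean()).reindex(index)
        n = grouped.size().reindex(index, fill_value=0)
        guides = (
            contrib.groupby("residue")["guide_id"]
            .apply(lambda s: ";".join(sorted(set(s))))
            .reindex(index, fill_value="")
        )
    hit = pd.Series(pd.NA, index=index, dtype="boolean")
    covered = n > 0
    hit[covered] = agg[covered] <= config.hit_z
    table = pd.DataFrame(
        {"aggregate_z": agg, "n_guides": n.astype(int), "hit": hit,
         "guides": guides},
        index=index,
    )
    return ResidueMap(table=table, contributions=contrib, hit_z=config.hit_z)
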