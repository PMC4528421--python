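"""Pipeline orchestration: preprocess -> annotate -> model fit -> PCA ->
selection -> report, with a single YAML config, deterministic per-stage
seed derivation and a run manifest.

Per-gene selection analyses are embarrassingly parallel; they are executed
as an ordinary (optionally process-parallel) map with per-gene seeds
derived deterministically from the run seed, so parallel and serial runs
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .annotate import (HAS_STOP, OUT_OF_FRAME, PRODUCTIVE, UNANNOTATABLE,
                       VDJAnnotator, annotation_table, read_germline_db)
from .pairs import CodonPair
from .selection import SiteSelectionModel, selection_report
from .seqio import (Read, collapse_reads, read_fasta, read_well_map,
                    write_consensus_fasta)
from .starmodel import (PairCounts, PartitionedStarModel, pca_models,
                        rank_models)

logger = logging.getLogger(__name__)

DEFAULTS = dict(
    seed=1,
    workers=1,
    max_dist=2,
    sw=dict(match=2, mismatch=-3, gap_open=5, gap_extend=1, min_score_fraction=0.5),
    models=["trQiGi", "trQiGs", "trQsGs", "tiQiGi"],
    fit_tol=0.001,
    selection=dict(mode="outofframe", min_coverage=100, bci_level=0.95,
                   mcmc_iters=20000, mcmc_thin=40, prior_mean=0.1,
                   n_rate_draws=500),
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    reads_fasta: Path | None = None
    well_map: Path | None = None
    germline_db: Path | None = None
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        opts = {**DEFAULTS, **raw}
        for key in ("sw", "selection"):
            opts[key] = {**DEFAULTS[key], **(raw.get(key) or {})}
        cfg = cls(
            output_dir=Path(opts.pop("output_dir", "bcrstar_run")),
            reads_fasta=Path(raw["reads_fasta"]) if raw.get("reads_fasta") else None,
            well_map=Path(raw["well_map"]) if raw.get("well_map") else None,
            germline_db=Path(raw["germline_db"]) if raw.get("germline_db") else None,
            options=opts,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        o = self.options
        if o["seed"] is None:
            raise ValueError("a run seed is required")
        sel = o["selection"]
        for k in ("min_coverage", "mcmc_iters", "mcmc_thin"):
            if sel[k] <= 0:
                raise ValueError(f"selection.{k} must be positive")
        if not 0 < sel["bci_level"] < 1:
            raise ValueError("selection.bci_level must be in (0, 1)")


def stage_seed(run_seed: int, stage: str, item: str = "") -> int:
    """Deterministic 31-bit seed for a (stage, item) pair."""
    h = hashlib.sha256(f"{run_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Executes pipeline stages into a run directory with a manifest.

    Stages are individually resumable: a stage whose outputs already exist
    is skipped (delete the file to recompute).
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"version": __version__,
                               "seed": config.options["seed"], "stages": {}}

    def _record(self, stage: str, t0: float, outputs: list[Path], **info) -> None:
        self.manifest["stages"][stage] = dict(
            seconds=round(time.time() - t0, 2),
            outputs={str(p): _sha256(p) for p in outputs if p.exists()},
            **info,
        )
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    # -- stages -------------------------------------------------------------

    def preprocess(self) -> Path:
        out = self.out / "consensus.fasta"
        if out.exists():
            return out
        t0 = time.time()
        cfg = self.config
        records = read_fasta(cfg.reads_fasta)
        wells = read_well_map(cfg.well_map) if cfg.well_map else {}
        reads = [Read(id=rid, well=wells.get(rid, "well0"), nucleotides=seq)
                 for rid, seq in records]
        consensuses = collapse_reads(reads, max_dist=cfg.options["max_dist"])
        write_consensus_fasta(out, consensuses)
        self._record("preprocess", t0, [out],
                     n_reads=len(reads), n_consensus=len(consensuses))
        return out

    def annotate(self, sequences_fasta: Path) -> Path:
        out = self.out / "annotations.tsv"
        if out.exists():
            return out
        t0 = time.time()
        cfg = self.config
        db = read_germline_db(cfg.germline_db)
        annotator = VDJAnnotator(db, **cfg.options["sw"],
                                 seed=stage_seed(cfg.options["seed"], "annotate"))
        pairs = []
        n_failed = 0
        for rid, seq in read_fasta(sequences_fasta):
            pair = annotator.annotate(rid, seq)
            if pair is None or pair.frame_class == UNANNOTATABLE:
                n_failed += 1
                continue
            pairs.append(pair)
        annotation_table(pairs).to_csv(out, sep="\t", index=False)
        self._pairs = pairs
        self._record("annotate", t0, [out],
                     n_annotated=len(pairs), n_unannotatable=n_failed)
        return out

    def fit_models(self, pairs) -> Path:
        out = self.out / "model_ranking.tsv"
        t0 = time.time()
        counts = [PairCounts.from_annotated(p) for p in pairs
                  if p.frame_class != HAS_STOP]
        counts = [c for c in counts if c.counts]
        results = []
        for name in self.config.options["models"]:
            res = PartitionedStarModel(counts, model_name=name).fit(
                tol=self.config.options["fit_tol"])
            results.append(res)
            (self.out / f"model_{name}.json").write_text(
                json.dumps(res.params_dict(), indent=2))
        table = rank_models(results)
        table.to_csv(out, sep="\t", index=False)
        best = min(results, key=lambda r: r.aic)
        t_hat = best.branch_lengths
        if not isinstance(t_hat, dict):
            import pandas as pd

            pd.DataFrame({"pair_id": [c.id for c in counts],
                          "branch_length": t_hat}).to_csv(
                self.out / "branch_lengths.tsv", sep="\t", index=False)
        self._model_results = results
        self._record("fit_models", t0, [out], models=list(table["model"]))
        return out

    def pca(self, results_by_label: dict) -> Path:
        out = self.out / "pca_scores.csv"
        t0 = time.time()
        labels = list(results_by_label)
        t_hat = float(np.median([r.median_branch_length()
                                 for r in results_by_label.values()]))
        vectors = np.stack([results_by_label[k].clr_vector("V", t=t_hat)
                            for k in labels])
        scores, _, evr = pca_models(vectors, labels)
        import pandas as pd

        df = pd.DataFrame({"label": labels, "pc1": scores[:, 0],
                           "pc2": scores[:, 1] if scores.shape[1] > 1 else 0.0})
        df.to_csv(out, index=False)
        self._record("pca", t0, [out],
                     explained_variance=[round(float(v), 4) for v in evr[:2]])
        return out

    def select(self, pairs_by_gene: dict, frame_classes_by_gene: dict) -> Path:
        out = self.out / "selection.tsv"
        t0 = time.time()
        cfg = self.config.options
        genes = sorted(pairs_by_gene)
        jobs = [(gene, pairs_by_gene[gene], frame_classes_by_gene[gene],
                 cfg["selection"], stage_seed(cfg["seed"], "select", gene))
                for gene in genes]
        if cfg["workers"] > 1:
            with ProcessPoolExecutor(max_workers=cfg["workers"]) as pool:
                outputs = list(pool.map(_select_one_gene, jobs))
        else:
            outputs = [_select_one_gene(j) for j in jobs]
        import pandas as pd

        tables, summaries = zip(*outputs)
        pd.concat(tables, ignore_index=True).to_csv(out, sep="\t", index=False)
        (self.out / "selection_summary.json").write_text(
            json.dumps(list(summaries), indent=2))
        self._record("select", t0, [out], genes=genes)
        return out


def _select_one_gene(job):
    gene, pairs, frame_classes, sel_cfg, seed = job
    model = SiteSelectionModel(
        pairs, frame_classes=frame_classes, mode=sel_cfg["mode"],
        prior_mean=sel_cfg["prior_mean"], mcmc_iters=sel_cfg["mcmc_iters"],
        mcmc_thin=sel_cfg["mcmc_thin"], min_coverage=sel_cfg["min_coverage"],
        bci_level=sel_cfg["bci_level"], n_rate_draws=sel_cfg["n_rate_draws"])
    results = model.fit(seed=seed)
    return selection_report(results, gene)


def pairs_from_annotations(pairs, min_v_columns: int = 9):
    """Group annotated pairs by V gene into codon-aligned pair sets.

    Returns (pairs_by_gene, frame_classes_by_gene); has_stop and
    unannotatable sequences are excluded, and reads covering fewer than
    ``min_v_columns`` germline-V nucleotides are dropped.
    """
    by_gene: dict[str, list[CodonPair]] = {}
    fc_by_gene: dict[str, list[str]] = {}
    for p in pairs:
        if p.frame_class not in (PRODUCTIVE, OUT_OF_FRAME):
            continue
        g, q = p.v_codon_alignment()
        if (q >= 0).sum() < min_v_columns:
            continue
        L = g.size // 3
        trip_g = g[:3 * L].reshape(-1, 3)
        trip_q = q[:3 * L].reshape(-1, 3)
        g_cod = 16 * trip_g[:, 0] + 4 * trip_g[:, 1] + trip_g[:, 2]
        q_cod = 16 * trip_q[:, 0] + 4 * trip_q[:, 1] + trip_q[:, 2]
        q_cod[(trip_q < 0).any(axis=1)] = -1
        g_cod[(trip_g < 0).any(axis=1)] = -1
        by_gene.setdefault(p.v_gene.name, []).append(
            CodonPair(id=p.query_id, germline=g_cod, query=q_cod))
        fc_by_gene.setdefault(p.v_gene.name, []).append(p.frame_class)
    return by_gene, fc_by_gene


def run_pipeline(config: RunConfig | str | Path) -> Path:
    """Execute all stages in order; returns the run directory."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    run = PipelineRun(config)
    try:
        sequences = run.preprocess() if config.well_map else config.reads_fasta
        run.annotate(sequences)
        pairs = run._pairs
        run.fit_models(pairs)
        # compositional PCA over per-(gene, frame) substitution processes
        groups: dict[str, list] = {}
        for p in pairs:
            if p.frame_class in (PRODUCTIVE, OUT_OF_FRAME):
                groups.setdefault(f"{p.v_gene.name}|{p.frame_class}", []).append(p)
        fits = {}
        for label, members in sorted(groups.items()):
            counts = [c for c in map(PairCounts.from_annotated, members) if c.counts]
            if len(counts) >= 5:
                fits[label] = PartitionedStarModel(
                    counts, model_name=config.options["models"][0]).fit(
                        tol=config.options["fit_tol"], max_rounds=4)
        if len(fits) >= 2:
            run.pca(fits)
        by_gene, fc_by_gene = pairs_from_annotations(pairs)
        usable = {g: v for g, v in by_gene.items() if len(v) >= 2}
        run.select(usable, {g: fc_by_gene[g] for g in usable})
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        done = list(run.manifest["stages"])
        raise RuntimeError(
            f"pipeline aborted after stages {done or 'none'}: {exc}") from exc
    return run.out
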