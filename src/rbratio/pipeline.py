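"""End-to-end orchestration: simulate/load -> signature -> cluster -> enrich
-> train -> classify -> group summary.

Every intermediate is persisted in the plain-text formats of
:mod:`rbratio.io`, and the final :class:`RunReport` records parameters,
SHA-256 digests of every artifact, the signature size, per-class call
counts, and the predicted RB1-negative frequency per sample group
(reported with numerator and denominator). Group frequencies are recounted
from the persisted calls file, never from in-memory state, so the report
can never diverge from the artifacts on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import classifier as clf
from . import io as rio
from .enrichment import enrich, signature_query
from .errors import ConfigError, ValidationError
from .signature import cluster_2d, derive_signature
from .simulate import SimulationConfig, simulate_ct_panel, simulate_expression_panel

logger = logging.getLogger("rbratio")

__all__ = ["RunConfig", "RunReport", "run_end_to_end"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run.

    With no input paths the run is fully synthetic: the expression panel
    and qPCR panel are generated from ``simulation`` (seeded by ``seed``),
    and the planted truth doubles as the gene-set collection for the
    enrichment stage.
    """

    outdir: Path
    seed: int = 1
    sd_min: float = 0.1
    alpha: float = 0.001
    efficiency: float = 2.0
    direction: str = "positive"
    model: str = "train"  # "train" | "published" | path to a model JSON
    ccnd1_symbol: str = "CCND1"
    cdkn2a_symbol: str = "CDKN2A"
    simulation: SimulationConfig | None = None
    matrix_path: Path | None = None
    labels_path: Path | None = None
    ct_path: Path | None = None
    ct_labels_path: Path | None = None
    sets_path: Path | None = None
    groups_path: Path | None = None

    def sim(self) -> SimulationConfig:
        return self.simulation if self.simulation is not None else SimulationConfig(seed=self.seed)

    @classmethod
    def from_json(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        sim = raw.pop("simulation", None)
        paths = {
            k: Path(raw.pop(k)) for k in list(raw)
            if k.endswith("_path") and raw[k] is not None
        }
        known = {
            "seed", "sd_min", "alpha", "efficiency", "direction", "model",
            "ccnd1_symbol", "cdkn2a_symbol",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run parameter(s): {sorted(unknown)}")
        cfg = cls(
            outdir=Path(outdir),
            simulation=SimulationConfig.from_dict(sim) if sim else None,
            **paths,
            **raw,
        )
        return cfg


@dataclass
class RunReport:
    parameters: dict[str, Any]
    artifacts: dict[str, str]  # relative path -> sha256
    signature_size: int = 0
    n_input_genes: int = 0
    call_counts: dict[str, int] = field(default_factory=dict)
    group_frequencies: list[dict[str, Any]] = field(default_factory=list)
    enrichment_top: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [
            "rbratio end-to-end run",
            f"  genes in: {self.n_input_genes}; signature size: {self.signature_size}",
            f"  calls: {self.call_counts}",
            "  predicted RB1-negative frequency by group:",
        ]
        for g in self.group_frequencies:
            lines.append(
                f"    {g['group']}: {g['percent']:.0f}% ({g['negatives']}/{g['n']})"
            )
        if self.enrichment_top:
            lines.append("  top enrichment:")
            for e in self.enrichment_top:
                lines.append(f"    {e['set_name']}: p={e['p']:.3g} (k={e['k']}/{e['K']})")
        lines.append(f"  artifacts: {len(self.artifacts)} files")
        return "\n".join(lines) + "\n"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def negative_frequencies(
    calls: pd.DataFrame, groups: dict[str, str]
) -> list[dict[str, Any]]:
    """Per-group predicted RB1-negative frequency with numerator/denominator."""
    out = []
    for group in sorted(set(groups.values())):
        members = [s for s, g in groups.items() if g == group]
        sub = calls[calls["sample_id"].isin(members)]
        n = len(sub)
        neg = int((sub["call"] == "negative").sum())
        out.append(
            {
                "group": group,
                "negatives": neg,
                "n": n,
                "frequency": (neg / n) if n else 0.0,
                "percent": (100.0 * neg / n) if n else 0.0,
            }
        )
    return out


def run_end_to_end(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def persist(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        artifacts[name] = path
        return path

    logger.info("stage=start seed=%d outdir=%s", config.seed, outdir)

    # --- stage 1: expression panel -------------------------------------
    truth: tuple[str, ...] = ()
    if config.matrix_path is not None:
        if config.labels_path is None:
            raise ConfigError("matrix_path requires labels_path")
        matrix = rio.read_expression_matrix(config.matrix_path)
        labels = rio.read_labels(config.labels_path)
    else:
        matrix, labels, truth = simulate_expression_panel(config.sim())
    persist("matrix.tsv", rio.write_expression_matrix, matrix)
    persist("labels.tsv", rio.write_labels, labels)
    logger.info(
        "stage=data n_genes=%d n_samples=%d n_pos=%d n_neg=%d",
        *matrix.shape, labels.n_positive(), labels.n_negative(),
    )

    # --- stage 2: signature ---------------------------------------------
    signature = derive_signature(matrix, labels, config.sd_min, config.alpha)
    persist(
        "signature.tsv",
        lambda df, p: df.to_csv(p, sep="\t", index=False),
        signature.to_frame(),
    )
    logger.info(
        "stage=signature sd_min=%g alpha=%g selected=%d of=%d",
        config.sd_min, config.alpha, len(signature), signature.n_input_genes,
    )

    # --- stage 3: clustering --------------------------------------------
    if len(signature) >= 2:
        clustering = cluster_2d(matrix.subset_genes(signature.gene_ids))
        persist("genes.nwk", lambda t, p: Path(p).write_text(t + "\n"), clustering.gene_tree.to_newick())
        persist("samples.nwk", lambda t, p: Path(p).write_text(t + "\n"), clustering.sample_tree.to_newick())
        persist("gene_order.txt", lambda o, p: Path(p).write_text("\n".join(o) + "\n"), clustering.gene_order)
        persist("sample_order.txt", lambda o, p: Path(p).write_text("\n".join(o) + "\n"), clustering.sample_order)
        logger.info("stage=cluster genes=%d samples=%d", len(clustering.gene_order), len(clustering.sample_order))

    # --- stage 4: enrichment --------------------------------------------
    enrichment_top: list[dict[str, Any]] = []
    if config.sets_path is not None:
        sets = rio.read_gene_sets(config.sets_path)
    elif truth:
        # synthetic run: the planted truth defines the annotation, split by
        # direction so the up-regulated query should hit the "up" set
        up = [g for i, g in enumerate(truth) if i % 2 == 0]
        down = [g for i, g in enumerate(truth) if i % 2 == 1]
        sets = rio.GeneSetCollection(
            (
                rio.GeneSet("planted_up", "planted genes up in RB1-positive", tuple(up)),
                rio.GeneSet("planted_down", "planted genes down in RB1-positive", tuple(down)),
            )
        )
        persist("sets.gmt", rio.write_gene_sets, sets)
    else:
        sets = None
    if sets is not None and len(signature):
        query = signature_query(signature, config.direction)
        report = enrich(query, sets, list(matrix.gene_ids))
        persist(
            "enrichment.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index=False),
            report.to_frame(),
        )
        enrichment_top = [
            {"set_name": r.set_name, "p": r.p, "k": r.k, "K": r.K}
            for r in report.results[:5]
        ]
        logger.info(
            "stage=enrich direction=%s n_query=%d dropped=%d",
            config.direction, len(query), report.n_query_outside_universe,
        )

    # --- stage 5: qPCR panel, model, calls ------------------------------
    truth_x: dict[str, float] = {}
    if config.ct_path is not None:
        ct = rio.read_ct_table(config.ct_path)
        ct_labels = rio.read_labels(config.ct_labels_path) if config.ct_labels_path else None
    else:
        ct, ct_labels, truth_x = simulate_ct_panel(config.sim().replace(n_pos=7, n_neg=5))
    persist("ct_panel.csv", rio.write_ct_table, ct)
    scores = clf.scores_from_ct_table(
        ct, config.ccnd1_symbol, config.cdkn2a_symbol, config.efficiency
    )
    persist("scores.tsv", clf.write_scores, scores)

    if config.model == "published":
        model = clf.published_model()
    elif config.model == "train":
        if ct_labels is None:
            raise ConfigError("model='train' requires ct panel labels")
        model = clf.train_discriminant(scores, ct_labels)
    else:
        model = clf.load_model(config.model)
    persist("model.json", clf.save_model, model)
    logger.info("stage=model source=%s threshold=%g", model.provenance.get("source"), model.threshold)

    preds = clf.classify(scores, model)
    calls = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in preds],
            "x": [p.x for p in preds],
            "threshold": model.threshold,
            "call": [p.call for p in preds],
            "margin": [p.margin for p in preds],
        }
    )
    calls_path = persist("calls.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), calls)

    # --- stage 6: group summary -----------------------------------------
    if config.groups_path is not None:
        gdf = pd.read_csv(config.groups_path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(gdf.columns):
            raise ValidationError("groups file needs columns sample_id, group")
        groups = dict(zip(gdf["sample_id"], gdf["group"]))
    elif ct_labels is not None:
        groups = {
            s: ("true-positive-class" if ct_labels[s] == 1 else "true-negative-class")
            for s in ct_labels.sample_ids
        }
    else:
        groups = {p.sample_id: "all" for p in preds}
    persisted_calls = pd.read_csv(calls_path, sep="\t", dtype={"sample_id": str})
    freqs = negative_frequencies(persisted_calls, groups)
    for g in freqs:
        logger.info(
            "stage=summary group=%s negatives=%d n=%d", g["group"], g["negatives"], g["n"]
        )

    call_counts = {
        "positive": int((calls["call"] == "positive").sum()),
        "negative": int((calls["call"] == "negative").sum()),
    }
    report = RunReport(
        parameters={
            "seed": config.seed,
            "sd_min": config.sd_min,
            "alpha": config.alpha,
            "efficiency": config.efficiency,
            "direction": config.direction,
            "model": config.model,
            "threshold": model.threshold,
            "simulation": None if (config.matrix_path and config.ct_path) else vars(config.sim()) | {},
            "truth_x_available": bool(truth_x),
        },
        artifacts={name: _digest(path) for name, path in sorted(artifacts.items())},
        signature_size=len(signature),
        n_input_genes=signature.n_input_genes,
        call_counts=call_counts,
        group_frequencies=freqs,
        enrichment_top=enrichment_top,
    )
    (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    (outdir / "report.txt").write_text(report.to_text(), encoding="utf-8")
    logger.info("stage=done artifacts=%d", len(report.artifacts))
    return report
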