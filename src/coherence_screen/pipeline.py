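"""End-to-end orchestration: simulate-or-load, dual DEG screen, ant-colony
frequency screen, clinical ranking, and the two-gene diagnostic model.

Every stage writes its table to the output directory so any later stage can
be re-run in isolation; the machine-readable run report is JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coherence_screen import __version__
from coherence_screen import clinical_assoc, diagnostic, diffexpr
from coherence_screen.aco_seriation import (
    ACOParams,
    GeneSequence,
    distance_matrix,
    neighbor_frequency,
    repeated_ordering,
    screen_candidates,
)
from coherence_screen.dataio import (
    DataIOError,
    ExpressionMatrix,
    PhenotypeTable,
    read_expression,
    read_phenotype,
    write_expression,
    write_phenotype,
    write_table,
)
from coherence_screen.synthetic_data import SyntheticConfig, generate_expression

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSET_ACO = 100
SEED_OFFSET_DIAG = 200
SEED_OFFSET_SPLIT = 300


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Exactly one of ``synthetic`` or (``expression_path``, ``phenotype_path``)
    must be provided.
    """

    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    phenotype_path: str | None = None
    anchor: str = "METTL3"
    lfc_min: float = 0.3
    p_max: float = 0.05
    deg_method: str = "welch"
    adjust_p: bool = False
    aco: ACOParams = field(default_factory=ACOParams)
    window: int = 5
    n_runs: int = 10
    min_count: int = 5
    strict_gt: bool = False
    standardize: bool = True
    sample_scope: str = "case"  # distance-matrix scope: "case" or "all"
    kernel: str = "rbf"
    svm_c: float = 1.0
    cv_folds: int = 10
    train_fraction: float = 0.6
    fit_case_only: bool = True
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        findings = validate_config(self)
        if findings:
            raise DataIOError("invalid pipeline config: " + "; ".join(findings))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        if "aco" in raw and raw["aco"] is not None:
            aco_raw = dict(raw["aco"])
            raw["aco"] = ACOParams(**aco_raw)
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise DataIOError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable findings (empty = valid)."""
    findings: list[str] = []
    has_files = config.expression_path is not None or config.phenotype_path is not None
    if config.synthetic is not None and has_files:
        findings.append("provide either synthetic config or input paths, not both")
    if config.synthetic is None and not (
        config.expression_path and config.phenotype_path
    ):
        findings.append(
            "need a synthetic config or both expression_path and phenotype_path"
        )
    if config.lfc_min <= 0 or config.p_max <= 0:
        findings.append("DEG thresholds must be > 0")
    if config.window < 1:
        findings.append("window must be >= 1")
    if config.n_runs < 1:
        findings.append("n_runs must be >= 1")
    if not (1 <= config.min_count <= config.n_runs):
        findings.append("min_count must lie in [1, n_runs]")
    if config.sample_scope not in ("case", "all"):
        findings.append("sample_scope must be 'case' or 'all'")
    if config.kernel not in ("linear", "rbf"):
        findings.append("kernel must be 'linear' or 'rbf'")
    if not (0.0 < config.train_fraction < 1.0):
        findings.append("train_fraction must lie in (0, 1)")
    if config.cv_folds < 2:
        findings.append("cv_folds must be >= 2")
    return findings


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    anchor: str
    counts: dict[str, int]
    candidates: list[str]
    chosen_candidate: str | None
    candidate_source: str | None
    fit_table: list[dict]
    cv_auc_values: list[float]
    cv_mean_auc: float | None
    holdout_auc: float | None
    anchor_threshold: float | None
    flags: list[str]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _deg_frame(records, gene_set) -> pd.DataFrame:
    passed = set(gene_set.genes)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "passed_filter": [r.gene_id in passed for r in records],
        }
    )


def _sequences_frame(seqs: list[GeneSequence]) -> pd.DataFrame:
    rows = []
    for run, seq in enumerate(seqs):
        for position, gene in enumerate(seq.order):
            rows.append(
                {"run": run, "position": position, "gene_id": gene,
                 "length": seq.length, "seed": seq.seed}
            )
    return pd.DataFrame(rows)


def load_sequences(path: str | Path) -> list[GeneSequence]:
    """Rebuild GeneSequence objects from a sequences TSV (resume support)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    seqs = []
    for run, grp in df.groupby("run", sort=True):
        grp = grp.sort_values("position")
        seqs.append(
            GeneSequence(
                order=tuple(grp["gene_id"].astype(str)),
                length=float(grp["length"].iloc[0]),
                seed=int(grp["seed"].iloc[0]),
            )
        )
    return seqs


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; see the module docstring for outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags: list[str] = []
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    # ---- stage: data -----------------------------------------------------
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            expr, phen, truth = generate_expression(syn)
            outputs["expression"] = str(
                write_expression(expr, outdir / "expression.tsv", seed=config.seed)
            )
            outputs["phenotype"] = str(
                write_phenotype(phen, outdir / "phenotype.tsv", seed=config.seed)
            )
            with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
                json.dump(dataclasses.asdict(truth), fh, indent=2)
            outputs["ground_truth"] = str(outdir / "ground_truth.json")
        else:
            expr = read_expression(config.expression_path)
            phen = read_phenotype(config.phenotype_path)
        anchor = config.anchor if config.synthetic is None else syn.anchor_name
        if anchor not in expr.gene_ids:
            raise DataIOError(f"anchor '{anchor}' not in expression matrix")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("data", exc) from exc

    labels = phen.labels_for(expr.sample_ids)
    case_ids = [s for s, g in zip(expr.sample_ids, labels) if g == "case"]
    counts["n_samples"] = expr.n_samples
    counts["n_case"] = len(case_ids)
    counts["n_control"] = expr.n_samples - len(case_ids)
    counts["n_genes"] = expr.n_genes

    # ---- stage: dual DEG screen -----------------------------------------
    try:
        recs_cc = diffexpr.two_group_test(expr, labels, method=config.deg_method)
        if config.adjust_p:
            recs_cc = diffexpr.adjust_bh(recs_cc)
        set_cc = diffexpr.filter_degs(recs_cc, config.lfc_min, config.p_max)

        split = diffexpr.median_split(expr, anchor, case_ids)
        case_expr = expr.subset(sample_ids=case_ids)
        split_labels = [split[s] for s in case_ids]
        recs_split = diffexpr.two_group_test(
            case_expr, split_labels, group_a="high", group_b="low",
            method=config.deg_method,
        )
        if config.adjust_p:
            recs_split = diffexpr.adjust_bh(recs_split)
        set_split = diffexpr.filter_degs(recs_split, config.lfc_min, config.p_max)
        intersection = diffexpr.intersect_gene_sets(set_cc.genes, set_split.genes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diffexpr", exc) from exc

    counts["degs_case_control"] = len(set_cc)
    counts["degs_case_control_up"] = len(set_cc.up)
    counts["degs_case_control_down"] = len(set_cc.down)
    counts["degs_anchor_split"] = len(set_split)
    counts["degs_anchor_split_up"] = len(set_split.up)
    counts["degs_anchor_split_down"] = len(set_split.down)
    counts["intersection"] = len(intersection)
    logger.info(
        "DEGs case/control: %d (%d up, %d down); anchor split: %d; intersection: %d",
        len(set_cc), len(set_cc.up), len(set_cc.down), len(set_split),
        len(intersection),
    )
    outputs["degs_case_control"] = str(
        write_table(_deg_frame(recs_cc, set_cc), outdir / "degs_case_control.tsv",
                    seed=config.seed)
    )
    outputs["degs_anchor_split"] = str(
        write_table(_deg_frame(recs_split, set_split),
                    outdir / "degs_anchor_split.tsv", seed=config.seed)
    )

    # ---- stage: ACO frequency screen ------------------------------------
    candidates: list[str] = []
    freq = None
    aco_universe = [anchor] + [g for g in intersection if g != anchor]
    counts["aco_universe"] = len(aco_universe)
    if len(aco_universe) < 3:
        flags.append("empty_or_tiny_intersection")
        logger.info("intersection too small for seriation (%d genes incl. anchor)",
                    len(aco_universe))
    else:
        try:
            scope = case_ids if config.sample_scope == "case" else None
            dist = distance_matrix(
                expr, genes=aco_universe, samples=scope,
                standardize=config.standardize,
            )
            aco_params = dataclasses.replace(
                config.aco, seed=config.seed + SEED_OFFSET_ACO
            )
            seqs = repeated_ordering(dist, aco_params, n_runs=config.n_runs)
            freq = neighbor_frequency(seqs, anchor, window=config.window)
            candidates = screen_candidates(
                freq, min_count=config.min_count, strict_gt=config.strict_gt
            )
            outputs["sequences"] = str(
                write_table(_sequences_frame(seqs), outdir / "sequences.tsv",
                            seed=config.seed)
            )
            freq_df = pd.DataFrame(
                sorted(freq.counts.items(), key=lambda gc: (-gc[1], gc[0])),
                columns=["gene_id", "count"],
            )
            freq_df["passed"] = freq_df["gene_id"].isin(candidates)
            outputs["frequency"] = str(
                write_table(freq_df, outdir / "frequency.tsv", seed=config.seed)
            )
            logger.info("frequency screen: %d of %d genes reached count >= %d",
                        len(candidates), len(freq.counts), config.min_count)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("aco_seriation", exc) from exc
    counts["candidates"] = len(candidates)
    if freq is not None and not candidates:
        flags.append("no_candidates_passed_screen")

    # ---- stage: clinical ranking ----------------------------------------
    chosen: str | None = None
    source: str | None = None
    fit_rows: list[dict] = []
    if candidates:
        try:
            ranked = clinical_assoc.rank_by_fit(
                candidates, expr, phen, case_only=config.fit_case_only
            )
            chosen = ranked[0][0]
            source = "clinical_fit"
            for gene, fits in ranked:
                for endpoint in ("mmse", "nft"):
                    f = fits[endpoint]
                    if f is None:
                        continue
                    fit_rows.append({
                        "gene_id": gene, "endpoint": endpoint, "slope": f.slope,
                        "intercept": f.intercept, "r_squared": f.r_squared,
                        "p_value": f.p_value, "n": f.n,
                    })
            outputs["fits"] = str(
                write_table(pd.DataFrame(fit_rows), outdir / "fits.tsv",
                            seed=config.seed)
            )
        except DataIOError as exc:
            flags.append("no_clinical_data")
            logger.info("clinical ranking unavailable (%s); falling back to "
                        "top-frequency candidate", exc)
            chosen = candidates[0]
            source = "top_frequency"

    # ---- stage: diagnostic ----------------------------------------------
    cv_values: list[float] = []
    cv_mean: float | None = None
    ho_auc: float | None = None
    threshold: float | None = None
    if chosen is not None:
        try:
            feats = np.column_stack([
                expr.gene_values(anchor), expr.gene_values(chosen)
            ])
            report_cv = diagnostic.cv_auc(
                feats, labels, k=config.cv_folds, kernel=config.kernel,
                c=config.svm_c, seed=config.seed + SEED_OFFSET_DIAG,
            )
            cv_values = list(report_cv.auc_values)
            cv_mean = report_cv.mean_auc
            ho_auc = diagnostic.holdout_auc(
                feats, labels, train_fraction=config.train_fraction,
                kernel=config.kernel, c=config.svm_c,
                seed=config.seed + SEED_OFFSET_SPLIT,
            )
            threshold = diagnostic.anchor_threshold(feats, labels, axis=0)
            outputs["cv_auc"] = str(
                write_table(
                    pd.DataFrame({"fold": range(1, len(cv_values) + 1),
                                  "auc": cv_values}),
                    outdir / "cv_auc.tsv", seed=config.seed,
                )
            )
            logger.info("diagnostic: mean CV AUC %.3f, holdout AUC %.3f, "
                        "anchor threshold %s", cv_mean, ho_auc, threshold)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("diagnostic", exc) from exc
    else:
        flags.append("no_final_candidate")

    report = RunReport(
        version=__version__,
        seed=config.seed,
        anchor=anchor,
        counts=counts,
        candidates=candidates,
        chosen_candidate=chosen,
        candidate_source=source,
        fit_table=fit_rows,
        cv_auc_values=cv_values,
        cv_mean_auc=cv_mean,
        holdout_auc=ho_auc,
        anchor_threshold=threshold,
        flags=flags,
        outputs=outputs,
    )
    write_report(report, outdir)
    return report


def write_report(report: RunReport, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(report.to_json() + "\n", encoding="utf-8")
    return path


def load_report(outdir: str | Path) -> RunReport:
    path = Path(outdir) / "report.json"
    if not path.exists():
        raise DataIOError(f"no report.json under {outdir}")
    return RunReport(**json.loads(path.read_text(encoding="utf-8")))
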